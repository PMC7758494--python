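# Empirical maximum accessible surface area per residue type (angstrom^2),
# Tien et al. 2013 (PLoS ONE 8:e80635), used as the denominator of relative
# accessibility.  Override with any two-column TSV of the same shape.
ALA	121.0
ARG	265.0
ASN	187.0
ASP	187.0
CYS	148.0
GLU	214.0
GLN	214.0
GLY	97.0
HIS	216.0
ILE	195.0
LEU	191.0
LYS	230.0
MET	203.0
PHE	228.0
PRO	154.0
SER	143.0
THR	163.0
TRP	264.0
TYR	255.0
VAL	165.0
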