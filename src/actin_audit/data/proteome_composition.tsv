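# Reference amino-acid composition of the reviewed human proteome
# (approximate SwissProt average frequencies, fraction of residues).
# Used as the denominator of composition enrichment; values are
# renormalised to sum to 1 on load.
A	0.0702
R	0.0564
N	0.0359
D	0.0473
C	0.0230
E	0.0710
Q	0.0477
G	0.0657
H	0.0263
I	0.0433
L	0.0996
K	0.0573
M	0.0213
F	0.0365
P	0.0631
S	0.0833
T	0.0536
W	0.0122
Y	0.0267
V	0.0597
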