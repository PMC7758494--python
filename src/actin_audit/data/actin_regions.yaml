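# Canonical region definitions for skeletal-muscle alpha-actin (mature
# chain numbering, 1-based inclusive, length 375).
# Exons: protein segments encoded by the six gene exons.
# Subdomains: the four structural subdivisions of the monomer.
# Loops: mobile loops implicated in inter-monomer contacts.
exons:
  exon_I: "1-42"
  exon_II: "43-151"
  exon_III: "152-204"
  exon_IV: "205-269"
  exon_V: "270-329"
  exon_VI: "330-375"
subdomains:
  subdomain_1: "1-32,70-144,338-372"
  subdomain_2: "33-69"
  subdomain_3: "145-180,270-337"
  subdomain_4: "181-269"
loops:
  D_loop: "39-50"
  W_loop: "165-172"
  H_loop: "264-273"
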