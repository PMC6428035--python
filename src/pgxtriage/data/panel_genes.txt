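# Bundled pharmacogene panel fixture. Covers every gene of the bundled
# actionable-variant fixture plus a spread of commonly screened pharmacogenes;
# the full published 293-gene panel is user-supplied.
CYP2C9
CYP2C19
CYP2D6
CYP2B6
CYP4F2
CYP3A4
CYP3A5
CYP1A1
CYP1A2
CYP2R1
CYP24A1
SLCO1B1
SLC10A2
SLC22A1
SLC22A2
SLC22A6
ABCB1
ABCC4
ABCG2
ABCA4
UGT1A1
UGT2B7
UGT2B15
VKORC1
CFTR
DPYD
TPMT
NUDT15
COMT
VDR
F5
TP53
ANKK1
EPHX2
CDA
SULF1
G6PD
NAT2
GSTP1
IFNL3
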