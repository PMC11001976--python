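gene	role	dr_direction
SERPINA1	Antimicrobial	None
ATP5F1B	Antibacterial	None
CCL20	Antibacterial	None
CXCL2	Antibacterial	None
PI3	Antibacterial	None
LCN2	Antibacterial	None
PIGR	Antimicrobial	Up
DEFB1	Antibacterial	Up
CXCL3	Antibacterial	None
CXCL1	Antibacterial	None
ISG20	Antiviral	None
LTF	Antimicrobial	Up
CXCL6	Antibacterial, Antiparasitic	None
CXCL8	Antibacterial	None
AZGP1	Antimicrobial	None
CLU	Antimicrobial	Up
H2AFJ	Antibacterial, Antifungal	None
CXCL13	Antibacterial	None
SCGB2A1	Antimicrobial	Up
ZG16B	Antimicrobial	None
SLPI	Antibacterial, Antifungal, Antiviral	Down
BST2	Antiviral	None
GAPDH	Antibacterial, Antifungal	None
HMGN2	Antibacterial, Antiviral, Antifungal	None
S100A7	Antibacterial	Up
HMGB1	Antimicrobial	None
S100A8	Antifungal	None
S100A9	Antibacterial	None
B2M	Antimicrobial	Down
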