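gene	phenotype	frequency
# Phenotype prevalences approximate published U.S. population frequencies.
CYP2B6	IM	0.27
CYP2B6	NM	0.67
CYP2B6	PM	0.06
CYP2C19	IM	0.27
CYP2C19	NM	0.40
CYP2C19	PM	0.03
CYP2C19	RM	0.26
CYP2C19	UM	0.04
CYP2C9	IM	0.32
CYP2C9	NM	0.65
CYP2C9	PM	0.03
CYP2D6	IM	0.39
CYP2D6	NM	0.50
CYP2D6	PM	0.07
CYP2D6	UM	0.04
CYP3A4	Decreased	0.05
CYP3A4	Normal	0.95
CYP3A5	Expresser	0.08
CYP3A5	IntermediateExpresser	0.12
CYP3A5	NonExpresser	0.80
CYP4F2	Increased	0.30
CYP4F2	Normal	0.70
DPYD	Decreased	0.04
DPYD	Normal	0.96
HLA-B*57:01	Negative	0.94
HLA-B*57:01	Positive	0.06
IFNL3	Favorable	0.50
IFNL3	Unfavorable	0.50
SLCO1B1	Decreased	0.24
SLCO1B1	Normal	0.74
SLCO1B1	Poor	0.02
TPMT	IM	0.097
TPMT	NM	0.900
TPMT	PM	0.003
UGT1A1	IM	0.35
UGT1A1	NM	0.55
UGT1A1	PM	0.10
VKORC1	Normal	0.63
VKORC1	Sensitive	0.37
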