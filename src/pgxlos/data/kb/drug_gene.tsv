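drug	gene	actionable_phenotypes	source
abacavir	HLA-B*57:01	Positive	label
azathioprine	TPMT	IM;PM	cpic
capecitabine	DPYD	Decreased	cpic
citalopram	CYP2C19	PM;UM	cpic
clopidogrel	CYP2C19	IM;PM	cpic
escitalopram	CYP2C19	PM;UM	cpic
fluoxetine	CYP2D6	IM;PM	label
irinotecan	UGT1A1	PM	label
metoprolol	CYP2D6	IM;PM	cpic
omeprazole	CYP2C19	RM;UM	cpic
pantoprazole	CYP2C19	RM;UM	cpic
peginterferon	IFNL3	Unfavorable	cpic
simvastatin	SLCO1B1	Decreased;Poor	cpic
tacrolimus	CYP3A5	Expresser;IntermediateExpresser	cpic
tramadol	CYP2D6	PM;UM	cpic
warfarin	CYP2C9	IM;PM	cpic
warfarin	CYP4F2	Increased	cpic
warfarin	VKORC1	Sensitive	cpic
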