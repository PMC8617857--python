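inhibitor_drug	gene	induced_phenotype
fluoxetine	CYP2D6	PM
paroxetine	CYP2D6	PM
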