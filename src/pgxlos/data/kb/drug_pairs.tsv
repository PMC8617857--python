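drug_a	drug_b	severity
acetaminophen	ondansetron	minimal
aspirin	ibuprofen	minor
aspirin	warfarin	major
azithromycin	hydroxychloroquine	contraindicated
clopidogrel	omeprazole	moderate
fluoxetine	tramadol	major
furosemide	gentamicin	major
lisinopril	spironolactone	moderate
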