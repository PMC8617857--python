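{
  "version": "0.1.0",
  "panel": [
    "CYP2C19",
    "CYP2C9",
    "CYP2D6",
    "CYP3A4",
    "CYP3A5",
    "CYP2B6",
    "CYP4F2",
    "DPYD",
    "HLA-B*57:01",
    "IFNL3",
    "SLCO1B1",
    "TPMT",
    "UGT1A1",
    "VKORC1"
  ]
}
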