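{
  "LEV": {
    "name": "LEV",
    "ka_per_h": 2.618,
    "ke_per_h": 0.099,
    "a": 0.0073
  },
  "TPM": {
    "name": "TPM",
    "ka_per_h": 1.215,
    "ke_per_h": 0.033,
    "a": 0.002
  },
  "LTG": {
    "name": "LTG",
    "ka_per_h": 1.572,
    "ke_per_h": 0.012,
    "a": 0.00078
  }
}
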