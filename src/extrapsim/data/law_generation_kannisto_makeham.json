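{
  "law_kind": "kannisto_makeham",
  "params": {
    "a": 4.058703342277944e-05,
    "b": 0.09403826818191467,
    "c": 2.330128192451646e-16
  },
  "x0": 40.0,
  "label": "synthetic Canadian 1980/82, Kannisto-Makeham"
}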