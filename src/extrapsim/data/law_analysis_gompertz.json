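{
  "law_kind": "gompertz",
  "params": {
    "rate": 0.004573783490188735,
    "shape": 0.1095347055950078
  },
  "x0": 60.0,
  "label": "synthetic Canadian 2017/19, Gompertz from 60"
}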