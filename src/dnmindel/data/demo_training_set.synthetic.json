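{
  "composition": {
    "validated": 8,
    "synthetic": 23,
    "false_dnm": 20,
    "inherited": 23
  },
  "fingerprint": "b6229c836e5efbb5",
  "seed": 404,
  "n_examples": 74
}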