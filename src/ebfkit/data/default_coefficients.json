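{
  "c1": 0.936,
  "c2": 0.089,
  "c3": 0.602,
  "c4": 0.375,
  "c5": 0.130,
  "c6": 0.413,
  "ci_c1": 0.132,
  "ci_c2": 0.012,
  "ci_c3": 0.126,
  "ci_c4": 0.065,
  "ci_c5": 0.004,
  "ci_c6": 0.006
}
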