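name: ackley
goal: minimize
objective:
  kind: ackley
  n_dims: 2
  a: 20.0
  b: 0.2
  c: 6.283185307179586
  lower: -20.0
  upper: 20.0
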