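system:
  classes: {C: [0], H: [1, 2, 3, 4, 5]}
  populations: {C: 6.0, H: 0.8}
  formal_charge: 1
  exponents: {C: 1.0, H: 1.0}
basis:
  M: 4
fit:
  model: chm
  d0: 2.0
  t0: 2.0
  alpha: {C: 1.0, H: 1.0}
  charge_weight: 0.01
data:
  preset: basin2A
  system: ch5+
  seed: 1
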