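system:
  classes: {H: [0, 1, 2]}
  populations: {H: 0.6666666666666666}
  formal_charge: 1
  exponents: {H: 1.0}
basis:
  M: 2
fit:
  model: chm
  d0: 1.0
  t0: 1.5
  alpha: {H: 0.6}
  charge_weight: 0.01
data:
  system: h3+
  kinetic_energy: 7335.0
  timestep: 0.25
  steps: 2000
  stride: 4
  seed: 1
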