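data:
  kinetic_energy: 16000.0
  preset: basin1
  restraints: []
  steps: 50000
  stride: 5
  system: ch5+
  timestep: 1.0
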