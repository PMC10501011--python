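data:
  kinetic_energy: 5000.0
  preset: basin2C
  restraints:
  - k: 0.5
    pair:
    - 0
    - 1
    r0: 3.0
  - k: 0.5
    pair:
    - 0
    - 2
    r0: 3.0
  steps: 4000
  stride: 5
  system: ch5+
  timestep: 1.0
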