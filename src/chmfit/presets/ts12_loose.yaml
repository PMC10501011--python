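data:
  kinetic_energy: 5000.0
  preset: ts12_loose
  restraints:
  - k: 0.1
    pair:
    - 5
    - 2
    r0: 1.337
  - k: 0.1
    pair:
    - 4
    - 2
    r0: 1.343
  steps: 10000
  stride: 7
  system: formamide
  timestep: 1.0
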