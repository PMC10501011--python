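data:
  kinetic_energy: 1000.0
  preset: ts12_tight
  restraints:
  - k: 0.2
    pair:
    - 5
    - 2
    r0: 1.337
  - k: 0.2
    pair:
    - 4
    - 2
    r0: 1.343
  steps: 1000
  stride: 3
  system: formamide
  timestep: 1.0
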