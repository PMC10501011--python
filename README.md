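# chmfit

Potential-energy-surface fitting with a core-Hamiltonian charge-density
model parameterized by permutationally invariant polynomials (PIPs).

Instead of fitting the energy directly with one invariant polynomial
expansion, the model writes

```
E(R) = Enuc(R) + sum_ab P_ab(R) Hcore_ab(R) + dE(R) + offset
```

where `Hcore` collects analytic one-electron integrals (kinetic +
electron-nucleus attraction) over one s-type Gaussian per atom, the
charge-density matrix elements `P_ab` are expanded in atom- and
pair-covariant PIPs of Morse-transformed internuclear distances, and the
correction energy `dE` uses the ordinary invariant PIP basis.  All linear
coefficients come from a single weighted least-squares problem
(an optional low-weight block of rows nudges the configuration-dependent
electron count `sum_ab P_ab S_ab` toward the declared populations); the
few nonlinear parameters (Morse ranges `d0`, `t0` and Gaussian exponents
per atom class) are optimized by a grid-plus-simplex search of the
validation RMSE.  A conventional invariant-PIP fit is included as the
comparison baseline, and a data-generation module (analytic surrogate
surfaces, NVE / restrained velocity-Verlet sampling, stratified pruning,
grid-midpoint splits) exercises everything at desk scale with no external
inputs.

## Layout

| module             | contents                                                            |
| ------------------ | ------------------------------------------------------------------- |
| `chmfit.molsys`    | configurations, atom typing, distances, permutation groups          |
| `chmfit.pipbasis`  | invariant / atom-covariant / pair-covariant PIP enumeration, augmentation, evaluation |
| `chmfit.integrals` | s-Gaussian overlap, kinetic, nuclear attraction (Boys function), core matrices |
| `chmfit.chm`       | the density-matrix energy model, design assembly, linear & nonlinear fitting, baseline PIP fit |
| `chmfit.datagen`   | surrogate surfaces, NVE / restrained dynamics, pruning, splits, engine adapter contract |
| `chmfit.io` / `chmfit.cli` | extended-XYZ datasets, YAML run configs, model files, CLI   |

## CLI

```sh
# enumerate a basis and print its size L and the coefficient dimension
chmfit genbasis --config examples/h3.yaml

# sample a training set from the surrogate surface
chmfit sample --config examples/h3.yaml --out train.xyz --seed 1

# fit, predict, report
chmfit fit --config examples/h3.yaml --train train.xyz --model-out model.json
chmfit predict --model model.json --xyz train.xyz --units cm-1
chmfit report --model model.json --data train.xyz
```

A run config is YAML with `system` (classes, populations, charge,
exponents), `basis` (`M`, optional augmentation `patterns`), `fit`
(model kind, `d0`/`t0`/`alpha`, `charge_weight`, optional nonlinear
`optimize` + `search`), `data` (sampling preset or explicit trajectory
parameters) and `output` blocks.  Sampling presets matching the
documented restrained-trajectory protocols ship in
`src/chmfit/presets/`.

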