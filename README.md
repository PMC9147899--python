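# spotfit

Analysis of two-dimensional antigen-microspot titrations: arrays printed
with an antigen density series are incubated with a serum dilution series,
and the resulting binding surface is fitted with the product of two
generalized logistic (Richards) functions on the log-log scale. The fit
yields unit-free, concentration-independent measures of polyclonal
antibody reactivity — the inflection point `x_i` on the ln-molar-antigen
axis and the asymmetry parameter `d` — together with activity-coefficient
curves that can be overlaid across samples and isotypes. Conventional
mid-point/end-point titers are provided for comparison; unlike `(x_i, d)`
they depend on the antigen density.

## Modules

- `spotfit.model_core` — Richards curve, its logarithm, the 2D product
  model, activity-coefficient curves, limiting slope `s = k/(d-1)`.
- `spotfit.synthetic_data` — equilibrium binding simulator (complex
  formation with steric inhibition, log-linear detection, lognormal
  noise), array layouts (7 half serial antigen dilutions from 200 µM in
  quintuplicate), CSV and GPR-dialect writers.
- `spotfit.preprocess` — spot-table readers, replicate averaging,
  background subtraction using the least-concentration spots, log
  transform to the fitting grid.
- `spotfit.fitting` — Gauss–Newton nonlinear least squares (step-halving,
  Levenberg damping on rank deficiency) for the 1D and 2D models, with
  profile-likelihood confidence intervals.
- `spotfit.titer` — per-density mid-point and end-point titer calculators.
- `spotfit.cli` — `spotfit` command with `simulate | quantify | fit |
  titer | report` subcommands.

## CLI

```sh
# simulate a two-channel experiment (writes spots.csv, spots.gpr, truth.json)
spotfit simulate --seed 1 --out-dir sim

# reduce spots to the ln-signal fitting grid
spotfit quantify sim/spots.csv --out binding_table.csv

# 2D fit + profile CIs + activity-coefficient curves per channel
spotfit fit sim/spots.csv --out-dir results

# per-density conventional titers
spotfit titer sim/spots.csv --out titers.csv

# everything at once
spotfit report sim/spots.csv --out-dir results
```

All commands accept `--config cfg.json`; `simulate` supports
`"mode": "surface"` to generate data directly from a known 2D model surface
for recovery studies.

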