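# bitecurve

Cumulative food-intake curves from bite-level meal records.

Researchers studying ingestive behavior summarize a meal by its *cumulative
intake curve* — grams consumed as a function of time within the eating
episode.  Laboratory instruments (the Universal Eating Monitor, drinkometers)
measure that curve by continuously weighing the meal, but their strict
protocols are a poor fit for children and for multi-item meals.  The
practical alternative is observational video coding: record the timestamp of
every bite and approximate intake with the average bite size.  `bitecurve`
provides the two standard models of the cumulative intake curve, estimates
them from bite-level data, and — because average-bite-size data carries
extra measurement error — ships a complete simulation framework to certify
that the estimation machinery recovers known ground truth under
video-coding-like noise.

## Models

Both models describe cumulative intake `E(t)` (g) at minute `t` of the meal:

* **Quadratic** (Kissileff): `E(t) = a·t² + b·t + c`, with `b` the initial
  eating rate (g/min), `a` the change in eating rate across the meal
  (negative when eating decelerates with satiation) and `c` an
  uninterpreted intercept.  Its inverted-U shape can predict *non-feasible*
  intake — negative intake early, declining intake late.
* **LODE** (logistic ordinary differential equation, Thomas): the solution
  of `dE/dt = (θ + rE)(1 − E/E_max)`:

  `E(t) = (e^{kt} − 1) / (e^{kt}/E_max + r/θ)`, `k = (E_max·r + θ)/E_max`

  with `θ` the initial eating rate (g/min), `r` the doubling rate (1/min;
  `1/r` approximates the intake-doubling time) and `E_max` the meal's total
  intake, which the curve approaches asymptotically.  The curve is strictly
  increasing and bounded, so its predictions are always feasible.

Fitting maximizes a Gaussian likelihood of cumulative intake at the
observed bite times (quadratic: exact weighted least squares; LODE: bounded
nonlinear least squares with multi-start, `E_max` fixed to the observed
total).  Per-parameter 95% confidence intervals are profile-likelihood
intervals: the bound sits where the deviance, re-optimizing all other free
parameters, reaches the χ²(1) quantile.  The declared measurement
resolution (bite quantization, optional video-coding timing resolution)
floors the error scale so intervals stay honest on noise-free data; see
`docs/methods.md`.

## Worked example

Build a feasible LODE parameter distribution from simulated child-meal
microstructure, simulate three video-coded-style meals, and fit them:

```
$ printf 'n_generating_cases: 120\n' > study.yaml
$ bitecurve generate --config study.yaml --seed 7 --model lode --outdir .
wrote distribution_lode.json (120 retained fits)
$ bitecurve simulate --distribution distribution_lode.json \
    --condition measurement_error --n-cases 3 --seed 8 --out meals.csv
wrote 3 simulated meals to meals.csv
$ bitecurve fit meals.csv --model lode --timing-sd 0.033
{
  "case0000": {
    "estimates": {
      "theta": 15.781796063244233,
      "r": 0.6434859786647239,
      "emax": 344.01651314958406
    },
    ...
    "ci": {
      "theta": [15.358974693637442, 16.212530366632343],
      "r": [0.6339755320543057, 0.6530475674255641]
    },
    "ci_level": 0.95
  },
  ...
}
```

This case was simulated from true parameters θ = 15.769 g/min,
r = 0.6434 min⁻¹ (recorded in `meals.csv.truth.json`): the recovered
estimates match to three significant figures despite the average-bite-size
and timing-coding noise, and both true values fall inside their 95%
profile intervals.  `--timing-sd 0.033` declares the ~2 s timing
resolution of manual video coding so it is propagated into the likelihood.

`bitecurve run-all --seed 1 --outdir study/` executes the full validation
study (below) and writes tidy CSV tables plus a JSON summary and manifest.

## The validation study

`bitecurve.report.run_study` certifies parameter recovery end to end.  For
each model it (1) builds a generating distribution by fitting the model to
500 simulated child meals (bite counts, totals and durations drawn from
configurable reference statistics; bite timings from a zero-truncated
logistic so the cumulative curve decelerates), (2) draws 100 "true"
parameter sets, (3) simulates each under three conditions — **constant
bite** (noise-free), **variable bite** (process noise on bite sizes, exact
timings, like continuous weighing) and **bite measurement error**
(average-bite-size intake plus jittered timings, like video coding) — then
(4) fits, builds profile CIs, and reports coverage of the true values,
distinguishability of the estimates (how many other cases' CIs contain
each estimate), a median-scaled goodness-of-fit index, and RMSE/pseudo-R²
of intake and timing predicted from the recovered parameters, with
Fisher-exact and Mann–Whitney contrasts between models and conditions.

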