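# Methods

This note documents the models, the measurement conventions, the simulator,
and the numerical choices behind `bitecurve`, including the places where the
design was genuinely open and what the package chose.

## Models and units

Time is in minutes, intake in grams, throughout.

**Quadratic**: `E(t) = a t² + b t + c`.  `b` (g/min) is the initial eating
rate, `a` (g/min²) the change in eating rate (negative under satiation),
`c` (g) an uninterpreted intercept.  The inverse used for timing
prediction solves on the *increasing* branch (pre-apex for `a < 0`),
evaluated in the cancellation-safe form `t = 2(e−c)/(b + √(b²−4a(c−e)))`,
which degrades gracefully to `(e−c)/b` as `a → 0`.  Intake above the apex
or times below zero are returned as `nan` *non-feasible markers*, not
exceptions: downstream diagnostics count them, and a case with more than
10% non-feasible predicted bites is marked non-convergent and excluded
from error summaries.

**LODE**: the logistic rate law `dE/dt = (θ + rE)(1 − E/E_max)` with
solution `E(t) = (e^{kt} − 1)/(e^{kt}/E_max + r/θ)`, `k = r + θ/E_max`.
`θ > 0` (g/min) is the initial eating rate, `r > 0` (1/min) the doubling
rate, `E_max > 0` (g) the asymptotic meal total.  The forward map is
evaluated in the factored form `(1 − e^{−kt})/(1/E_max + (r/θ)e^{−kt})` so
large `k·t` returns `E_max` instead of overflowing.  The closed-form
inverse is `t = (1/k)·ln[(1 + e r/θ)/(1 − e/E_max)]`, defined on
`0 ≤ e < E_max`; the test suite verifies the closed form against direct
numerical integration of the rate law.

## The midpoint observation convention

Observed cumulative intake is a step function that jumps by `Δᵢ` at bite
`i`; the smooth model curve cannot pass through the top of every jump.
`bitecurve` adopts a half-increment continuity correction everywhere: the
curve is taken to cross the *middle* of each jump, so bite `i` occurs where
`E(t) = eᵢ − Δᵢ/2`.  This single convention is used to simulate bite times
from true parameters, to form the fitting target, and to predict timings
from recovered parameters.  Besides being the natural discretization, it
resolves a structural singularity: with `E_max` equal to the meal total
(its defining value), intake at the final bite sits exactly on the LODE
asymptote and its model time would otherwise be infinite.  With the
midpoint convention every inversion is finite, LODE predictions are always
feasible, and noise-free simulations are exactly identifiable (the
recovery battery confirms recovery to ~1e-6 and timing/intake pseudo-R²
of 1.0 on noise-free data).

## Likelihood and confidence intervals

Fitting maximizes an independent-Gaussian likelihood of the
midpoint-corrected intake at the observed bite times,

    yᵢ = E(tᵢ; params) + εᵢ,   εᵢ ~ N(0, s²·σᵢ²).

The declared per-bite resolution has two components:

* **bite quantization** `σ_q = (average bite size)/√12` — intake recorded
  by counting bites carries a uniform error of up to one increment, whose
  SD is `Δ/√12`;
* **timing resolution** `(rateᵢ·timing_sd)` — when bite timestamps come
  from manual video coding, their resolution `timing_sd` (default 2 s
  where declared) displaces intake in proportion to the local eating rate
  (delta method).  Rates are taken from a first-pass fitted curve and the
  model is refit once with the combined weights (a single IRLS pass);
  data-derived rates are too noisy at closely spaced bites.

The overdispersion scale `s` is profiled from the residuals but floored at
1: intervals never shrink below the declared resolution (noise-free data
would otherwise give zero-width intervals), and they widen when the data
are noisier than declared.  `timing_sd` defaults to 0 and should be set to
the coding resolution for video-coded data; the study pipeline sets it
only for the measurement-error condition.

The quadratic model is linear in its parameters and is fit by exact
weighted least squares; the LODE model is fit by bounded nonlinear least
squares (`θ, r` free, `E_max` fixed to the observed total — the value the
model defines it to be, and the reason no interval is reported for it)
from five data-driven starts (initial rate from the first quarter of the
meal, doubling rate from the observed half-intake time, each perturbed
×0.3/×3, plus the global mean rate).

**Profile intervals.**  For each free parameter the 95% bound solves
`deviance(ψ) = χ²₁(0.95) = 3.841`, where the deviance re-optimizes all
other free parameters (closed form for the quadratic; warm-started 1-d
least squares for LODE) and the profiled, floored scale.  The search steps
10% of |estimate| (0.1 absolute near zero), doubling until the cutoff is
bracketed, then polishes with Brent to 1e-4 relative tolerance.  Bounds
that run into a positivity limit are clipped and flagged `censored`; a
profile that never reaches the cutoff yields an `open` bound treated as
infinite (it can only make coverage conservative).

## The generating model

The simulator emulates child meal microstructure.  Meal-level profiles
(bite count, total intake, meal duration) are drawn from a positive-
truncated multivariate normal with configurable moments; the shipped
defaults — 40 ± 15 bites, 300 ± 100 g, 15 ± 5 min, correlations
(bites–intake 0.5, bites–duration 0.4, intake–duration 0.3) — are
documented approximations of published child-meal statistics, not fitted
values, and any study should override them with its own reference data.

Bite timings for a profile are sorted draws from a zero-truncated standard
logistic (half-logistic; location 0, scale 1 — the scale cancels under
max-normalization), scaled by `duration·(value/max)` so the last bite ends
the meal, then Gaussian-jittered (SD 2% of duration) and repaired to be
positive, strictly increasing, and within the meal.  The decreasing
half-logistic density front-loads bites, producing the decelerating
cumulative curve of a satiating meal; intake rises by one average bite per
bite.  Each model is fit to every generated meal and a fit is retained
when its curve can produce the complete meal — the midpoint bite ladder
inverts to finite, positive, strictly increasing times.  (A stricter
"non-decreasing over the whole meal" criterion is unattainable for the
quadratic model, whose fitted apex routinely sits just inside the meal;
that inverted-U behavior is precisely the model's documented limitation.)
Retained parameter vectors, jointly with bite count and total intake, are
summarized as a multivariate normal plus medians; true parameter sets for
the recovery study are drawn from it with rejection of draws that cannot
produce a feasible meal, and LODE draws set `E_max` equal to the drawn
total intake.

## Simulation conditions

* **Constant bite** — intake ladder of equal average bites, times computed
  exactly from the true parameters; no noise.  Tests identifiability.
* **Variable bite** — Gaussian process noise (SD 10% of the average bite)
  on the cumulative values, repaired by sorting, positivity clipping and
  rescaling so the final value conserves the meal total; times recomputed
  exactly from the jittered intake.  Emulates continuous weighing of a
  human eater: bite sizes vary but the record is error-free.
* **Bite measurement error** — the variable-bite meal re-recorded the way
  a video coder would: intake replaced by the average-bite ladder and
  timings jittered (SD 2 s) after the fact, then re-sorted.  Both recorded
  channels now deviate from the true curve.

With all noise SDs zero the three conditions emit identical data.
Conservation (final intake = drawn total) holds in every condition — the
asymptote is defined as the episode's total intake, so process noise is
not allowed to change it.

## What the defaults do and do not show

The study defaults (500 generating cases, 100 recovery cases per model —
a typical sample size for child eating-behavior studies — three
conditions, 95% profile CIs) run in about a minute on one CPU; the test
suite exercises the full default study once.  Because the generator's
timing law is itself logistic-shaped, generated meals are kind to the LODE
model; real meals include pauses, sips and within-meal bursts that neither
model represents, so passing recovery here certifies the estimation
machinery, not the models' adequacy for any particular population.  The
simulator also couples θ and r through meal pace more strongly than
empirical child data appears to, so cross-parameter correlation magnitudes
should be read qualitatively (the quadratic a–b correlation ≈ −0.95 is far
stronger than any LODE coupling).

## Known limitations

* Measurement-error timing jitter plus re-sorting slightly widens crowded
  early inter-bite spacings, biasing θ low by ~1%; the declared-resolution
  likelihood keeps coverage ≥95%, but a deconvolution estimator would be
  needed to remove the bias itself.
* `E_max` is fixed, not estimated; meals interrupted before satiation
  violate its defining identity and will bias θ and r.
* Comparison p-values are reported raw, with no multiple-testing
  correction, and condition contrasts treat the per-condition samples as
  independent draws.
* Bayesian and hierarchical (multi-meal) estimation are out of scope.
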