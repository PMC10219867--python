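# Methods

`edwarn` implements an hourly early-warning pipeline for emergency-department
(ED) crowding: univariate seasonal exponential-smoothing forecasters of
arrivals and occupancy, a prospective rolling-origin harness, a quartile-based
binary crowding definition, and an evaluation layer built on the rank-based
AUC. A mechanistic synthetic ED generator makes the whole pipeline — and every
claim the test suite checks — exercisable without hospital data.

## Forecasting models

Three Holt-Winters variants are implemented, in the classical
parameterization, over a seasonal cycle of `m = 24` hours:

* **AHWM** (additive trend + additive seasonality)

      l_t = α (y_t − s_{t−m}) + (1−α)(l_{t−1} + b_{t−1})
      b_t = β (l_t − l_{t−1}) + (1−β) b_{t−1}
      s_t = γ (y_t − l_{t−1} − b_{t−1}) + (1−γ) s_{t−m}
      ŷ_{t+k} = l_t + k b_t + s_{t+k−m(⌈k/m⌉)}

* **MHWM** replaces the seasonal subtraction/addition by division/
  multiplication (`ŷ_{t+k} = (l_t + k b_t)·s`).
* **HWDM** multiplies the trend contribution by a damping factor
  `φ ∈ [0.8, 0.98]`: forecasts use `(φ + φ² + … + φᵏ) b_t`, which is bounded
  as `k → ∞`.

Parameters `α, β, γ ∈ [0, 1]` (and `φ` for HWDM) are estimated by maximum
likelihood under Gaussian one-step errors, which reduces to minimizing the
residual sum of squares; σ² is the mean squared one-step residual. The
optimizer is bounded L-BFGS-B from a fixed five-point multi-start grid
(deterministic; extra starts beyond five are drawn from a seeded generator).
Initial states use the standard two-cycle heuristic: level = mean of the
first cycle, trend = per-step difference of the first two cycle means,
seasonal indices = averaged per-position deviations (differences normalized
to sum 0 for additive seasonality, ratios normalized to mean 1 for
multiplicative). For long hourly training series the difference from
estimating initial states by MLE is negligible, and the heuristic keeps
hourly refits fast and deterministic.

Design choices in ambiguous corners:

* The damped variant uses **additive** seasonality, symmetric with AHWM.
* The multiplicative variant requires strictly positive data; overnight
  arrival counts of zero are handled by adding a fixed offset of 0.5 before
  training and removing it from forecasts.
* Count forecasts are floored at 0 but **not** rounded: the evaluation uses
  them as continuous scores and rounding would manufacture ties.
* Weekly (m = 168) seasonality is not modelled; single-seasonality
  Holt-Winters cannot hold both cycles, and the daily cycle dominates
  hourly ED data.
* The inner recursions are numba-compiled; fitting a model on years of
  hourly data takes well under a second.

The statsmodels implementations of the same recursions are used in the test
suite as independent references (never as the implementation): state
trajectories are compared against `ExponentialSmoothing` at fixed parameters,
and multi-step forecasts are verified both against `ETSModel` (additive
variants) and through the zero-residual fixed-point property: appending the
claimed forecasts to the series and re-running the reference recursion must
produce zero residuals over the extension.

## Prospective harness

At each hourly forecast origin the harness trains on **all** history up to
and including the origin — never later ("no lookahead" is property-tested by
corrupting post-origin values) — and writes 24 hourly point forecasts per
model × target to an append-only CSV prediction store keyed by
(origin, model, target, horizon). Full parameter re-estimation happens every
`refit_stride` hours (default 1 in the config; the desk-scale runs in this
repository use 24); between refits the smoothing states are advanced through
each new observation with the last fitted parameters, so forecasts always
start from the most recent state. Origins with insufficient history
(< 2m hours) or a fitting failure are skipped and logged with a reason code;
the run continues, mimicking a deployed system that keeps operating through
downtime. Training gaps of ≤ 6 missing hours are linearly interpolated
(keeping seasonal alignment); longer gaps truncate history to the run after
the gap. `created_at` is recorded as the origin itself so a re-run of the
same configuration is byte-identical.

## Crowding definition

Daily peak occupancy (DPO) is the maximum occupancy of each calendar day
(00:00–23:00; ties take the first hour). The crowding threshold θ is the
nearest-rank 75th percentile of complete-day DPOs — an observed integer
occupancy level, matching how such thresholds are reported in practice. An
hour is crowded when occupancy **reaches** θ (`≥`), a 24-hour window when
any of its hours is crowded. Windows containing missing hourly labels but no
observed crowding are labelled *missing*, not 0, so downtime cannot create
false negatives. θ is computed once over the full evaluation period; a
rolling threshold is out of scope. Incomplete days stay out of the threshold
estimate.

## Evaluation

All binary metrics are built from (score, label) pairs:

* **AUC** is the Mann-Whitney statistic with midrank tie handling,
  `P(s⁺ > s⁻) + ½P(tie)`; single-class samples are *undefined* (reported
  missing), never coerced to 0.5.
* **Class balancing**: noncrowded pairs are randomly downsampled without
  replacement to the number of crowded ones (seeded, deterministic). The
  default is a single draw; an `n_draws` option averages the point estimate
  over repeated draws to remove draw noise (the downsampled AUC is unbiased
  for the full-sample AUC).
* **Confidence intervals**: percentile bootstrap over jointly resampled
  pairs, 250 iterations by default; single-class resamples are redrawn.
* **PPH** (per horizon h = 1..24): pairs are (forecast for origin+h,
  crowding label at origin+h), aggregated over origins.
* **PPO** (per origin hour 0..23): the window score is the **maximum of the
  24 point forecasts** — the natural analogue of predicted daily peak
  occupancy — and the label is the 24-hour window label.
* **AUC matrix**: the (origin-hour, horizon) cell scores only the restricted
  pairs, without downsampling; cells lacking a crowding event are missing.
* **Single-threshold metrics** (sensitivity, specificity, precision, F1)
  use θ itself as the unadjusted score threshold (predicted occupancy ≥ θ ⇒
  predict crowded); zero-denominator ratios are missing.
* **Continuous metrics**: MAE, MSE and RMSE per model × target aggregated
  over all horizons; RMSE ≥ MAE is asserted as a standing invariant.
* No multiple-testing adjustment is applied to the per-stratum CIs.

## Synthetic ED generator

Occupancy is generated **mechanistically** rather than as a direct seasonal
signal, so arrivals and occupancy are mutually consistent:

* Arrivals are a nonhomogeneous Poisson process with a diurnal intensity
  vector λ(hour): trough 2/h at 05–06, peak 13/h at 16:00.
* Each day draws an i.i.d. log-normal **surge multiplier**
  (mean ≈ 1, σ_day = 0.22, capped at 1.4) applied to intensities in
  12:00–23:00. The cap reflects capacity-bounded demand on a real ED.
* Each arrival draws a uniform within-hour instant and a log-normal length
  of stay (median 6 h, σ = 0.65, truncated at 12 h); occupancy at the top
  of an hour counts patients present (an M_t/G/∞ queue). The 12-h
  truncation means no patient arriving before midnight is still present
  during the next day's crowding-capable hours (≥ 13:00), so together with
  the i.i.d. surges, midnight 24-h crowding prediction is no-skill
  *exactly by construction* — an untruncated stay distribution would leak
  a previous evening's surge into the next afternoon. The queue reproduces
  the occupancy cycle lagging arrivals by ~2 h, a morning trough median
  ≈ 22, an evening peak median ≈ 74 at 17–18, ≈ 4% of hours crowded under
  the quartile rule, and crowding confined to 13:00–23:00 (verified over
  12 simulated years; `scripts/calibrate.py` reprints these statistics).
* Downtime injection removes a contiguous block (≈ 70% of the missing mass)
  plus sporadic single hours to a target missing fraction, mirroring the two
  failure modes a deployed system exhibits.

What the generator does **not** emulate: weekly/holiday structure, trends,
exogenous drivers (weather, epidemics), within-day surge autocorrelation,
and admission/boarding dynamics. Tests passing on this generator therefore
demonstrate the pipeline's correctness and its structural behaviours
(horizon degradation, intraday information accrual, midnight no-skill) —
not clinical-grade accuracy on any particular hospital's data.

## Problem sizes and numerical choices

* Prospective evaluation runs in this repository use a 14-day warm-up,
  hourly origins and a 24-h refit stride; the shipped structural check uses
  1000 evaluation days because the midnight PPO AUC over only ~200 days
  (~50 crowded windows) has a sampling sd of ≈ 0.05, while ~250 windows
  bring it to ≈ 0.02.
* Seeds are explicit everywhere (generator, fitting multi-starts,
  downsampling, bootstrap); identical configurations yield byte-identical
  outputs.
* Degenerate inputs surface explicitly: all-equal DPOs make every day
  crowded (reported, not hidden); single-class AUC is an error; fitting
  failures carry best-so-far diagnostics.

## Known limitations

* Single-seasonality models; no prediction intervals (point forecasts only).
* The crowding threshold is global, not rolling.
* PPO's window score is the max of point forecasts; alternatives (e.g. the
  forecast at a fixed afternoon hour) are easy to add but not implemented.
* The multiplicative variant's 0.5 offset for zero counts is a pragmatic
  device; a count-data observation model is out of scope.
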