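# Methods

## Scope and data model

The package analyses two linked experiments. In the **co-location chamber
experiment**, three wearable optical PM monitors, a fast optical comparison
monitor, and a slow gravimetric-equivalent reference (TEOM-class) sample the
same chamber air while the concentration is stepped through a series of
quasi-steady plateaus. In the **cross-over feed trial**, each horse wears a
monitor for 8 h after being fed dry hay on one occasion and soaked hay on
another, and the calibrated 20-min and 8-h window means are compared.

All series travel as `UnitSeries`: a validated, time-ordered frame of
records at the instrument's nominal cadence (5 s wearable, 1 min reference
and comparison). Wearable records carry PM1/PM2.5/PM10 mass, six cumulative
number bins, temperature, humidity and optional GPS; validation enforces
`pm1 ≤ pm2_5 ≤ pm10`, non-increasing cumulative bins, non-negative
concentrations and RH ∈ [0, 100]. Out-of-order timestamps are sorted with a
warning (field SD-card logs rewind at boot); duplicate timestamps are
ambiguous and rejected. Timestamps are timezone-naive local time: the
intended studies are single-site.

## Steady-state screening and lag alignment

Minute averages are formed over `[minute, minute + 60 s)`; a minute is kept
only when it holds ≥ 75% of its expected samples (≥ 9 of 12 at 5-s cadence),
a standard completeness rule that stops single-sample minutes from driving
CV windows. A quasi-steady interval requires every rolling 5-min window of
the reference minute series to have sample CV (SD/mean, n−1 denominator)
below 1%. Maximal qualifying runs are reduced to consecutive, disjoint 5-min
reporting intervals from the run's start — deterministic, non-overlapping
(no pseudo-replicated regression points), and maximally data-preserving.

The reference's response lag is the argmax over integer minute shifts
k ∈ [0, 15] of the Pearson correlation between the comparison monitor and
the reference shifted k minutes earlier, with ties broken toward the
smaller lag. Sign convention everywhere: the *reference lags*; when a
reference interval `[a, b)` is matched, the fast instruments are averaged
over `[a − lag, b − lag)`. Matched intervals drop out when any instrument
covers < 75% of the window.

## Calibration and precision

Each unit's correction is a univariate OLS of the reference interval means
on the unit's raw interval means, `corrected = β·raw + α`, with r², RMSE,
the two-sided slope p-value, and a Shapiro–Wilk test of residual normality.
RMSE uses the √(SSE/n) (population) convention common in sensor-calibration
reporting rather than √(SSE/(n−2)); the serialized model states the
convention (`"rmse_convention": "sse_over_n"`), and the difference is ~3% at
n ≈ 30. The **universal** model is a fresh regression on the per-interval
arithmetic mean of the unit means — not the average of the per-unit
coefficients, which differs under noise.

Precision across units is reported as (a) a pooled inter-unit CV — per
interval, cross-unit sample SD over cross-unit mean, pooled by
root-mean-square across intervals — and (b) the pairwise Pearson correlation
matrix of unit interval means. Corrections are affine, so logs are corrected
without per-sample flooring; negatives are floored at 0 only at the
reporting (window-mean) stage, preserving regression-scale linearity.

## Exposure windows and the trial models

For each horse-day the short window is `[feed, feed + 20 min)` — the eating
peak, anchored at forage placement — and the extended window is
`[feed, feed + 8 h)`. Window exposure is the arithmetic mean of the raw 5-s
values, calibrated (affinely, hence equivalently before or after averaging)
and floored at 0. Windows with < 75% coverage are errors naming the gap.

The repeated-measures analysis is a linear mixed model on the natural log of
the window means with a random horse intercept, fitted by REML
(statsmodels `MixedLM` in a cell-means parametrization). Rationale: a
"repeated-measures model under a lognormal assumption" with two occasions
per subject is exactly the compound-symmetry model, which coincides with the
random-intercept formulation. Exposure data are multiplicative, so log-scale
modelling both stabilises variance and makes the back-transformed
least-squares means geometric-mean-like exposures.

Inference uses the closed-form balanced-design degrees of freedom to which
the Satterthwaite approximation reduces for this design (the cross-over is
complete and balanced after exclusions):

* treatment contrast in the two-cell model: within-horse, df = n − 1
  (identical to the paired t-test on log ratios);
* within-horse contrasts (treatment, duration, interaction) in the 2×2
  model: df = (k − 1)(n − 1) with k = 4 cells;
* least-squares-mean intervals involve both variance components
  (Var = (σ²_horse + σ²_resid)/n), so their df use the two-component
  Satterthwaite combination of the subject and residual mean squares.

With more than one pairwise comparison (the six cell contrasts of the 2×2
model) p-values are Tukey-adjusted via the studentized-range distribution
with parameters (4, 3(n − 1)); the single 2-level treatment comparison is
reported unadjusted. Confidence level is fixed at 95%. Zero window means
(possible after flooring) are replaced by 0.1 μg/m³ before logging, with a
logged count. Horses missing a design cell are excluded with a warning;
fewer than 3 complete horses is an error. Degenerate zero-variance inputs
(the deterministic limit used in tests) bypass the iterative fit: cell
means are returned and p-values are undefined (NaN) rather than fabricated.
`percent_reduction` is 100·(1 − lsmean_soaked/lsmean_dry).

## The synthetic generators

The generators define the package's study conditions; every downstream
stage is exercised on them without any field data, and their defaults are
anchored to the published study this pipeline targets.

**Chamber** (`ColocationConfig`): the true concentration path is a sequence
of 10-min plateaus joined by 3-min linear ramps; the default levels span
3.5–163.3 μg/m³ (PM2.5) and 9.7–2543 μg/m³ (PM10), the printed operating
range. The reference observes the truth through a pure 4-min delay plus
first-order exponential smoothing, averaged to 1-min with multiplicative
lognormal noise (CV 0.5%); the comparison monitor reports 1-min truth means
with the same small noise and zero lag; each wearable unit i reports 5-s raw
values `max(0, (true − αᵢ)/βᵢ)·exp(ε)` with lognormal noise of CV 5% at the
5-s scale. The default (βᵢ, αᵢ) are the three published per-unit calibration
pairs per fraction, so the generating universal slope is the harmonic mean
of the βᵢ (≈ 4.05 for PM2.5, ≈ 44.1 for PM10). PM1 and the number bins are
plausible deterministic functions of the PM2.5 channel (they are carried but
never calibrated), and a final max-chain guarantees the record ordering
invariant — with the default schedule it can engage only at the lowest
plateau, where it perturbs interval means negligibly.

The smoothing time constant defaults to 0.5 min. A pure delay plus
first-order smoothing is the simplest response model reproducing a
measurable integer-minute lag, but the net correlation lag is the delay
plus roughly the smoothing centroid (≈ τ): a large τ would both shift the
recovered lag off the configured delay and erode plateau steadiness after
each ramp. At τ = 0.5 min the settling transient dies within ~1–2 min of a
ramp's end, leaving most of each 10-min plateau steady, and the
correlation-argmax lag equals the configured 4-min delay.

The 5-s noise CV (5%) is this package's choice — the underlying study does
not report a within-unit noise magnitude at that scale. A 5-min interval
mean then carries ≈ 0.65% relative noise per unit, which keeps calibration
r² near 1 and leaves the pooled inter-unit CV (≈ 10%) dominated by the real
between-unit sensitivity spread, comfortably inside the < 15% precision
bound the study reports.

**Trial** (`TrialConfig`): for horse h, treatment t and metric, the window
means follow `log m₂₀ = log M₂₀(t) + b_h + e₁`, `log m₈ = log M₈(t) + b_h +
e₂` with a horse effect `b_h ~ N(0, 0.35²)` drawn once per horse (the
cross-over's repeated-measures structure) and window residuals
`e ~ N(0, 0.25²)`. The default group geometric means are the study's
printed values — PM2.5 160/53 (20-min dry/soaked) and 76/31 (8-h); PM10
2829/970 and 1581/488 μg/m³. The true 5-s exposure profile is piecewise
two-level: `L₁ = m₂₀` for the first 20 min, then
`L₂ = (480·m₈ − 20·m₂₀)/460` (floored at 0.5 μg/m³ with a warning), which
hits both window means exactly. Only the two analysed windows are targets,
so this two-level profile is preferred to a mechanistic eating model. The
horse effect and window residuals are shared between PM2.5 and PM10 — one
horse-day's air drives both fractions — which also guarantees
`pm2_5 ≤ pm10` on the raw records; only the 5-s sensor noise is independent
per channel. Logs are emitted in RAW sensor units by inverting the universal
calibration, so the analysis pipeline must apply the calibration to recover
truth. Between-horse SD 0.35 and residual SD 0.25 (log scale, GSDs ≈ 1.42
and 1.28) are typical of repeated personal dust measurements and give the
10-horse design high power for two-fold contrasts while keeping replicate
scatter visible.

What the generators do **not** emulate: hay-agitation physics, chamber
airflow, temperature/RH dynamics (constants within the reported ranges),
diurnal or behavioural exposure structure beyond the two-level profile, and
any aerosol-composition dependence of sensor response. Passing tests
therefore demonstrate that the pipeline recovers the generating model's
truths — not that a particular field deployment meets them.

## Numerical conventions and edge cases

* CV uses the sample SD (n − 1) throughout.
* Lag ties break toward the smaller lag (parsimony); the lag search
  requires ≥ 30 overlapping minutes at every candidate shift.
* `fit_ols` refuses constant predictors (< 3 points or zero spread).
* Pairwise correlation with a constant unit is undefined and reported NaN.
* Window means of exactly 0 enter the log models as 0.1 μg/m³ (logged).
* Generators are reproducible from an integer seed via independent spawned
  streams; identical seeds give bit-identical outputs.

## Problem sizes

The default chamber run is 9 plateaus (114 min), yielding ~12 matched 5-min
intervals per fraction — the same order as the study's 29/31. The
acceptance script averages the trial recovery over 200 seeded replicates of
the full 10-horse cross-over (raw logs → calibration → windows → models);
the test suite uses 30 replicates for the same check and 500 direct
Monte-Carlo replicates of the generative lognormal model for the type-I
error calibration of the treatment test.

## Known limitations

* The mixed-model df formulas assume the balanced complete cross-over; the
  package enforces balance by excluding incomplete horses rather than
  supporting general unbalanced designs.
* Sub-minute lags and deconvolution of the reference response are out of
  scope; the lag is an integer number of minutes.
* Temperature/RH are carried in the records but deliberately excluded from
  the calibration regressions; PM1 is never calibrated (the raw channel's
  bias is unknown) and is reported raw only inside the record frame.
* The steady-interval subdivision (disjoint 5-min blocks from each run
  start) is one defensible convention; printed segment counts from studies
  using another subdivision are not expected to match exactly.
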