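# Methods

## Design

The analysis estimates the non-linear and delayed (distributed-lag)
association between daily temperature and daily cardiovascular death counts.
Counts are modelled as overdispersed Poisson,

    Y_t ~ Poisson(mu_t),   Var(Y_t) = phi * mu_t
    log mu_t = alpha + beta' T_{t,l} + lambda_strata(t) + eta_dow(t),

with the time-stratified case-crossover realized as fixed-effect indicator
columns for year x calendar month strata (reference: first stratum) plus
day-of-week indicators (reference: Monday).  Within a one-month stratum every
death day is compared against the other days of the same month, which removes
seasonal and long-term confounding by design; the exposure history of a day
is allowed to reach back into the previous stratum, as is standard for DLNMs
embedded in case-crossover designs.  An alternative time-series design
replaces the strata with a natural cubic spline over calendar time at 7 df
per year of data.

Estimation is by iteratively reweighted least squares (statsmodels GLM,
Poisson family, deviance tolerance 1e-8, at most 100 iterations).  The
Poisson likelihood treats zero-count days as data.  Strata whose total count
is zero are dropped with a warning (their stratum effect is unbounded below).
Overdispersion is the Pearson statistic divided by the residual degrees of
freedom — the dominant quasi-Poisson convention — and multiplies the inverse
Fisher information to give the coefficient covariance, so Wald intervals
widen by sqrt(phi) exactly.

## Cross-basis

The exposure-lag-response surface is the tensor product of two marginal
bases, collapsed over the lag window 0..L (L = 10 by default):

    T_{t,(i,j)} = sum_l B_i(x_{t-l}) C_j(l).

* **Temperature**: quadratic B-spline, `var_df` = 4 columns, no intercept
  (risk is always a contrast against the reference, and the count level is
  carried by the model intercept).  Boundary knots sit at the observed range;
  `var_df - 2` interior knots at evenly distributed percentiles (33.3/66.7
  for the default).  Evaluation outside the boundary extends the edge
  polynomial pieces rather than clipping — relevant when the integer grid
  value for the series maximum is predicted at the edge of knot coverage.
* **Lag**: natural cubic spline *with* intercept, `lag_df` = 4 columns,
  boundary knots at lag 0 and lag L, `lag_df - 2` interior knots.  The
  intercept is essential: without it every representable lag curve vanishes
  at the left boundary and no effect on the day of exposure could be
  expressed, contradicting the phenomenon being modelled (the risk peak at
  lag 0).  Interior knots are evenly spaced on the log(1 + lag) scale by
  default (1.22 and 3.95 for L = 10), concentrating resolution at short lags
  where delayed heat effects change fastest; evenly spaced quantiles of 0..L
  are available via `lag_knot_spacing="linear"`, and the sensitivity suite
  can be run under either.  In simulation the log spacing roughly halves the
  attenuation of a pure lag-0 effect relative to linear spacing.

The natural spline basis is constructed as the *cardinal interpolation
basis*: column i is the natural cubic spline interpolating the indicator of
knot i.  This basis is uniquely defined by the knots (no QR/SVD convention
enters), spans exactly the natural-spline space, sums to one, and is checked
in the tests against an independent tridiagonal-solver implementation; the
B-spline bases are checked against a hand-written Cox-de Boor recursion.

The first L days of any series carry incomplete lag history and are masked
out of the likelihood (warm-up), as is any day whose lag window touches a
missing exposure value.  With the defaults the cross-basis contributes
k_cb = 4 x 4 = 16 parameters.

## Model selection

`select_df` fits every (var_df, lag_df) pair on a grid (default {4,5,6}^2)
and minimizes QAIC = -2L + 2 phi k, reporting QBIC = -2L + ln(n) phi k
alongside; when the two disagree QAIC decides and the disagreement is
logged.  L is the Poisson log-likelihood at the estimate, k counts all
parameters (intercept, cross-basis, strata, day-of-week), n counts the
observations actually entering the fit (warm-up excluded).

## Risk prediction

For temperature x and lag l the log relative risk against reference `ref`
(the series median) is the contrast `[b(x) - b(ref)]' C_l beta`, with
variance from the same contrast vector and the phi-scaled covariance of
beta; bounds are exponentiated log-scale Wald bounds at the 95% level (the
normal quantile is computed, not hard-coded).  At x = ref the contrast is
identically zero, so RR = 1 with a degenerate interval — an exact identity
used as a test.  Cumulative risk sums the log RR over lags 0..L via the
summed contrast vector.  Surfaces are evaluated on a 0.1 degC grid plus the
integer evaluation temperatures (percentiles rounded up, maximum rounded
down); slices are extracted at the p90/p95/p99/max grid values (lag
profiles) and at lags 0, 1, 2, 4 (temperature profiles).

## Exposure aggregation

Station records are combined per day as a weighted mean with weights
proportional to the population each station represents, renormalized over
the stations reporting that day (no imputation); days with no report are
missing and mask the affected cross-basis rows.  Percentiles use linear
interpolation between order statistics (type 7); the median of an even-length
series is the mean of the central pair.  Age structure is ignored in the
weighting, matching the data situation the design targets.

## Synthetic data generator

The generator emulates a subtropical island climate observed by a station
network, and cause-specific daily deaths at the study's scale, with the full
truth retained for recovery tests.

* **Calendar**: `n_years` x 365 consecutive days (no special leap-day
  handling), 7 years by default.
* **Climate**: station t_mean = annual mean (20 degC) + seasonal sinusoid
  (amplitude 8.5 degC, peak mid-July) + a *shared* regional daily deviation
  (sd 1.5 degC — synoptic weather is spatially coherent at island scale, so
  it must survive cross-station averaging) + independent station noise
  (sd 0.75 degC) + a persistent station altitude offset (sd 1.5 degC).
  t_max/t_min add/subtract a non-negative excursion (mean 6 degC, sd 1), so
  the ordering t_min <= t_mean <= t_max always holds.  These values put the
  population-weighted summer (JJA) mean near 27.5 degC — inside the 22-29
  degC band characteristic of the region — and the series median near the
  study's printed 20.0 degC reference.  34 stations, equal weights by
  default.
* **Mortality**: log mu_t stacks log(baseline) with baseline 13889/2557 ~
  5.43 deaths/day (the study's printed total over its day count), a
  winter-peaking seasonal confounder (log-amplitude 0.15), day-of-week
  offsets (order 1-3%, free parameters — the study reports no within-week
  structure), and the injected surface summed over the lag window.  Counts
  are Poisson at overdispersion 1, otherwise gamma-mixed Poisson (negative
  binomial) with variance phi * mu, phi = 1.2 by default; the gamma
  multiplier is shared across the five ICD-10 categories, which are drawn as
  independent Poissons at rates mu_t x category share (shares from the
  printed per-category counts), so the aggregate equals the category sum by
  construction and inherits mu_t and phi.
* **Truth surface**: `f(x, l) = c_l * shape(x)` with shape zero at the
  reference for every form (linear, threshold-linear, or quadratic above the
  reference).  The default is threshold-linear above 20 degC with
  coefficients 0.030/0.018/0.006 at lags 0/1/2 and zero beyond — a heat
  effect concentrated on the event day and the day after, of realistic size
  (RR ~ 1.3 at the 95th percentile).
* The first L days of counts are generated with truncated lag history and
  flagged so the fit can exclude them, mirroring the warm-up masking.

What the generator does **not** emulate: spatial climate fields or station
outages, humidity, heat waves as autocorrelated extreme spells beyond the
AR-free daily noise, age structure, harvesting feedback (the truth surface is
static — no depletion of the at-risk pool), and calendar irregularities.
Passing recovery tests therefore demonstrate correctness of the estimation
machinery under the stated data-generating assumptions, not robustness to
every feature of real registry data.

## Numerical choices and edge cases

* IRLS convergence: deviance tolerance 1e-8, 100 iterations, hard error with
  the deviance trace on failure.
* Rank deficiency is detected before fitting and reported with the offending
  column names (greedy elimination).
* Pearson dispersion is floored at 1e-12 so degenerate perfectly-fitted toy
  data keep a defined covariance.
* Fixed stratum windows shorter than 7 days are rejected as degenerate; the
  final window of a fixed-window scheme may be shorter than requested.
* Duplicate (station, date) rows and physically inconsistent rows
  (t_min > t_mean or t_mean > t_max) are rejected / dropped with a warning at
  ingestion; an empty mortality table is a hard error.
* All randomness flows through numpy SeedSequence spawns of one seed; rerunning
  a study with the same config and seed is byte-identical.

## Sensitivity analysis

One factor at a time against the base configuration (max lag 10, calendar-
month strata): maximum lag in {5, 15, 20} and fixed stratum windows of
{30, 28, 21} days (a full cross is available behind a flag).  The report
tabulates RR with 95% CI at the p90/p95/p99 integer grid temperatures, at lag
0 and cumulated over lags, the delta against the base run, and whether a
variant's point estimate leaves the base interval.

## Problem sizes used in validation

Study-scale checks run 7 x 365 days at ~5.4 deaths/day.  The validation suite
uses 50 replicates for recovery of an injected lag-0 effect (the 95% interval
at the 95th percentile covers truth in >= 90% of replicates), 200 replicates
for null calibration (coverage 95% +/- 3%), and 9 replicates for the
sensitivity robustness check; the acceptance script reports a 100-replicate
null calibration.  These sizes give Monte-Carlo error comfortably inside the
asserted bands while keeping the suite quick on one CPU.

## Known limitations

* The case-crossover is fitted by unconditional quasi-Poisson with stratum
  indicators (the textbook formulation of the time-stratified design), not by
  conditional logistic likelihood.
* No penalized splines, no autocorrelation correction, no random effects.
* Attributable fractions and minimum-mortality temperature are out of scope.
* A sharp single-lag effect is not exactly representable by a 4-df smooth lag
  basis; the fitted lag-0 risk is mildly attenuated (log-scale bias ~ -0.05
  under the default log knot spacing in simulation).  This is inherent to
  DLNM smoothing, and is why the lag knots default to log spacing.
* The observed-minimum temperature series in real data carries a one-day
  reporting delay (the 24-h observation window convention); the analysis
  consumes whatever daily series it is given and does not shift it.
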