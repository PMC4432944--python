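# heatlag

Distributed-lag non-linear modelling (DLNM) of daily temperature and
cardiovascular mortality in a **time-stratified case-crossover design**, with
synthetic data generation for validation against known ground truth.

The package is aimed at environmental epidemiologists studying how heat
affects death counts: how large is the relative risk at high temperatures,
how many days does the effect persist, and is there mortality displacement
("harvesting") at intermediate lags?

## The model

Daily deaths are overdispersed Poisson counts,

```
Y_t ~ Poisson(mu_t),        Var(Y_t) = phi * mu_t
log(mu_t) = alpha + beta' T_{t,l} + lambda_strata(t) + eta_dow(t)
```

where `T_{t,l}` is the **cross-basis** row for day *t*: the tensor product of
a quadratic B-spline over temperature (4 df, interior knots at evenly
distributed percentiles) and a natural cubic spline over lag (4 df, boundary
knots at lag 0 and lag 10, interior knots evenly spaced on the log-lag
scale), collapsed over the exposure history:

```
T_{t,(i,j)} = sum_{l=0..10}  B_i(x_{t-l}) * C_j(l)
```

`strata(t)` are year-by-calendar-month indicator terms — the time-stratified
case-crossover device that removes seasonal and long-term confounding by
design — and `dow(t)` are day-of-week indicators.  Overdispersion `phi` is
the Pearson statistic over residual degrees of freedom and scales the
coefficient covariance.  Spline degrees of freedom are selected with
quasi-likelihood criteria

```
QAIC = -2L + 2*phi*k          QBIC = -2L + ln(n)*phi*k
```

All risks are reported relative to the reference temperature (the series
median): `RR(x, l) = exp([b(x) - b(ref)]' C_l beta)` with Wald 95% intervals,
plus the cumulative risk summed over lags 0–10.

Multi-station temperature records are collapsed to one daily series by
population-weighted spatial averaging before modelling; the evaluation grid
uses the 90th/95th/99th percentiles rounded up and the series maximum rounded
down to stay inside the recorded range.

## Worked example

```python
import numpy as np
from heatlag import (CaseCrossoverDLNM, SyntheticConfig,
                     simulate_station_temperatures, simulate_mortality,
                     weighted_spatial_average, summarize_temperature)

cfg = SyntheticConfig(seed=7)              # 7 years, ~13,900 deaths, 34 stations
stations = simulate_station_temperatures(cfg)
exposure = weighted_spatial_average(stations, cfg.weights(), "mean")
mortality, truth = simulate_mortality(exposure, cfg)
summary = summarize_temperature(exposure)

model = CaseCrossoverDLNM().fit(exposure, mortality.aggregate)
surface = model.predict_rr([summary.p95], reference=summary.reference)
rr, lo, hi = surface.at(summary.p95, 0)
```

This prints (via the obvious `print` statements):

```
reference=19.5  p90=27.7  p95=28.7  p99=30.1  max=32.9
total deaths: 15910
n=2545  k=106  dispersion=1.172
QAIC=12301.1  QBIC=13027.1
RR at p95 (28.7 degC), lag 0: 1.282 (95% CI 1.121-1.467)
injected truth at that temperature, lag 0: 1.297
cumulative RR over lags 0-10: 1.374 (95% CI 1.103-1.712)
```

Reading the numbers: the synthetic truth injects a 3%-per-degC log-linear
heat effect above 20 degC at lag 0 (so RR 1.297 at 28.7 degC); the fitted
case-crossover DLNM, using n = 2555 − 10 warm-up days and k = 106 parameters
(16 cross-basis + 84 strata + 6 day-of-week, minus references, plus
intercept), recovers RR 1.282 with a 95% interval covering the truth, and
estimates the overdispersion near the generator's 1.2.

## Command line

```
heatlag generate  --seed 7 --out data/            # synthetic input tables
heatlag aggregate --stations data/stations.csv --weights data/weights.csv \
                  --metric mean --out data/exposure.csv
heatlag fit       --exposure data/exposure.csv --mortality data/mortality.csv \
                  --out data/fit.json
heatlag predict   --fit data/fit.json --reference 20 --temperatures 25,28,31 \
                  --out data/rr.csv
heatlag run-all   --config config.yaml            # full study + sensitivity
```

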