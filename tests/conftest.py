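import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from heatlag import (CrossBasisSpec, ExposureSeries, SyntheticConfig,
                     build_crossbasis, fit_quasipoisson, make_strata,
                     simulate_mortality, simulate_station_temperatures,
                     weighted_spatial_average)
from heatlag.synthetic import LogRRSurface

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


def exposure_from_values(values, start="2004-01-01", metric="mean") -> ExposureSeries:
    values = np.asarray(values, dtype=float)
    idx = pd.date_range(start, periods=len(values), freq="D")
    return ExposureSeries(metric=metric, values=pd.Series(values, index=idx))


def small_config(seed, **kw) -> SyntheticConfig:
    """Two-year generator config used for fast fitting tests."""
    defaults = dict(n_years=2, n_stations=4, baseline_daily_deaths=8.0,
                    overdispersion=1.0, seed=seed)
    defaults.update(kw)
    return SyntheticConfig(**defaults)


def simulate_exposure(config) -> ExposureSeries:
    stations = simulate_station_temperatures(config)
    return weighted_spatial_average(stations, config.weights(), "mean")


@pytest.fixture(scope="session")
def study_run():
    """One study-scale realization (7 years, default truth) plus its fit."""
    cfg = SyntheticConfig(seed=20)
    exposure = simulate_exposure(cfg)
    mortality, truth = simulate_mortality(exposure, cfg)
    cb = build_crossbasis(exposure, CrossBasisSpec())
    strata = make_strata(mortality.dates, "calendar_month")
    fit = fit_quasipoisson(mortality.aggregate, cb, strata)
    return {"config": cfg, "exposure": exposure, "mortality": mortality,
            "truth": truth, "cb": cb, "strata": strata, "fit": fit}


@pytest.fixture(scope="session")
def toy_fit():
    """Small 120-day fit with 16 cross-basis columns for exact identities."""
    cfg = small_config(7, n_years=1)
    exposure = simulate_exposure(cfg)
    exposure = ExposureSeries("mean", exposure.values.iloc[:120])
    mortality, _ = simulate_mortality(exposure, cfg)
    cb = build_crossbasis(exposure, CrossBasisSpec())
    strata = make_strata(exposure.dates, "calendar_month")
    fit = fit_quasipoisson(mortality.aggregate.iloc[:120], cb, strata)
    return {"exposure": exposure, "cb": cb, "fit": fit}


def null_surface_config(seed, **kw) -> SyntheticConfig:
    base = dict(true_surface=LogRRSurface.null(), seed=seed)
    base.update(kw)
    return SyntheticConfig(**base)
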