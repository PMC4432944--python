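import numpy as np
import pandas as pd
import pytest

from heatlag import (ExposureSeries, SyntheticConfig, simulate_mortality,
                     simulate_station_temperatures)
from heatlag.synthetic import LogRRSurface, synthetic_dates

from conftest import null_surface_config, simulate_exposure


class TestStationTemperatures:
    def test_degenerate_noise_gives_constant_field(self):
        cfg = SyntheticConfig(n_years=1, n_stations=3, climate_mean_annual=20.0,
                              climate_seasonal_amplitude=0.0,
                              climate_daily_noise_sd=0.0, station_offset_sd=0.0,
                              seed=1)
        st = simulate_station_temperatures(cfg)
        assert np.allclose(st["t_mean"], 20.0)

    def test_seed_determinism_bit_identical(self):
        cfg = SyntheticConfig(n_years=1, seed=42)
        a = simulate_station_temperatures(cfg)
        b = simulate_station_temperatures(SyntheticConfig(n_years=1, seed=42))
        pd.testing.assert_frame_equal(a, b)
        c = simulate_station_temperatures(SyntheticConfig(n_years=1, seed=43))
        assert not np.array_equal(a["t_mean"].to_numpy(), c["t_mean"].to_numpy())

    def test_summer_mean_in_subtropical_band(self):
        # long-run JJA mean of T_mean must land in the 22-29 degC band
        cfg = SyntheticConfig(n_years=10, n_stations=3,
                              climate_seasonal_amplitude=3.5,
                              climate_mean_annual=25.5,
                              climate_daily_noise_sd=1.0,
                              station_offset_sd=0.0, seed=7)
        st = simulate_station_temperatures(cfg)
        summer = st[pd.to_datetime(st["date"]).dt.month.isin([6, 7, 8])]
        assert 22.0 <= summer["t_mean"].mean() <= 29.0

    def test_default_climate_summer_band_and_median(self):
        exposure = simulate_exposure(SyntheticConfig(seed=3))
        jja = exposure.values[exposure.dates.month.isin([6, 7, 8])]
        assert 22.0 <= jja.mean() <= 29.0
        assert 18.5 <= float(np.median(exposure.dropna())) <= 21.5

    def test_temperature_ordering_always_holds(self):
        st = simulate_station_temperatures(SyntheticConfig(n_years=1, seed=9))
        assert (st["t_min"] <= st["t_mean"]).all()
        assert (st["t_mean"] <= st["t_max"]).all()

    def test_rejects_negative_noise_parameters(self):
        with pytest.raises(ValueError):
            SyntheticConfig(climate_daily_noise_sd=-1.0)
        with pytest.raises(ValueError):
            SyntheticConfig(climate_seasonal_amplitude=-0.1)

    def test_calendar_is_gap_free_365_day_years(self):
        dates = synthetic_dates(3)
        assert len(dates) == 3 * 365
        assert (np.diff(dates.to_numpy()).astype("timedelta64[D]")
                == np.timedelta64(1, "D")).all()


class TestSimulateMortality:
    def test_null_config_recovers_baseline_rate(self):
        # all-zero surface, flat seasonality and DOW: LLN on the daily mean
        cfg = null_surface_config(
            3, n_years=7, baseline_daily_deaths=5.4,
            dow_log_effects=(0.0,) * 7, seasonal_log_amplitude=0.0,
            overdispersion=1.0)
        exposure = simulate_exposure(cfg)
        mortality, truth = simulate_mortality(exposure, cfg)
        n = len(mortality.dates)
        se = np.sqrt(5.4 / n)
        assert abs(mortality.aggregate.mean() - 5.4) < 3 * se
        assert np.allclose(truth.mu, 5.4)

    def test_study_scale_total_matches_printed_total(self):
        # baseline 13889/2557 per day reproduces the study-scale death total
        from heatlag import study
        cfg = null_surface_config(11, dow_log_effects=(0.0,) * 7,
                                  seasonal_log_amplitude=0.0, overdispersion=1.0)
        exposure = simulate_exposure(cfg)
        mortality, _ = simulate_mortality(exposure, cfg)
        expected = study.BASELINE_DEATHS_PER_DAY * len(mortality.dates)
        assert abs(mortality.total() - expected) < 3 * np.sqrt(study.TOTAL_DEATHS)

    def test_equidispersed_pearson_statistic_near_one(self):
        cfg = null_surface_config(5, n_years=3, overdispersion=1.0)
        exposure = simulate_exposure(cfg)
        mortality, truth = simulate_mortality(exposure, cfg)
        z = (mortality.aggregate.to_numpy() - truth.mu.to_numpy()) / np.sqrt(truth.mu)
        assert abs(np.mean(z ** 2) - 1.0) < 0.12

    def test_overdispersed_variance_scales_with_phi(self):
        cfg = null_surface_config(15, n_years=7, overdispersion=2.0,
                                  dow_log_effects=(0.0,) * 7,
                                  seasonal_log_amplitude=0.0)
        exposure = simulate_exposure(cfg)
        mortality, truth = simulate_mortality(exposure, cfg)
        z2 = ((mortality.aggregate.to_numpy() - truth.mu.to_numpy()) ** 2
              / truth.mu.to_numpy())
        assert 1.6 < np.mean(z2) < 2.4

    def test_count_conservation_and_category_sum(self):
        cfg = SyntheticConfig(n_years=2, seed=8)
        exposure = simulate_exposure(cfg)
        mortality, truth = simulate_mortality(exposure, cfg)
        total_mu = truth.mu.sum()
        assert abs(mortality.total() - total_mu) < 4 * np.sqrt(total_mu)
        assert (mortality.aggregate == mortality.counts.sum(axis=1)).all()

    def test_null_surface_counts_independent_of_exposure(self):
        cfg = null_surface_config(21, n_years=7, seasonal_log_amplitude=0.0,
                                  dow_log_effects=(0.0,) * 7, overdispersion=1.0)
        exposure = simulate_exposure(cfg)
        mortality, _ = simulate_mortality(exposure, cfg)
        r = np.corrcoef(mortality.aggregate.to_numpy(),
                        exposure.values.to_numpy())[0, 1]
        assert abs(r) < 3.5 / np.sqrt(len(exposure))

    def test_warmup_flagging_and_short_exposure_error(self):
        cfg = SyntheticConfig(n_years=1, seed=2)
        exposure = simulate_exposure(cfg)
        _, truth = simulate_mortality(exposure, cfg)
        L = cfg.true_surface.max_lag
        assert truth.warmup.sum() == L and truth.warmup.iloc[:L].all()
        short = ExposureSeries("mean", exposure.values.iloc[:L])
        with pytest.raises(ValueError):
            simulate_mortality(short, cfg)

    def test_seed_determinism(self):
        cfg = SyntheticConfig(n_years=1, seed=33)
        exposure = simulate_exposure(cfg)
        a, _ = simulate_mortality(exposure, cfg)
        b, _ = simulate_mortality(exposure, SyntheticConfig(n_years=1, seed=33))
        pd.testing.assert_frame_equal(a.counts, b.counts)


class TestLogRRSurface:
    @pytest.mark.parametrize("form", ["linear", "threshold_linear",
                                      "quadratic_above_reference"])
    def test_zero_at_reference_every_lag(self, form):
        surf = LogRRSurface(form, 20.0, np.linspace(0.05, 0.0, 11))
        for lag in range(11):
            assert surf.log_rr(20.0, lag) == 0.0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SyntheticConfig(overdispersion=0.5)
        with pytest.raises(ValueError):
            SyntheticConfig(station_weights=(1.0,), n_stations=2)
        with pytest.raises(ValueError):
            SyntheticConfig(dow_log_effects=(0.0,) * 6)
        with pytest.raises(ValueError):
            LogRRSurface("cubic", 20.0, np.zeros(3))
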