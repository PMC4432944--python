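import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from heatlag import (CaseCrossoverDLNM, CrossBasisSpec, build_crossbasis,
                     fit_quasipoisson, fit_timeseries_alternative,
                     information_criteria, make_strata, quasi_criteria,
                     select_df, simulate_mortality)
from heatlag.model import _assemble_design
from heatlag.synthetic import LogRRSurface, synthetic_dates

from conftest import exposure_from_values, simulate_exposure, small_config
from oracles import poisson_negloglike


class TestMakeStrata:
    def test_single_month(self):
        dates = pd.date_range("2004-01-01", "2004-01-31", freq="D")
        s = make_strata(dates, "calendar_month")
        assert s.n_strata() == 1 and set(s.labels) == {"2004-01"}

    def test_seven_years_have_84_monthly_strata(self):
        s = make_strata(synthetic_dates(7), "calendar_month")
        assert s.n_strata() == 84

    def test_fixed_window_boundary(self):
        dates = pd.date_range("2004-01-01", periods=60, freq="D")
        s = make_strata(dates, "fixed_window:28")
        assert s.labels.iloc[27] != s.labels.iloc[28]  # day 28 vs day 29
        assert s.labels.iloc[0] == s.labels.iloc[27]

    def test_short_window_rejected(self):
        dates = pd.date_range("2004-01-01", periods=30, freq="D")
        with pytest.raises(ValueError):
            make_strata(dates, "fixed_window:6")


class TestFitQuasipoisson:
    def test_intercept_only_closed_form(self):
        dates = pd.date_range("2004-01-01", periods=90, freq="D")
        y = pd.Series(7, index=dates)
        strata = make_strata(dates, "calendar_month")
        fit = fit_quasipoisson(y, None, strata, dow_terms=False)
        assert fit.params["intercept"] == pytest.approx(np.log(7.0), abs=1e-8)

    def test_matches_generic_likelihood_maximizer(self):
        # 60 days, 2 monthly strata, 4 cross-basis columns
        rng = np.random.default_rng(17)
        exposure = exposure_from_values(rng.uniform(5, 35, 60))
        spec = CrossBasisSpec(max_lag=3, var_df=2, var_degree=1, lag_df=2)
        cb = build_crossbasis(exposure, spec)
        y = pd.Series(rng.poisson(6.0, 60), index=exposure.dates)
        strata = make_strata(exposure.dates, "calendar_month")
        fit = fit_quasipoisson(y, cb, strata, dow_terms=False)

        keep = cb.valid
        X = _assemble_design(exposure.dates[keep], cb.matrix[keep],
                             cb.column_names, strata.labels[keep],
                             dow_terms=False).to_numpy(dtype=float)
        res = minimize(poisson_negloglike, np.zeros(X.shape[1]),
                       args=(X, y[keep].to_numpy(dtype=float)),
                       method="BFGS", options={"gtol": 1e-10, "maxiter": 500})
        assert np.allclose(fit.params.to_numpy(), res.x, atol=1e-6)

    def test_score_equations_vanish_at_optimum(self):
        rng = np.random.default_rng(23)
        exposure = exposure_from_values(rng.uniform(5, 35, 90))
        cb = build_crossbasis(exposure, CrossBasisSpec(max_lag=5, lag_df=3))
        y = pd.Series(rng.poisson(5.0, 90), index=exposure.dates)
        strata = make_strata(exposure.dates, "calendar_month")
        fit = fit_quasipoisson(y, cb, strata)
        keep = cb.valid
        X = _assemble_design(exposure.dates[keep], cb.matrix[keep],
                             cb.column_names, strata.labels[keep],
                             dow_terms=True).to_numpy(dtype=float)
        mu = np.exp(X @ fit.params.to_numpy())
        assert np.abs(X.T @ (y[keep].to_numpy() - mu)).max() < 1e-6

    def test_beta_invariant_to_per_stratum_rate_shifts(self):
        # deterministic expected counts in the model span: MLE is exact, and
        # a per-stratum multiplier is absorbed entirely by the strata terms
        rng = np.random.default_rng(31)
        exposure = exposure_from_values(rng.uniform(5, 35, 120))
        cb = build_crossbasis(exposure, CrossBasisSpec(max_lag=5, lag_df=3))
        strata = make_strata(exposure.dates, "calendar_month")
        keep = cb.valid
        X = _assemble_design(exposure.dates[keep], cb.matrix[keep],
                             cb.column_names, strata.labels[keep],
                             dow_terms=False)
        theta = rng.normal(0, 0.05, X.shape[1])
        theta[0] = np.log(8.0)
        mu = pd.Series(np.exp(X.to_numpy() @ theta), index=exposure.dates[keep])
        mu_full = mu.reindex(exposure.dates, fill_value=1.0)
        fit1 = fit_quasipoisson(mu_full, cb, strata, dow_terms=False)
        shift = strata.labels.map(
            {lab: 0.4 * i for i, lab in enumerate(strata.labels.unique())})
        fit2 = fit_quasipoisson(mu_full * np.exp(shift), cb, strata, dow_terms=False)
        assert np.allclose(fit1.params[fit1.cb_names], theta[1:1 + len(fit1.cb_names)],
                           atol=1e-6)
        assert np.allclose(fit1.params[fit1.cb_names], fit2.params[fit2.cb_names],
                           atol=1e-6)

    def test_dispersion_calibrated_on_equidispersed_counts(self):
        cfg = small_config(41, n_years=6, baseline_daily_deaths=10.0,
                          true_surface=LogRRSurface.null())
        exposure = simulate_exposure(cfg)
        mortality, _ = simulate_mortality(exposure, cfg)
        cb = build_crossbasis(exposure, CrossBasisSpec())
        strata = make_strata(exposure.dates, "calendar_month")
        fit = fit_quasipoisson(mortality.aggregate, cb, strata)
        assert 0.9 <= fit.dispersion <= 1.1
        assert fit.n == len(exposure) - 10  # warm-up rows excluded

    def test_covariance_is_dispersion_times_fisher_inverse(self, toy_fit):
        fit = toy_fit["fit"]
        cb = toy_fit["cb"]
        exposure = toy_fit["exposure"]
        keep = cb.valid
        strata = make_strata(exposure.dates, "calendar_month")
        X = _assemble_design(exposure.dates[keep], cb.matrix[keep],
                             cb.column_names, strata.labels[keep],
                             dow_terms=True).to_numpy(dtype=float)
        mu = np.exp(X @ fit.params.to_numpy())
        fisher_inv = np.linalg.inv(X.T @ (X * mu[:, None]))
        # IRLS weights lag the final coefficients by one update, so agreement
        # is to ~1e-4 relative rather than machine precision
        assert np.allclose(fit.cov.to_numpy(), fit.dispersion * fisher_inv,
                           rtol=1e-3, atol=1e-8)

    def test_zero_count_strata_dropped_with_warning(self):
        dates = pd.date_range("2004-01-01", periods=62, freq="D")
        y = pd.Series([5] * 31 + [0] * 31, index=dates)
        strata = make_strata(dates, "calendar_month")
        with pytest.warns(UserWarning, match="zero total count"):
            fit = fit_quasipoisson(y, None, strata, dow_terms=False)
        assert fit.n == 31

    def test_rank_deficiency_reported_with_column_names(self):
        rng = np.random.default_rng(3)
        exposure = exposure_from_values(np.full(40, 20.0))  # constant exposure
        spec = CrossBasisSpec(max_lag=3, var_df=3, lag_df=2,
                              var_knots=(20.0,), var_boundary=(10.0, 30.0))
        cb = build_crossbasis(exposure, spec)
        y = pd.Series(rng.poisson(5.0, 40), index=exposure.dates)
        strata = make_strata(exposure.dates, "calendar_month")
        with pytest.raises(ValueError, match="collinear"):
            fit_quasipoisson(y, cb, strata)


class TestInformationCriteria:
    def test_dispersion_one_reduces_to_aic(self):
        qaic, _ = quasi_criteria(-50.0, 1.0, 12, 300)
        assert qaic == pytest.approx(-2 * -50.0 + 2 * 12)

    def test_hand_arithmetic(self):
        qaic, qbic = quasi_criteria(-100.0, 1.5, 16, 2557)
        assert qaic == pytest.approx(248.0)
        assert qbic == pytest.approx(200.0 + np.log(2557) * 1.5 * 16)

    def test_qbic_exceeds_qaic_beyond_n_e_squared(self):
        qaic, qbic = quasi_criteria(-10.0, 1.2, 4, 8)
        assert qbic > qaic
        qaic, qbic = quasi_criteria(-10.0, 1.2, 4, 7)
        assert qbic < qaic

    def test_fit_consistency(self, toy_fit):
        fit = toy_fit["fit"]
        qaic, qbic = information_criteria(fit)
        assert qaic == pytest.approx(-2 * fit.loglike + 2 * fit.dispersion * fit.k)
        assert qbic == pytest.approx(-2 * fit.loglike
                                     + np.log(fit.n) * fit.dispersion * fit.k)


class TestSelectDf:
    def test_single_element_grid(self):
        cfg = small_config(19, n_years=1)
        exposure = simulate_exposure(cfg)
        mortality, _ = simulate_mortality(exposure, cfg)
        strata = make_strata(exposure.dates, "calendar_month")
        best, table = select_df(mortality.aggregate, exposure, strata,
                                var_df_grid=(4,), lag_df_grid=(4,))
        assert (best.var_df, best.lag_df) == (4, 4)
        assert len(table) == 1

    def test_full_grid_reports_nine_rows(self):
        cfg = small_config(29, n_years=2, baseline_daily_deaths=10.0)
        exposure = simulate_exposure(cfg)
        mortality, _ = simulate_mortality(exposure, cfg)
        strata = make_strata(exposure.dates, "calendar_month")
        best, table = select_df(mortality.aggregate, exposure, strata)
        assert len(table) == 9
        assert {"qaic", "qbic"} <= set(table.columns)
        row = table.loc[table["qaic"].idxmin()]
        assert (best.var_df, best.lag_df) == (row["var_df"], row["lag_df"])

    def test_selection_favours_true_df_in_majority_of_replicates(self):
        # data generated from a 4x4 cross-basis surface: the 4x4 model should
        # win the QAIC comparison against richer alternatives most of the time
        wins = 0
        n_rep = 10
        for rep in range(n_rep):
            cfg = small_config(100 + rep, n_years=3, baseline_daily_deaths=12.0)
            exposure = simulate_exposure(cfg)
            spec = CrossBasisSpec().resolve(exposure.values.to_numpy())
            cb = build_crossbasis(exposure, spec)
            rng = np.random.default_rng(200 + rep)
            beta = rng.normal(0.0, 0.02, 16)
            lin = np.where(cb.valid, cb.matrix @ beta, 0.0)
            mu = 12.0 * np.exp(lin - lin[cb.valid].mean())
            y = pd.Series(rng.poisson(mu), index=exposure.dates)
            strata = make_strata(exposure.dates, "calendar_month")
            best, _ = select_df(y, exposure, strata,
                                var_df_grid=(4, 6), lag_df_grid=(4, 6))
            wins += (best.var_df, best.lag_df) == (4, 4)
        assert wins > n_rep / 2


class TestTimeSeriesAlternative:
    def test_one_year_gives_seven_time_columns(self):
        cfg = small_config(53, n_years=1)
        exposure = simulate_exposure(cfg)
        mortality, _ = simulate_mortality(exposure, cfg)
        cb = build_crossbasis(exposure, CrossBasisSpec())
        fit = fit_timeseries_alternative(mortality.aggregate, cb)
        time_cols = [c for c in fit.params.index if c.startswith("time_ns")]
        assert len(time_cols) == 7
        assert fit.design == "time_series"

    def test_cross_design_concordance_at_p95(self):
        # smooth seasonality: the two designs should give overlapping CIs
        from heatlag import predict_rr, summarize_temperature
        cfg = small_config(61, n_years=4, baseline_daily_deaths=10.0)
        exposure = simulate_exposure(cfg)
        mortality, _ = simulate_mortality(exposure, cfg)
        cb = build_crossbasis(exposure, CrossBasisSpec())
        summary = summarize_temperature(exposure)
        strata = make_strata(exposure.dates, "calendar_month")
        f_cc = fit_quasipoisson(mortality.aggregate, cb, strata)
        f_ts = fit_timeseries_alternative(mortality.aggregate, cb)
        s_cc = predict_rr(f_cc, cb.spec, [summary.p95], summary.reference)
        s_ts = predict_rr(f_ts, cb.spec, [summary.p95], summary.reference)
        assert s_cc.lower[0, 0] <= s_ts.upper[0, 0]
        assert s_ts.lower[0, 0] <= s_cc.upper[0, 0]


class TestEstimator:
    def test_sklearn_style_params_and_fitted_attributes(self):
        cfg = small_config(71, n_years=1)
        exposure = simulate_exposure(cfg)
        mortality, _ = simulate_mortality(exposure, cfg)
        est = CaseCrossoverDLNM(max_lag=5, lag_df=3)
        assert est.get_params()["max_lag"] == 5
        est.set_params(max_lag=10, lag_df=4)
        est.fit(exposure, mortality.aggregate)
        assert est.coef_.shape == (16,)
        assert est.dispersion_ > 0
        assert est.qaic_ == est.result_.qaic
        surface = est.predict_rr([est.reference_])
        assert surface.rr[0, 0] == pytest.approx(1.0)

    def test_unfitted_estimator_raises(self):
        with pytest.raises(RuntimeError):
            CaseCrossoverDLNM().predict_rr([20.0])
        with pytest.raises(ValueError):
            CaseCrossoverDLNM().set_params(bogus=1)
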