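"""Quasi-Poisson regression with case-crossover strata.

The time-stratified case-crossover design is realized, as is standard, as an
overdispersed Poisson regression of daily counts on the cross-basis with
fixed-effect indicator terms for the stratum (year x calendar month by
default) and the day of the week:

    log mu_t = alpha + beta' * crossbasis_t + lambda_strata(t) + eta_dow(t)

Overdispersion is estimated by the Pearson statistic divided by the residual
degrees of freedom, the coefficient covariance is scaled by it, and model
selection over spline degrees of freedom uses the quasi-likelihood criteria

    QAIC = -2 L + 2 phi k        QBIC = -2 L + ln(n) phi k

with L the Poisson log-likelihood at the estimate, k the number of parameters
and n the number of observations entering the fit (warm-up days with
incomplete lag history are excluded).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln

from .crossbasis import CrossBasisMatrix, CrossBasisSpec, build_crossbasis
from .exposure import ExposureSeries
from .splines import natural_cubic_basis

__all__ = [
    "StrataAssignment", "FitResult", "make_strata", "fit_quasipoisson",
    "information_criteria", "quasi_criteria", "select_df",
    "fit_timeseries_alternative", "CaseCrossoverDLNM",
]


def quasi_criteria(loglike: float, dispersion: float, k: int, n: int) -> tuple[float, float]:
    """QAIC = -2L + 2*phi*k and QBIC = -2L + ln(n)*phi*k.

    With dispersion 1 QAIC reduces to the ordinary AIC.
    """
    if n < 1 or k < 1 or dispersion <= 0:
        raise ValueError("need n >= 1, k >= 1, dispersion > 0")
    qaic = -2.0 * loglike + 2.0 * dispersion * k
    qbic = -2.0 * loglike + np.log(n) * dispersion * k
    return qaic, qbic

logger = logging.getLogger(__name__)

_DOW_NAMES = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


@dataclass
class StrataAssignment:
    """Mapping date -> stratum label for the case-crossover design."""

    scheme: str
    labels: pd.Series  # index: dates; values: stratum label strings

    def n_strata(self) -> int:
        return self.labels.nunique()


def make_strata(dates: pd.DatetimeIndex, scheme: str = "calendar_month") -> StrataAssignment:
    """Assign each date to a stratum.

    ``calendar_month`` labels by year and month; ``fixed_window:w`` cuts
    consecutive w-day windows anchored at the first date (the final window may
    be shorter).  Windows shorter than 7 days are rejected as degenerate.
    """
    if not isinstance(dates, pd.DatetimeIndex):
        dates = pd.DatetimeIndex(dates)
    if scheme == "calendar_month":
        labels = pd.Series(dates.strftime("%Y-%m"), index=dates)
    elif scheme.startswith("fixed_window:"):
        w = int(scheme.split(":", 1)[1])
        if w < 7:
            raise ValueError("fixed window shorter than 7 days is degenerate")
        idx = ((dates - dates[0]).days // w).astype(int)
        labels = pd.Series([f"w{i:04d}" for i in idx], index=dates)
    else:
        raise ValueError(f"unknown strata scheme {scheme!r}")
    return StrataAssignment(scheme=scheme, labels=labels)


@dataclass
class FitResult:
    """Everything the downstream risk prediction needs from one fit."""

    params: pd.Series               # all coefficients, named
    cov: pd.DataFrame               # phi-scaled covariance, same names
    dispersion: float               # Pearson phi-hat
    loglike: float                  # Poisson log-likelihood at the estimate
    k: int                          # number of parameters
    n: int                          # observations used
    qaic: float
    qbic: float
    converged: bool
    spec: CrossBasisSpec | None = None
    design: str = "case_crossover"
    meta: dict = field(default_factory=dict)

    @property
    def cb_names(self) -> list[str]:
        return [c for c in self.params.index if c.startswith("cb_")]

    @property
    def beta(self) -> np.ndarray:
        return self.params[self.cb_names].to_numpy()

    @property
    def beta_cov(self) -> np.ndarray:
        return self.cov.loc[self.cb_names, self.cb_names].to_numpy()


def _poisson_loglike(y: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify offending columns by greedy QR-style elimination
        bad = []
        keep: list[int] = []
        for j in range(mat.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(mat[:, trial]) == len(trial):
                keep = trial
            else:
                bad.append(X.columns[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def _assemble_design(
    dates: pd.DatetimeIndex,
    cb: np.ndarray | None,
    cb_names: list[str] | None,
    strata_labels: pd.Series | None,
    dow_terms: bool,
    time_spline: np.ndarray | None = None,
) -> pd.DataFrame:
    parts = [pd.DataFrame({"intercept": np.ones(len(dates))}, index=dates)]
    if cb is not None:
        parts.append(pd.DataFrame(cb, index=dates, columns=cb_names))
    if strata_labels is not None:
        dummies = pd.get_dummies(strata_labels, prefix="stratum", dtype=float)
        dummies = dummies.iloc[:, 1:]  # reference: first stratum
        parts.append(dummies.set_axis(dates, axis=0))
    if time_spline is not None:
        names = [f"time_ns{j + 1}" for j in range(time_spline.shape[1])]
        parts.append(pd.DataFrame(time_spline, index=dates, columns=names))
    if dow_terms:
        dow = pd.Categorical(dates.dayofweek, categories=range(7))
        dummies = pd.get_dummies(dow, prefix="dow", dtype=float)
        dummies.columns = [f"dow_{_DOW_NAMES[int(c.split('_')[1])]}" for c in dummies.columns]
        dummies = dummies.iloc[:, 1:]  # reference: Monday
        parts.append(dummies.set_axis(dates, axis=0))
    return pd.concat(parts, axis=1)


def _fit_glm(y: pd.Series, X: pd.DataFrame, spec, design: str, meta: dict) -> FitResult:
    _check_rank(X)
    yv = y.to_numpy(dtype=float)
    model = sm.GLM(yv, X.to_numpy(dtype=float), family=sm.families.Poisson())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        res = model.fit(maxiter=100, tol=1e-8)
    if not res.converged:
        raise RuntimeError(
            f"IRLS failed to converge in 100 iterations; deviance trace: "
            f"{res.fit_history.get('deviance', [])!r}")
    mu = res.fittedvalues
    n, k = X.shape
    ll = _poisson_loglike(yv, mu)
    # Pearson dispersion; floored so the phi-scaled covariance stays defined
    # even on degenerate perfectly-fitted toy data
    df_resid = n - k
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom (n <= k)")
    phi = max(float(np.sum((yv - mu) ** 2 / mu)) / df_resid, 1e-12)
    params = pd.Series(res.params, index=X.columns)
    cov = pd.DataFrame(phi * res.cov_params(), index=X.columns, columns=X.columns)
    qaic, qbic = quasi_criteria(ll, phi, k, n)
    return FitResult(params=params, cov=cov, dispersion=phi, loglike=ll,
                     k=k, n=n, qaic=qaic, qbic=qbic, converged=True,
                     spec=spec, design=design, meta=meta)


def fit_quasipoisson(
    y: pd.Series,
    cb: CrossBasisMatrix | None,
    strata: StrataAssignment,
    dow_terms: bool = True,
) -> FitResult:
    """Fit the case-crossover quasi-Poisson model.

    ``y`` is the daily (aggregated or per-category) count series; ``cb`` may
    be None for a covariate-only model.  Rows masked invalid in the
    cross-basis (warm-up or missing exposure) are excluded, and strata whose
    total count is zero are dropped with a warning (their stratum effect is
    unbounded below).
    """
    dates = y.index
    if cb is not None:
        if not cb.dates.equals(dates):
            raise ValueError("count series and cross-basis are not date-aligned")
        keep = cb.valid.copy()
    else:
        keep = np.ones(len(dates), dtype=bool)
    labels = strata.labels.reindex(dates)
    if labels.isna().any():
        raise ValueError("strata assignment does not cover all analysis dates")

    y_keep = y[keep]
    lab_keep = labels[keep]
    totals = y_keep.groupby(lab_keep).sum()
    dead = set(totals.index[totals == 0])
    if dead:
        warnings.warn(f"dropping {len(dead)} strata with zero total count", UserWarning)
        keep = keep & ~labels.isin(dead).to_numpy()

    dates_k = dates[keep]
    X = _assemble_design(
        dates_k,
        cb.matrix[keep] if cb is not None else None,
        cb.column_names if cb is not None else None,
        labels[keep],
        dow_terms,
    )
    meta = {"strata_scheme": strata.scheme, "n_strata": int(labels[keep].nunique()),
            "dow_terms": dow_terms}
    return _fit_glm(y[keep], X, cb.spec if cb is not None else None,
                    "case_crossover", meta)


def information_criteria(fit: FitResult) -> tuple[float, float]:
    """(QAIC, QBIC) of a converged fit."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    return fit.qaic, fit.qbic


def select_df(
    y: pd.Series,
    exposure: ExposureSeries,
    strata: StrataAssignment,
    var_df_grid=(4, 5, 6),
    lag_df_grid=(4, 5, 6),
    base_spec: CrossBasisSpec | None = None,
    dow_terms: bool = True,
) -> tuple[CrossBasisSpec, pd.DataFrame]:
    """Grid search over spline degrees of freedom, minimizing QAIC.

    Returns the winning spec and a table with QAIC/QBIC for every candidate.
    When QAIC and QBIC disagree on the winner, QAIC decides and the
    disagreement is logged.
    """
    base = base_spec or CrossBasisSpec()
    rows = []
    fits: dict[tuple[int, int], CrossBasisSpec] = {}
    for vdf in var_df_grid:
        for ldf in lag_df_grid:
            spec = CrossBasisSpec(max_lag=base.max_lag, var_df=vdf,
                                  var_degree=base.var_degree, lag_df=ldf,
                                  lag_knot_spacing=base.lag_knot_spacing)
            try:
                cb = build_crossbasis(exposure, spec)
                fit = fit_quasipoisson(y, cb, strata, dow_terms)
            except Exception as exc:  # candidate excluded, grid continues
                warnings.warn(f"df grid member ({vdf},{ldf}) failed: {exc}", UserWarning)
                continue
            rows.append({"var_df": vdf, "lag_df": ldf, "qaic": fit.qaic,
                         "qbic": fit.qbic, "dispersion": fit.dispersion,
                         "loglike": fit.loglike, "k": fit.k})
            fits[(vdf, ldf)] = cb.spec
    if not rows:
        raise RuntimeError("all df grid members failed")
    table = pd.DataFrame(rows)
    best_qaic = table.loc[table["qaic"].idxmin()]
    best_qbic = table.loc[table["qbic"].idxmin()]
    if (best_qaic["var_df"], best_qaic["lag_df"]) != (best_qbic["var_df"], best_qbic["lag_df"]):
        logger.info("QAIC and QBIC disagree: QAIC -> (%d,%d), QBIC -> (%d,%d); QAIC wins",
                    best_qaic["var_df"], best_qaic["lag_df"],
                    best_qbic["var_df"], best_qbic["lag_df"])
    return fits[(int(best_qaic["var_df"]), int(best_qaic["lag_df"]))], table


def fit_timeseries_alternative(
    y: pd.Series,
    cb: CrossBasisMatrix,
    dow_terms: bool = True,
    seasonal_df_per_year: int = 7,
) -> FitResult:
    """Time-series design: the strata indicators are replaced by a natural
    cubic spline over calendar time with ``seasonal_df_per_year`` df per year
    of data (rounded to the nearest whole number of columns)."""
    dates = y.index
    if not cb.dates.equals(dates):
        raise ValueError("count series and cross-basis are not date-aligned")
    keep = cb.valid
    dates_k = dates[keep]
    t = (dates_k - dates_k[0]).days.to_numpy(dtype=float)
    n_years = (dates[-1] - dates[0]).days / 365.25
    df = max(2, int(round(seasonal_df_per_year * n_years)))
    # df columns without intercept => df + 1 knots spanning the time range
    knots = np.quantile(t, np.linspace(0, 1, df + 1))
    spline = natural_cubic_basis(t, knots, intercept=False)
    X = _assemble_design(dates_k, cb.matrix[keep], cb.column_names, None,
                        dow_terms, time_spline=spline)
    meta = {"seasonal_df_per_year": seasonal_df_per_year, "time_spline_df": df,
            "dow_terms": dow_terms}
    return _fit_glm(y[keep], X, cb.spec, "time_series", meta)


class CaseCrossoverDLNM:
    """Distributed-lag non-linear model in a case-crossover (or time-series)
    design, scikit-learn style.

    Parameters
    ----------
    max_lag, var_df, var_degree, lag_df, lag_knot_spacing : cross-basis
        settings (see :class:`heatlag.crossbasis.CrossBasisSpec`).
    strata : "calendar_month" or "fixed_window:w".
    design : "case_crossover" (strata indicators) or "time_series"
        (natural cubic spline over time, ``seasonal_df_per_year`` df/year).
    dow_terms : include day-of-week indicators.

    Fitted attributes (trailing underscore): ``spec_``, ``result_``,
    ``coef_``, ``dispersion_``, ``qaic_``, ``qbic_``, ``reference_``.
    """

    _param_names = ("max_lag", "var_df", "var_degree", "lag_df",
                    "lag_knot_spacing", "strata", "design",
                    "seasonal_df_per_year", "dow_terms")

    def __init__(self, max_lag: int = 10, var_df: int = 4, var_degree: int = 2,
                 lag_df: int = 4, lag_knot_spacing: str = "log",
                 strata: str = "calendar_month", design: str = "case_crossover",
                 seasonal_df_per_year: int = 7, dow_terms: bool = True):
        self.max_lag = max_lag
        self.var_df = var_df
        self.var_degree = var_degree
        self.lag_df = lag_df
        self.lag_knot_spacing = lag_knot_spacing
        self.strata = strata
        self.design = design
        self.seasonal_df_per_year = seasonal_df_per_year
        self.dow_terms = dow_terms

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "CaseCrossoverDLNM":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: ExposureSeries, y: pd.Series) -> "CaseCrossoverDLNM":
        """Fit on a daily exposure series X and aligned daily counts y."""
        spec = CrossBasisSpec(max_lag=self.max_lag, var_df=self.var_df,
                              var_degree=self.var_degree, lag_df=self.lag_df,
                              lag_knot_spacing=self.lag_knot_spacing)
        cb = build_crossbasis(X, spec)
        if self.design == "case_crossover":
            assignment = make_strata(X.dates, self.strata)
            self.result_ = fit_quasipoisson(y, cb, assignment, self.dow_terms)
        elif self.design == "time_series":
            self.result_ = fit_timeseries_alternative(
                y, cb, self.dow_terms, self.seasonal_df_per_year)
        else:
            raise ValueError(f"unknown design {self.design!r}")
        self.spec_ = cb.spec
        self.crossbasis_ = cb
        self.coef_ = self.result_.beta
        self.dispersion_ = self.result_.dispersion
        self.qaic_ = self.result_.qaic
        self.qbic_ = self.result_.qbic
        self.reference_ = float(np.median(X.dropna()))
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")

    def predict_rr(self, temperatures=None, reference: float | None = None,
                   level: float = 0.95):
        """Relative-risk surface against the reference temperature."""
        from .prediction import predict_rr
        self._check_fitted()
        ref = self.reference_ if reference is None else reference
        if temperatures is None:
            lo, hi = self.spec_.var_boundary
            temperatures = np.arange(np.floor(lo * 10), np.ceil(hi * 10) + 1) / 10.0
        return predict_rr(self.result_, self.spec_, temperatures, ref, level=level)

    def cumulative_rr(self, temperatures, reference: float | None = None,
                      level: float = 0.95):
        from .prediction import cumulative_rr
        self._check_fitted()
        ref = self.reference_ if reference is None else reference
        return cumulative_rr(self.result_, self.spec_, temperatures, ref, level=level)
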