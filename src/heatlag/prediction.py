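"""Relative-risk prediction from a fitted model.

All risks are contrasts against a reference temperature (the series median in
the main analysis).  For temperature x and lag l the log relative risk is

    log RR(x, l) = sum_{i,j} [B_i(x) - B_i(ref)] * C_j(l) * beta_{ij}

with Wald variance from the corresponding contrast vector and the
phi-scaled coefficient covariance; confidence bounds are exponentiated
log-scale bounds.  The cumulative (overall) risk at x sums log RR over all
lags 0..L, with the variance of the summed contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .crossbasis import CrossBasisSpec, build_lag_basis, build_var_basis
from .model import FitResult

__all__ = ["RRSurface", "CumulativeRR", "predict_rr", "lag_slice",
           "temperature_slice", "cumulative_rr"]


@dataclass
class RRSurface:
    """Relative risk with 95% bounds on a temperature x lag grid."""

    temperatures: np.ndarray          # (nT,)
    lags: np.ndarray                  # (L+1,)
    rr: np.ndarray                    # (nT, L+1)
    lower: np.ndarray
    upper: np.ndarray
    reference: float
    fit_id: str = ""

    def at(self, temperature: float, lag: int) -> tuple[float, float, float]:
        i = int(np.argmin(np.abs(self.temperatures - temperature)))
        if not np.isclose(self.temperatures[i], temperature):
            raise KeyError(f"temperature {temperature} not on the surface grid")
        j = int(np.where(self.lags == lag)[0][0])
        return float(self.rr[i, j]), float(self.lower[i, j]), float(self.upper[i, j])

    def frame(self) -> pd.DataFrame:
        t, l = np.meshgrid(self.temperatures, self.lags, indexing="ij")
        return pd.DataFrame({
            "temperature": t.ravel(), "lag": l.ravel().astype(int),
            "rr": self.rr.ravel(), "lower": self.lower.ravel(),
            "upper": self.upper.ravel(),
        })


@dataclass
class CumulativeRR:
    """Overall relative risk summed over lags 0..L."""

    temperatures: np.ndarray
    rr: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    reference: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"temperature": self.temperatures, "rr": self.rr,
                             "lower": self.lower, "upper": self.upper})


def _contrast_pieces(fit: FitResult, spec: CrossBasisSpec, temperatures, reference):
    if not spec.is_resolved:
        raise ValueError("spec must carry resolved knots (fit the cross-basis first)")
    if spec.n_params != len(fit.cb_names):
        raise ValueError("fit and spec have inconsistent basis dimensions")
    lo, hi = spec.var_boundary
    if not (lo <= reference <= hi):
        raise ValueError("reference temperature outside the basis boundary")
    temps = np.atleast_1d(np.asarray(temperatures, dtype=float))
    D = build_var_basis(temps, spec) - build_var_basis([reference], spec)  # (nT, v)
    C = build_lag_basis(spec)                                              # (L+1, j)
    beta = fit.beta.reshape(spec.var_df, spec.lag_df)
    cov4 = fit.beta_cov.reshape(spec.var_df, spec.lag_df,
                                spec.var_df, spec.lag_df)
    return temps, D, C, beta, cov4


def predict_rr(fit: FitResult, spec: CrossBasisSpec, temperatures,
               reference: float, level: float = 0.95) -> RRSurface:
    """RR(x, l) with Wald bounds for every temperature and lag 0..L."""
    temps, D, C, beta, cov4 = _contrast_pieces(fit, spec, temperatures, reference)
    z = norm.ppf(0.5 + level / 2.0)
    log_rr = D @ (beta @ C.T)                                   # (nT, L+1)
    # var[i,l] = D_i' W_l D_i with W_l = C_l' Sigma C_l contracted over j
    W = np.einsum("lj,vjwk,lk->lvw", C, cov4, C)                # (L+1, v, v)
    var = np.einsum("iv,lvw,iw->il", D, W, D)
    se = np.sqrt(np.maximum(var, 0.0))
    return RRSurface(
        temperatures=temps,
        lags=np.arange(spec.max_lag + 1),
        rr=np.exp(log_rr),
        lower=np.exp(log_rr - z * se),
        upper=np.exp(log_rr + z * se),
        reference=float(reference),
        fit_id=fit.meta.get("fit_id", ""),
    )


def lag_slice(surface: RRSurface, at_temperatures) -> pd.DataFrame:
    """RR along lags at the requested grid temperatures (e.g. p90/p95/p99)."""
    rows = []
    for temp in np.atleast_1d(at_temperatures):
        for j, lag in enumerate(surface.lags):
            i = int(np.argmin(np.abs(surface.temperatures - temp)))
            if not np.isclose(surface.temperatures[i], temp):
                raise KeyError(f"temperature {temp} not on the surface grid")
            rows.append({"temperature": float(temp), "lag": int(lag),
                         "rr": surface.rr[i, j], "lower": surface.lower[i, j],
                         "upper": surface.upper[i, j]})
    return pd.DataFrame(rows)


def temperature_slice(surface: RRSurface, at_lags=(0, 1, 2, 4)) -> pd.DataFrame:
    """RR along the temperature range at the requested lags."""
    rows = []
    for lag in np.atleast_1d(at_lags):
        j = int(np.where(surface.lags == lag)[0][0])
        for i, temp in enumerate(surface.temperatures):
            rows.append({"temperature": float(temp), "lag": int(lag),
                         "rr": surface.rr[i, j], "lower": surface.lower[i, j],
                         "upper": surface.upper[i, j]})
    return pd.DataFrame(rows)


def cumulative_rr(fit: FitResult, spec: CrossBasisSpec, temperatures,
                  reference: float, level: float = 0.95) -> CumulativeRR:
    """Overall RR over lags 0..L via the summed contrast vector."""
    temps, D, C, beta, cov4 = _contrast_pieces(fit, spec, temperatures, reference)
    z = norm.ppf(0.5 + level / 2.0)
    S = C.sum(axis=0)                                           # (j,)
    log_rr = D @ (beta @ S)                                     # (nT,)
    W = np.einsum("j,vjwk,k->vw", S, cov4, S)                   # (v, v)
    var = np.einsum("iv,vw,iw->i", D, W, D)
    se = np.sqrt(np.maximum(var, 0.0))
    return CumulativeRR(
        temperatures=temps,
        rr=np.exp(log_rr),
        lower=np.exp(log_rr - z * se),
        upper=np.exp(log_rr + z * se),
        reference=float(reference),
    )
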