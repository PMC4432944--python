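"""Distributed-lag non-linear cross-basis.

The exposure-lag-response surface is parameterized by the tensor product of a
quadratic B-spline basis over temperature and a natural cubic spline basis
over lag.  For day ``t`` the cross-basis row collapses the exposure history
over lags 0..L:

    entry_{t,(i,j)} = sum_{l=0..L}  B_i(x_{t-l}) * C_j(l)

where ``B`` is the temperature basis (var_df columns, no intercept: relative
risks are contrasts, so the level is absorbed by the model intercept) and
``C`` the lag basis (lag_df columns, *with* intercept so an effect at lag 0
is representable; boundary knots at lag 0 and lag L).  The first L days have
incomplete lag history and are masked invalid, as is any day whose lag window
touches a missing exposure value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exposure import ExposureSeries
from .splines import bspline_basis, natural_cubic_basis, quantile_knots

__all__ = ["CrossBasisSpec", "CrossBasisMatrix", "CrossBasis",
           "build_var_basis", "build_lag_basis", "build_crossbasis"]


@dataclass
class CrossBasisSpec:
    """Settings of the two marginal bases.

    ``var_knots``/``var_boundary`` may be left None, in which case they are
    resolved from the exposure series when the cross-basis is built: boundary
    knots at the observed range, interior knots at evenly distributed
    percentiles (var_df - var_degree of them).  The lag basis is a natural
    cubic spline with intercept: lag_df columns require lag_df - 2 interior
    knots, placed evenly on the log(1 + lag) scale by default
    (``lag_knot_spacing = "log"``, concentrating resolution at the short lags
    where delayed temperature effects change fastest) or at evenly spaced
    quantiles of 0..L (``"linear"``).
    """

    max_lag: int = 10
    var_df: int = 4
    var_degree: int = 2
    var_knots: tuple[float, ...] | None = None
    var_boundary: tuple[float, float] | None = None
    lag_df: int = 4
    lag_knot_spacing: str = "log"

    def __post_init__(self) -> None:
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        if self.var_df < self.var_degree + 1:
            raise ValueError("var_df must be >= var_degree + 1")
        if self.lag_df < 2:
            raise ValueError("lag_df must be >= 2")
        if self.lag_df - 2 > self.max_lag - 1:
            raise ValueError(f"lag_df={self.lag_df} too large for max_lag={self.max_lag}")
        if self.lag_knot_spacing not in ("linear", "log"):
            raise ValueError("lag_knot_spacing must be 'linear' or 'log'")
        if self.var_knots is not None:
            expected = self.var_df - self.var_degree
            if len(self.var_knots) != expected:
                raise ValueError(
                    f"var_df={self.var_df} with degree {self.var_degree} "
                    f"requires {expected} interior knots, got {len(self.var_knots)}")

    @property
    def n_params(self) -> int:
        return self.var_df * self.lag_df

    def lag_knots(self) -> np.ndarray:
        """Full lag knot vector: boundary (0, L) plus interior knots."""
        n_int = self.lag_df - 2
        if n_int == 0:
            interior = np.array([])
        elif self.lag_knot_spacing == "linear":
            interior = quantile_knots(np.arange(self.max_lag + 1.0), n_int)
        else:
            probs = np.arange(1, n_int + 1) / (n_int + 1)
            interior = np.expm1(probs * np.log1p(self.max_lag))
        return np.r_[0.0, interior, float(self.max_lag)]

    def resolve(self, x: np.ndarray) -> "CrossBasisSpec":
        """Fill var_knots/var_boundary from observed exposure values."""
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        if x.size < 2:
            raise ValueError("need at least two observed exposure values")
        out = self
        if out.var_boundary is None:
            out = replace(out, var_boundary=(float(x.min()), float(x.max())))
        if out.var_knots is None:
            n_int = out.var_df - out.var_degree
            out = replace(out, var_knots=tuple(quantile_knots(x, n_int)))
        return out

    @property
    def is_resolved(self) -> bool:
        return self.var_knots is not None and self.var_boundary is not None


def build_var_basis(x, spec: CrossBasisSpec) -> np.ndarray:
    """Quadratic B-spline temperature basis (var_df columns, no intercept)."""
    if not spec.is_resolved:
        spec = spec.resolve(np.asarray(x, dtype=float))
    return bspline_basis(x, spec.var_knots, spec.var_boundary,
                         degree=spec.var_degree, intercept=False)


def build_lag_basis(spec: CrossBasisSpec) -> np.ndarray:
    """Natural cubic spline basis over integer lags 0..L, (L+1) x lag_df."""
    return natural_cubic_basis(np.arange(spec.max_lag + 1.0), spec.lag_knots(),
                               intercept=True)


@dataclass
class CrossBasisMatrix:
    """Cross-basis rows per day with a validity mask.

    ``matrix`` has one column per (i, j) pair, i (temperature basis) outer and
    j (lag basis) inner; ``valid`` is False for the first L days and wherever
    the lag window contains a missing exposure value.
    """

    matrix: np.ndarray
    valid: np.ndarray
    dates: pd.DatetimeIndex
    spec: CrossBasisSpec

    @property
    def column_names(self) -> list[str]:
        return [f"cb_v{i + 1}_l{j + 1}"
                for i in range(self.spec.var_df)
                for j in range(self.spec.lag_df)]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.dates, columns=self.column_names)


def build_crossbasis(exposure: ExposureSeries, spec: CrossBasisSpec) -> CrossBasisMatrix:
    """Apply the tensor-product basis to the lagged exposure history."""
    x = exposure.values.to_numpy(dtype=float)
    n = len(x)
    L = spec.max_lag
    if n < L + 1:
        raise ValueError(f"exposure must cover at least {L + 1} consecutive days")
    spec = spec.resolve(x)

    # lagged exposure matrix Q[t, l] = x_{t-l} (NaN where unavailable)
    Q = np.full((n, L + 1), np.nan)
    for lag in range(L + 1):
        Q[lag:, lag] = x[: n - lag]

    valid = np.all(np.isfinite(Q), axis=1)
    Qf = np.where(np.isfinite(Q), Q, 0.0)  # placeholder; invalid rows masked
    V = build_var_basis(Qf.ravel(), spec).reshape(n, L + 1, spec.var_df)
    C = build_lag_basis(spec)  # (L+1) x lag_df
    M = np.einsum("tlv,lj->tvj", V, C).reshape(n, spec.var_df * spec.lag_df)
    M[~valid] = np.nan
    return CrossBasisMatrix(matrix=M, valid=valid, dates=exposure.dates, spec=spec)


class CrossBasis:
    """Transformer view of the cross-basis (scikit-learn conventions).

    ``fit`` resolves the knots from the observed exposure; ``transform``
    returns the cross-basis matrix (invalid rows NaN).  Parameters mirror
    :class:`CrossBasisSpec`.
    """

    def __init__(self, max_lag: int = 10, var_df: int = 4, var_degree: int = 2,
                 lag_df: int = 4, lag_knot_spacing: str = "log"):
        self.max_lag = max_lag
        self.var_df = var_df
        self.var_degree = var_degree
        self.lag_df = lag_df
        self.lag_knot_spacing = lag_knot_spacing

    # minimal get/set_params so the transformer composes with sklearn tooling
    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("max_lag", "var_df", "var_degree", "lag_df", "lag_knot_spacing")}

    def set_params(self, **params) -> "CrossBasis":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _make_spec(self) -> CrossBasisSpec:
        return CrossBasisSpec(max_lag=self.max_lag, var_df=self.var_df,
                              var_degree=self.var_degree, lag_df=self.lag_df,
                              lag_knot_spacing=self.lag_knot_spacing)

    def fit(self, X: ExposureSeries, y=None) -> "CrossBasis":
        self.spec_ = self._make_spec().resolve(X.values.to_numpy(dtype=float))
        return self

    def transform(self, X: ExposureSeries) -> CrossBasisMatrix:
        if not hasattr(self, "spec_"):
            raise RuntimeError("CrossBasis must be fitted before transform")
        return build_crossbasis(X, self.spec_)

    def fit_transform(self, X: ExposureSeries, y=None) -> CrossBasisMatrix:
        return self.fit(X).transform(X)
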