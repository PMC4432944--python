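"""Independent brute-force oracles used by the test suite.

These deliberately avoid scipy.interpolate: B-splines are evaluated by the
Cox-de Boor recursion written out below, and natural cubic interpolation
splines by the classic tridiagonal second-derivative solve.
"""

import numpy as np


def cox_de_boor(i: int, k: int, t: np.ndarray, x: float) -> float:
    """Value of the i-th B-spline of degree k on knot vector t at x."""
    if k == 0:
        # half-open intervals, closed at the right end of the basis support
        if t[i] <= x < t[i + 1]:
            return 1.0
        if x == t[-1] and t[i] < t[i + 1] <= t[-1] and t[i + 1] == t[-1]:
            return 1.0
        return 0.0
    left = 0.0
    if t[i + k] > t[i]:
        left = (x - t[i]) / (t[i + k] - t[i]) * cox_de_boor(i, k - 1, t, x)
    right = 0.0
    if t[i + k + 1] > t[i + 1]:
        right = (t[i + k + 1] - x) / (t[i + k + 1] - t[i + 1]) * cox_de_boor(i + 1, k - 1, t, x)
    return left + right


def bspline_design_oracle(x, interior, boundary, degree, intercept=False):
    """B-spline design matrix via the recursion (points inside the boundary)."""
    lo, hi = boundary
    t = np.r_[[lo] * (degree + 1), np.sort(np.asarray(interior, float)), [hi] * (degree + 1)]
    n_basis = len(t) - degree - 1
    out = np.array([[cox_de_boor(i, degree, t, xi) for i in range(n_basis)]
                    for xi in np.atleast_1d(np.asarray(x, float))])
    return out if intercept else out[:, 1:]


def natural_interp_second_derivs(knots, y):
    """Second derivatives of the natural cubic interpolation spline
    (classic tridiagonal solve; M_0 = M_{m-1} = 0)."""
    knots = np.asarray(knots, float)
    y = np.asarray(y, float)
    m = len(knots)
    if m == 2:
        return np.zeros(2)
    h = np.diff(knots)
    A = np.zeros((m - 2, m - 2))
    b = np.zeros(m - 2)
    for row, i in enumerate(range(1, m - 1)):
        A[row, row] = 2 * (h[i - 1] + h[i])
        if row > 0:
            A[row, row - 1] = h[i - 1]
        if row < m - 3:
            A[row, row + 1] = h[i]
        b[row] = 6 * ((y[i + 1] - y[i]) / h[i] - (y[i] - y[i - 1]) / h[i - 1])
    M = np.zeros(m)
    M[1:-1] = np.linalg.solve(A, b)
    return M


def natural_interp_eval(knots, y, x):
    """Evaluate the natural cubic interpolation spline through (knots, y)."""
    knots = np.asarray(knots, float)
    y = np.asarray(y, float)
    M = natural_interp_second_derivs(knots, y)
    x = np.atleast_1d(np.asarray(x, float))
    out = np.empty_like(x)
    for j, xi in enumerate(x):
        i = int(np.clip(np.searchsorted(knots, xi, side="right") - 1, 0, len(knots) - 2))
        h = knots[i + 1] - knots[i]
        a = (knots[i + 1] - xi) / h
        b = (xi - knots[i]) / h
        out[j] = (a * y[i] + b * y[i + 1]
                  + ((a ** 3 - a) * M[i] + (b ** 3 - b) * M[i + 1]) * h ** 2 / 6.0)
    return out


def natural_basis_oracle(x, knots, intercept=True):
    """Cardinal natural-spline basis via the tridiagonal interpolation solve."""
    knots = np.sort(np.unique(np.asarray(knots, float)))
    cols = [natural_interp_eval(knots, np.eye(len(knots))[i], x)
            for i in range(len(knots))]
    out = np.column_stack(cols)
    return out if intercept else out[:, 1:]


def crossbasis_oracle(x, spec):
    """Cross-basis by an explicit double loop over lags and basis functions."""
    x = np.asarray(x, float)
    n = len(x)
    L = spec.max_lag
    B = lambda v: bspline_design_oracle([v], spec.var_knots, spec.var_boundary,
                                        spec.var_degree, intercept=False)[0]
    C = natural_basis_oracle(np.arange(L + 1.0), spec.lag_knots(), intercept=True)
    out = np.full((n, spec.var_df * spec.lag_df), np.nan)
    for t in range(L, n):
        row = np.zeros((spec.var_df, spec.lag_df))
        for lag in range(L + 1):
            bv = B(x[t - lag])
            for i in range(spec.var_df):
                for j in range(spec.lag_df):
                    row[i, j] += bv[i] * C[lag, j]
        out[t] = row.reshape(-1)
    return out


def poisson_negloglike(theta, X, y):
    eta = X @ theta
    mu = np.exp(eta)
    return -(y @ eta - mu.sum())
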