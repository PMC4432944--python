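"""Spline bases used by the cross-basis: quadratic B-splines over temperature
and natural cubic splines over lag (and over calendar time in the time-series
design).

Conventions
-----------
* ``bspline_basis`` follows the usual regression-spline convention: with
  ``intercept=False`` the first basis function is dropped, so ``df`` columns
  correspond to ``df - degree`` interior knots.  Values outside the boundary
  knots are evaluated by polynomial extension of the edge pieces (never
  silently clipped).
* ``natural_cubic_basis`` returns the *cardinal* natural-spline basis on a
  given knot vector: basis function ``N_i`` is the natural cubic interpolating
  spline with ``N_i(knot_j) = delta_ij`` and zero second derivative at both
  boundary knots.  The cardinal basis spans exactly the space of natural cubic
  splines on those knots (dimension = number of knots) and sums to one
  everywhere, so the model intercept is contained in its span.  With
  ``intercept=False`` the first cardinal function is dropped; together with a
  separate model intercept the span is unchanged.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline, CubicSpline

__all__ = ["bspline_basis", "natural_cubic_basis", "quantile_knots"]


def quantile_knots(values: np.ndarray, n_interior: int) -> np.ndarray:
    """Interior knots at ``n_interior`` evenly distributed percentiles.

    For ``n_interior = m`` the percentiles are ``100 * i / (m + 1)`` for
    ``i = 1..m`` (e.g. 33.33 / 66.67 for two knots).
    """
    if n_interior < 0:
        raise ValueError("n_interior must be >= 0")
    if n_interior == 0:
        return np.array([])
    probs = np.arange(1, n_interior + 1) / (n_interior + 1)
    return np.quantile(np.asarray(values, dtype=float), probs)


def bspline_basis(
    x,
    interior_knots,
    boundary: tuple[float, float],
    degree: int = 2,
    intercept: bool = False,
) -> np.ndarray:
    """B-spline design matrix of the given degree.

    Parameters
    ----------
    x : array-like of evaluation points (must be finite).
    interior_knots : knots strictly inside ``boundary``.
    boundary : (lo, hi) boundary knots, repeated to full multiplicity.
    degree : polynomial degree (2 = quadratic).
    intercept : keep the first basis function.  With it, rows sum to one
        inside the boundary (partition of unity).

    Returns
    -------
    ndarray of shape (len(x), n_columns) where ``n_columns`` equals
    ``len(interior_knots) + degree + 1`` with intercept, one less without.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("basis evaluation points must be finite")
    lo, hi = float(boundary[0]), float(boundary[1])
    if not lo < hi:
        raise ValueError("boundary knots must satisfy lo < hi")
    interior = np.sort(np.asarray(interior_knots, dtype=float))
    if interior.size and (interior.min() <= lo or interior.max() >= hi):
        raise ValueError("interior knots must lie strictly inside the boundary")
    t = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    dm = BSpline.design_matrix(x, t, degree, extrapolate=True).toarray()
    if not intercept:
        dm = dm[:, 1:]
    return dm


def natural_cubic_basis(
    x,
    knots,
    intercept: bool = True,
) -> np.ndarray:
    """Cardinal natural-cubic-spline basis evaluated at ``x``.

    ``knots`` must contain the two boundary knots and any interior knots
    (at least two distinct values).  Column ``i`` is the natural cubic spline
    interpolating the indicator of knot ``i``; columns sum to one everywhere
    on the knot range.  Outside the boundary the edge cubic piece is extended.

    With ``intercept=False`` the first column is dropped (use together with a
    separate model intercept).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("basis evaluation points must be finite")
    knots = np.sort(np.unique(np.asarray(knots, dtype=float)))
    m = knots.size
    if m < 2:
        raise ValueError("need at least two distinct knots")
    cols = []
    eye = np.eye(m)
    for i in range(m):
        sp = CubicSpline(knots, eye[i], bc_type="natural")
        cols.append(sp(x))
    dm = np.column_stack(cols)
    if not intercept:
        dm = dm[:, 1:]
    return dm
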