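"""Spline bases for flexible dose-response terms.

Two families back the ensemble: the restricted (natural) cubic spline in
Harrell's truncated-power parameterisation -- linear beyond the outer
knots, ``k-1`` columns for ``k`` knots including the linear term -- and
B-spline bases built on :class:`scipy.interpolate.BSpline` with the first
column dropped (the basis partitions unity, which would alias the stratum
intercepts).
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["restricted_cubic_basis", "bspline_basis", "place_knots"]


def restricted_cubic_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis (Harrell), columns [x, s_1, ..., s_{k-2}].

    For knots t_0 < ... < t_{k-1} the nonlinear terms are

        s_j(x) = [ (x-t_j)+^3 - (x-t_{k-2})+^3 (t_{k-1}-t_j)/(t_{k-1}-t_{k-2})
                   + (x-t_{k-1})+^3 (t_{k-2}-t_j)/(t_{k-1}-t_{k-2}) ] / (t_{k-1}-t_0)^2,

    which makes the spline linear outside [t_0, t_{k-1}].
    """
    x = np.asarray(x, float)
    t = np.asarray(knots, float)
    if len(t) < 3 or np.any(np.diff(t) <= 0):
        raise ValueError("need at least 3 strictly increasing knots")
    k = len(t)
    norm2 = (t[-1] - t[0]) ** 2
    plus3 = lambda v: np.maximum(v, 0.0) ** 3
    cols = [x]
    for j in range(k - 2):
        s = (
            plus3(x - t[j])
            - plus3(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
            + plus3(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
        ) / norm2
        cols.append(s)
    return np.column_stack(cols)


def bspline_basis(x, internal_knots, boundary, degree: int = 3,
                  drop_first: bool = True) -> np.ndarray:
    """B-spline design matrix of the given degree.

    ``boundary`` are the exterior knots; evaluation points are clipped to
    the boundary (constant extrapolation of the basis), so the basis is
    defined for any exposure.  With ``drop_first`` one column is removed to
    keep the design full rank next to intercept columns.
    """
    x = np.asarray(x, float)
    lo, hi = float(boundary[0]), float(boundary[1])
    t_int = np.asarray(internal_knots, float)
    if np.any(np.diff(t_int) <= 0):
        raise ValueError("internal knots must be strictly increasing")
    if t_int.size and (t_int[0] <= lo or t_int[-1] >= hi):
        raise ValueError("internal knots must lie strictly inside the boundary")
    t = np.concatenate([[lo] * (degree + 1), t_int, [hi] * (degree + 1)])
    xc = np.clip(x, lo, hi)
    B = BSpline.design_matrix(xc, t, degree).toarray()
    return B[:, 1:] if drop_first else B


def place_knots(x, n_knots: int, method: str, window=(0.01, 0.99)) -> np.ndarray:
    """Choose ``n_knots`` internal knot positions inside the exposure window.

    ``method='quantile'`` places knots at equally spaced quantile levels
    between the window quantiles; ``method='equal'`` spaces them equally in
    Bq/m^3 between the window quantiles.  Duplicate positions (heavy ties)
    raise, as the resulting basis would be rank deficient.
    """
    x = np.asarray(x, float)
    q_lo, q_hi = np.quantile(x, window)
    if method == "quantile":
        levels = window[0] + (window[1] - window[0]) * (np.arange(1, n_knots + 1) / (n_knots + 1))
        knots = np.quantile(x, levels)
    elif method == "equal":
        knots = np.linspace(q_lo, q_hi, n_knots + 2)[1:-1]
    else:
        raise ValueError(f"unknown knot placement {method!r}")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knot collision: data too discrete for this placement")
    return knots
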