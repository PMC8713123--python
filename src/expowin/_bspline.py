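"""Cubic B-spline design matrices on evenly spaced knots (shared helper)."""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline


def bspline_knots(xmin: float, xmax: float, k: int, degree: int = 3) -> np.ndarray:
    """Full knot vector giving exactly ``k`` basis functions over [xmin, xmax].

    Knots are evenly spaced and extended beyond the range so every basis
    function is a proper polynomial piece (P-spline convention), which keeps
    the basis well defined slightly outside the data range for prediction.
    """
    if k < degree + 1:
        raise ValueError(f"need k >= degree + 1, got k={k}, degree={degree}")
    if not np.isfinite([xmin, xmax]).all():
        raise ValueError("non-finite knot range")
    if xmax <= xmin:
        # degenerate range: widen artificially so the basis is usable
        xmin, xmax = xmin - 0.5, xmax + 0.5
    n_interior = k - degree - 1
    step = (xmax - xmin) / (n_interior + 1)
    return xmin + step * np.arange(-degree, n_interior + degree + 2)


def bspline_design(x: np.ndarray, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    """Dense design matrix of the B-spline basis at ``x`` (extrapolating)."""
    x = np.asarray(x, dtype=float)
    mat = BSpline.design_matrix(x, knots, degree, extrapolate=True)
    return np.asarray(mat.todense())


def difference_penalty(k: int, order: int = 2) -> np.ndarray:
    """P-spline penalty D'D for ``k`` coefficients and a given difference order."""
    d = np.diff(np.eye(k), n=order, axis=0)
    return d.T @ d
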