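"""Restricted cubic spline (natural spline) bases with detrended columns.

The truncated-power restricted cubic spline of Harrell: with knots
``t_1 < ... < t_k`` the basis spans {1, x, f_1(x), ..., f_{k-2}(x)} where
each ``f_j`` is piecewise cubic between the knots and *linear* outside
the boundary knots.  That tail linearity is what makes the basis safe to
evaluate beyond the fitted range: extrapolation continues the boundary
slope instead of exploding cubically.

For trend/curvature decompositions the raw ``f_j`` are unsuitable
because each carries its own linear drift.  :class:`DetrendedSpline`
removes it: every column is projected off {1, x} by least squares *on a
fixed reference set of x values*, and the same affine correction is
applied wherever the basis is later evaluated.  Subtracting an affine
function preserves tail linearity, and the resulting columns have (by
construction) zero slope over the reference values — they are pure
curvature.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError


def rcs_knots(x: np.ndarray, n_knots: int) -> np.ndarray:
    """Knots at equally spaced quantiles of ``x`` (Harrell's convention)."""
    if n_knots < 3:
        raise InputError("restricted cubic splines need at least 3 knots")
    if len(np.unique(np.asarray(x, float))) < n_knots:
        raise InputError(
            f"axis has too few distinct values for {n_knots} knots"
        )
    if n_knots == 3:
        probs = np.array([0.10, 0.50, 0.90])
    elif n_knots == 4:
        probs = np.array([0.05, 0.35, 0.65, 0.95])
    elif n_knots == 5:
        probs = np.array([0.05, 0.275, 0.50, 0.725, 0.95])
    elif n_knots == 6:
        probs = np.array([0.05, 0.23, 0.41, 0.59, 0.77, 0.95])
    else:
        probs = np.linspace(0.025, 0.975, n_knots)
    knots = np.quantile(np.asarray(x, float), probs)
    knots = np.unique(np.round(knots, 10))
    if len(knots) < n_knots:
        raise InputError(
            f"axis has too few distinct values for {n_knots} knots "
            f"(got {len(knots)} distinct quantiles)"
        )
    return knots


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Nonlinear columns of the restricted cubic spline basis.

    Returns an ``(len(x), k-2)`` array; the full natural-spline space is
    these columns together with {1, x}.  Columns are scaled by the
    conventional ``(t_k - t_1)^2`` so their magnitude is comparable to x.
    """
    x = np.asarray(x, float)
    t = np.asarray(knots, float)
    if len(t) < 3 or np.any(np.diff(t) <= 0):
        raise InputError("knots must be >= 3 and strictly increasing")
    k = len(t)
    scale = (t[-1] - t[0]) ** 2

    def cube(u):
        return np.clip(u, 0.0, None) ** 3

    cols = []
    denom = t[-1] - t[-2]
    for j in range(k - 2):
        col = (
            cube(x - t[j])
            - cube(x - t[-2]) * (t[-1] - t[j]) / denom
            + cube(x - t[-1]) * (t[-2] - t[j]) / denom
        )
        cols.append(col / scale)
    return np.column_stack(cols)


class DetrendedSpline:
    """RCS curvature basis orthogonalised against {1, x} on reference values."""

    def __init__(self, reference_x: np.ndarray, knots: np.ndarray):
        self.knots = np.asarray(knots, float)
        ref = np.asarray(reference_x, float)
        B = rcs_basis(ref, self.knots)
        A = np.column_stack([np.ones_like(ref), ref])
        # affine fit of each spline column on the reference axis values
        self._affine, *_ = np.linalg.lstsq(A, B, rcond=None)

    @property
    def n_cols(self) -> int:
        return len(self.knots) - 2

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, float))
        B = rcs_basis(x, self.knots)
        A = np.column_stack([np.ones_like(x), x])
        return B - A @ self._affine
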