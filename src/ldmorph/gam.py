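"""Penalized cubic regression spline with GCV smoothing selection.

A one-dimensional P-spline (Eilers & Marx): cubic B-spline basis on
equally spaced knots with a second-order difference penalty on the
coefficients, fitted by penalized least squares. The penalty null space
contains all straight lines, so linear trends are never shrunk, and with
a heavy penalty the fit degenerates gracefully to ordinary linear
regression — the behaviour expected of the thin-plate-style smoothers
used for size-scaling curves.

The smoothing parameter is chosen by generalized cross-validation,

    GCV(lam) = n * RSS(lam) / (n - edf(lam))^2,

minimized over a log-spaced grid. Predictions outside the fitted range
extrapolate linearly from the boundary value and slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["PenalizedSpline"]


def _knots(lo: float, hi: float, n_basis: int, degree: int) -> np.ndarray:
    # open knot vector: boundary knots repeated degree+1 times,
    # n_basis - degree - 1 equally spaced interior knots
    interior = np.linspace(lo, hi, n_basis - degree + 1)[1:-1]
    return np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]


@dataclass
class PenalizedSpline:
    """Penalized univariate spline smoother.

    Parameters
    ----------
    n_basis
        Number of basis functions (basis dimension). Automatically
        reduced to at most ``n_points // 2`` (floor 4) for small fits.
    degree
        Spline degree (cubic by default).
    lam
        Smoothing parameter; ``None`` selects it by GCV.
    """

    n_basis: int = 10
    degree: int = 3
    lam: float | None = None

    # fitted state
    knots_: np.ndarray | None = field(default=None, repr=False)
    coef_: np.ndarray | None = field(default=None, repr=False)
    lam_: float | None = None
    edf_: float | None = None
    r_squared_: float | None = None
    n_fit_: int | None = None
    x_range_: tuple[float, float] | None = None

    def fit(self, x: np.ndarray, y: np.ndarray) -> "PenalizedSpline":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        n = len(x)
        if n < 4:
            raise ValueError(f"need at least 4 points to fit a spline, got {n}")
        lo, hi = float(x.min()), float(x.max())
        if hi - lo <= 0:
            raise ValueError("degenerate predictor: all x values identical")

        m = min(self.n_basis, max(4, n // 2))
        k = min(self.degree, m - 1)
        t = _knots(lo, hi, m, k)
        B = BSpline.design_matrix(x, t, k).toarray()

        D2 = np.diff(np.eye(m), n=2, axis=0)
        P = D2.T @ D2
        BtB = B.T @ B
        Bty = B.T @ y

        def solve(lam: float) -> tuple[np.ndarray, float]:
            A = BtB + lam * P
            # small ridge on the linear null space guards against rank
            # deficiency when n is close to m
            A = A + 1e-10 * np.trace(BtB) / m * np.eye(m)
            coef = np.linalg.solve(A, Bty)
            edf = float(np.trace(np.linalg.solve(A, BtB)))
            return coef, edf

        if self.lam is not None:
            lam_opt = float(self.lam)
            coef, edf = solve(lam_opt)
        else:
            scale = np.trace(BtB) / max(np.trace(P), 1e-12)
            grid = scale * np.logspace(-6, 6, 31)
            best = (np.inf, None, None, None)
            for lam in grid:
                coef, edf = solve(lam)
                rss = float(np.sum((y - B @ coef) ** 2))
                denom = max(n - edf, 1e-8)
                gcv = n * rss / denom**2
                if gcv < best[0]:
                    best = (gcv, lam, coef, edf)
            _, lam_opt, coef, edf = best

        fitted = B @ coef
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.knots_ = t
        self.coef_ = coef
        self.lam_ = lam_opt
        self.edf_ = edf
        self.n_fit_ = n
        self.x_range_ = (lo, hi)
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self._spline = BSpline(t, coef, k)
        self._deriv = self._spline.derivative()
        return self

    def predict(self, x: np.ndarray | float) -> np.ndarray:
        """Evaluate the fitted smoother; linear extrapolation outside range."""
        if self.coef_ is None:
            raise RuntimeError("spline is not fitted")
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lo, hi = self.x_range_
        out = self._spline(np.clip(x, lo, hi))
        below, above = x < lo, x > hi
        if below.any():
            out[below] = self._spline(lo) + self._deriv(lo) * (x[below] - lo)
        if above.any():
            out[above] = self._spline(hi) + self._deriv(hi) * (x[above] - hi)
        return out

    def in_range(self, x: np.ndarray | float) -> np.ndarray:
        """Boolean mask: which x lie inside the fitted predictor range."""
        if self.x_range_ is None:
            raise RuntimeError("spline is not fitted")
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lo, hi = self.x_range_
        return (x >= lo) & (x <= hi)
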