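"""Robust local polynomial regression (loess) and the fitted bias curve.

The normalization learns, per sample, a smooth curve describing how that
sample's measurements deviate from the virtual reference as a function of the
measurement itself.  The smoother here is classic loess: for each evaluation
point, a weighted least-squares polynomial (degree 1 or 2) is fitted to the
``span`` fraction of nearest data points with tricube weights, optionally
re-weighted by bisquare robustness iterations so that outliers — such as the
variable CpG sites that contaminate any housekeeping list — do not distort
the curve.

Curves are fitted once on a dense grid spanning the data and evaluated
elsewhere by linear interpolation, which makes evaluation cheap and the whole
pipeline deterministic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class Extrapolation(str, enum.Enum):
    """Policy for inputs outside the fitted x-range.

    DISCARD sets them missing (the behaviour of discarding measurements
    outside the range of the reference set); CLAMP_TO_BOUNDARY evaluates the
    curve at the nearest boundary instead, trading bias for completeness.
    """

    DISCARD = "discard"
    CLAMP_TO_BOUNDARY = "clamp"


@dataclass(frozen=True)
class LoessParams:
    """Parameters of the local regression.

    span: fraction of points in each local window, in (0, 1].
    degree: local polynomial degree (1 or 2).
    robust_iterations: bisquare re-weighting passes (0 disables robustness).
    extrapolation: what to do outside the fitted range.
    grid_points: density of the evaluation grid the curve is interpolated on.
    min_points: minimum usable fit points; fewer is an error (enlarge E).
    """

    span: float = 0.75
    degree: int = 2
    robust_iterations: int = 4
    extrapolation: Extrapolation = Extrapolation.DISCARD
    grid_points: int = 2048
    min_points: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.span <= 1):
            raise ValueError(f"span must be in (0, 1], got {self.span}")
        if self.degree not in (1, 2):
            raise ValueError(f"degree must be 1 or 2, got {self.degree}")
        if self.robust_iterations < 0:
            raise ValueError("robust_iterations must be >= 0")


@dataclass
class BiasCurve:
    """A fitted smooth correction f(x), valid on ``x_range``.

    ``evaluate`` interpolates linearly on the fitted grid; callers decide what
    to do outside ``x_range`` (see Extrapolation).
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    x_range: tuple[float, float]
    n_points: int
    channel_or_stage: str = ""

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """f(x); inputs outside x_range are evaluated at the nearest boundary."""
        x = np.asarray(x, dtype=float)
        return np.interp(x, self.grid_x, self.grid_y)

    __call__ = evaluate

    def in_range(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo, hi = self.x_range
        return (x >= lo) & (x <= hi) & np.isfinite(x)

    def max_abs(self) -> float:
        return float(np.max(np.abs(self.grid_y)))


def _nearest_window_starts(x_sorted: np.ndarray, grid: np.ndarray, k: int) -> np.ndarray:
    """Start index of the k-nearest-neighbour window for each grid point.

    Among the contiguous windows of length k in sorted x, the one minimising
    the distance to the farthest endpoint is the window whose midpoint
    (x[s] + x[s+k-1])/2 brackets the query; found with one searchsorted.
    """
    n = x_sorted.size
    mid = 0.5 * (x_sorted[: n - k + 1] + x_sorted[k - 1 :])
    starts = np.searchsorted(mid, grid)
    return np.clip(starts, 0, n - k)


def _fit_on_grid(
    x: np.ndarray,
    y: np.ndarray,
    base_weight: np.ndarray,
    grid: np.ndarray,
    k: int,
    degree: int,
    chunk: int = 256,
) -> np.ndarray:
    """Local weighted polynomial fit evaluated at each grid point."""
    n = x.size
    starts = _nearest_window_starts(x, grid, k)
    out = np.empty(grid.size)
    for lo in range(0, grid.size, chunk):
        hi = min(lo + chunk, grid.size)
        idx = starts[lo:hi, None] + np.arange(k)[None, :]          # (g, k)
        xw = x[idx]
        yw = y[idx]
        g = grid[lo:hi, None]
        d = np.abs(xw - g)
        dmax = d.max(axis=1, keepdims=True)
        dmax[dmax == 0] = 1.0
        w = (1.0 - (d / dmax) ** 3) ** 3
        np.clip(w, 0.0, None, out=w)
        w *= base_weight[idx]
        # centred/scaled abscissa for conditioning; prediction = intercept
        t = (xw - g) / dmax
        p = degree + 1
        # weighted power sums built by incremental multiplication
        wy = w * yw
        moments = np.empty((hi - lo, 2 * degree + 1))
        b_vec = np.empty((hi - lo, p))
        tp = np.ones_like(t)
        for q in range(2 * degree + 1):
            moments[:, q] = (w * tp).sum(axis=1)
            if q < p:
                b_vec[:, q] = (wy * tp).sum(axis=1)
            tp = tp * t
        A = np.empty((hi - lo, p, p))
        for a in range(p):
            for b in range(p):
                A[:, a, b] = moments[:, a + b]
        # tiny relative ridge keeps near-singular windows solvable
        ridge = 1e-10 * np.trace(A, axis1=1, axis2=2) / p
        A += ridge[:, None, None] * np.eye(p)[None]
        try:
            coef = np.linalg.solve(A, b_vec[..., None])[..., 0]
        except np.linalg.LinAlgError:
            coef = np.array([np.linalg.lstsq(Ai, bi, rcond=None)[0] for Ai, bi in zip(A, b_vec)])
        out[lo:hi] = coef[:, 0]
    return out


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    params: LoessParams = LoessParams(),
    label: str = "",
) -> BiasCurve:
    """Fit a robust loess curve y ~ f(x) and return it as a BiasCurve.

    Missing (NaN) pairs are dropped.  Raises ValueError when fewer than
    ``params.min_points`` usable points remain — the usual cause is a
    housekeeping set that is too small for the probe class.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < params.min_points:
        raise ValueError(
            f"loess fit needs at least {params.min_points} points, got {n}; "
            "consider a larger housekeeping set"
        )
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    k = int(np.ceil(params.span * n))
    k = max(k, params.degree + 2)
    k = min(k, n)
    lo, hi = float(x[0]), float(x[-1])
    if lo == hi:
        raise ValueError("all explanatory values identical; cannot fit a curve")
    grid = np.linspace(lo, hi, params.grid_points)
    robust_w = np.ones(n)
    grid_y = np.zeros(grid.size)
    for iteration in range(params.robust_iterations + 1):
        grid_y = _fit_on_grid(x, y, robust_w, grid, k, params.degree)
        if iteration == params.robust_iterations:
            break
        resid = y - np.interp(x, grid, grid_y)
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        u = resid / (6.0 * s)
        robust_w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if robust_w.sum() < params.degree + 2:  # pathological: everything flagged
            robust_w = np.ones(n)
            break
    return BiasCurve(
        grid_x=grid,
        grid_y=grid_y,
        x_range=(lo, hi),
        n_points=n,
        channel_or_stage=label,
    )
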