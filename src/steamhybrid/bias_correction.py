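"""Multilevel B-spline (MBA) bias-correction surfaces.

A smoothly varying correction surface is built from model-minus-measurement
discrepancies at scattered sites: each level fits a uniform cubic B-spline
control lattice to the residuals of the previous level using the
per-control-point weighted least-squares formula of the multilevel B-spline
approximation algorithm (Lee, Wolberg & Shin), then doubles the lattice
resolution.  Truncating the hierarchy (two levels by default) yields a
surface that corrects large-scale bias without pinning the model output to
the measurements; enough levels (around eight) interpolate scattered points
essentially exactly.

The surface is fitted to mean-centred residuals with the mean carried as an
explicit offset, so a constant residual field is reproduced exactly at any
number of levels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["MBASurface", "fit_mba_surface", "apply_correction"]

MIN_CONC = 0.1

# cubic uniform B-spline segment weights B_0..B_3 evaluated at t in [0,1)
def _cubic_weights(t: np.ndarray) -> np.ndarray:
    t2, t3 = t * t, t * t * t
    return np.stack(
        [
            (1 - t) ** 3 / 6.0,
            (3 * t3 - 6 * t2 + 4) / 6.0,
            (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0,
            t3 / 6.0,
        ],
        axis=-1,
    )


def _lattice_coords(v: np.ndarray, lo: float, hi: float, n_cells: int) -> tuple[np.ndarray, np.ndarray]:
    """Cell index i in [0, n_cells-1] and local parameter t in [0, 1]."""
    s = (v - lo) / (hi - lo) * n_cells
    i = np.clip(np.floor(s).astype(int), 0, n_cells - 1)
    t = s - i
    return i, t


def _ba_level(x, y, z, domain, mx, my) -> np.ndarray:
    """Single-level B-spline approximation: returns (mx+3, my+3) control lattice."""
    x0, x1, y0, y1 = domain
    ix, tx = _lattice_coords(x, x0, x1, mx)
    iy, ty = _lattice_coords(y, y0, y1, my)
    wx = _cubic_weights(tx)  # (n, 4)
    wy = _cubic_weights(ty)
    w = wx[:, :, None] * wy[:, None, :]  # (n, 4, 4)
    sw2 = (w**2).sum(axis=(1, 2))  # (n,)
    num = np.zeros((mx + 3, my + 3))
    den = np.zeros((mx + 3, my + 3))
    w2 = w**2
    for a in range(4):
        for b in range(4):
            np.add.at(num, (ix + a, iy + b), w2[:, a, b] * w[:, a, b] * (z / sw2))
            np.add.at(den, (ix + a, iy + b), w2[:, a, b])
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(den > 0, num / den, 0.0)
    return phi


def _eval_lattice(x, y, phi, domain) -> np.ndarray:
    x0, x1, y0, y1 = domain
    mx, my = phi.shape[0] - 3, phi.shape[1] - 3
    ix, tx = _lattice_coords(x, x0, x1, mx)
    iy, ty = _lattice_coords(y, y0, y1, my)
    wx = _cubic_weights(tx)
    wy = _cubic_weights(ty)
    out = np.zeros(len(x))
    for a in range(4):
        for b in range(4):
            out += wx[:, a] * wy[:, b] * phi[ix + a, iy + b]
    return out


class MBASurface(RegressorMixin, BaseEstimator):
    """Truncated multilevel B-spline approximation of scattered residuals.

    Parameters
    ----------
    domain : (x0, x1, y0, y1)
        Rectangle containing all control points; evaluation is defined on it.
    n_levels : int
        Number of refinement levels; 2 gives the smooth truncated correction
        surface, ~8 interpolates scattered points near-exactly.
    initial_cells : int
        Control cells per axis at the coarsest level (doubled each level).
    """

    def __init__(self, domain=None, n_levels: int = 2, initial_cells: int = 4):
        self.domain = domain
        self.n_levels = n_levels
        self.initial_cells = initial_cells

    def fit(self, X, y) -> "MBASurface":
        xy = np.asarray(X, dtype=float)
        z = np.asarray(y, dtype=float).copy()
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError("X must be (n, 2) coordinates")
        if len(z) < 1:
            raise ValueError("at least one point required")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        dom = self.domain
        if dom is None:
            pad_x = 0.05 * max(np.ptp(xy[:, 0]), 1.0)
            pad_y = 0.05 * max(np.ptp(xy[:, 1]), 1.0)
            dom = (
                float(xy[:, 0].min() - pad_x),
                float(xy[:, 0].max() + pad_x),
                float(xy[:, 1].min() - pad_y),
                float(xy[:, 1].max() + pad_y),
            )
        x0, x1, y0, y1 = dom
        if not (x1 > x0 and y1 > y0):
            raise ValueError("degenerate domain rectangle")
        if np.any(xy[:, 0] < x0) or np.any(xy[:, 0] > x1) or np.any(xy[:, 1] < y0) or np.any(xy[:, 1] > y1):
            raise ValueError("points outside the declared domain")

        self.domain_ = dom
        self.offset_ = float(z.mean())
        resid = z - self.offset_
        self.lattices_: list[np.ndarray] = []
        self.level_max_residual_ = []
        m = self.initial_cells
        for _ in range(self.n_levels):
            phi = _ba_level(xy[:, 0], xy[:, 1], resid, dom, m, m)
            self.lattices_.append(phi)
            resid = resid - _eval_lattice(xy[:, 0], xy[:, 1], phi, dom)
            self.level_max_residual_.append(float(np.abs(resid).max()))
            m *= 2
        return self

    def predict(self, X) -> np.ndarray:
        xy = np.asarray(X, dtype=float)
        out = np.full(len(xy), self.offset_)
        for phi in self.lattices_:
            out += _eval_lattice(xy[:, 0], xy[:, 1], phi, self.domain_)
        return out

    __call__ = predict


def fit_mba_surface(points: pd.DataFrame, domain, n_levels: int = 2, initial_cells: int = 4) -> MBASurface:
    """Fit a correction surface from a (x, y, residual) table."""
    return MBASurface(domain=domain, n_levels=n_levels, initial_cells=initial_cells).fit(
        points[["x", "y"]].to_numpy(), points["residual"].to_numpy()
    )


def apply_correction(grid: pd.DataFrame, surface: MBASurface, floor: float = MIN_CONC) -> pd.DataFrame:
    """Add the correction surface to grid predictions, flooring the result."""
    out = grid.copy()
    corr = surface.predict(grid[["x", "y"]].to_numpy())
    out["prediction"] = np.maximum(grid["prediction"].to_numpy() + corr, floor)
    return out
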