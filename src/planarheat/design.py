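"""Heater-balance optimizer: choose the ring/square power ratio for flatness.

The combined surface field per unit square scale is
``f_beta(x, y) = square(x, y) + beta * ring(r; z0a)`` with ``beta = t2/t1``.
The optimizer minimizes the worst-case deviation of ``f_beta`` from its center
value over a probe disc (min-max, not variance: no sensor cell may exceed a
temperature tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from planarheat.ring import ring_shape_exact
from planarheat.square import square_shape_surface

__all__ = ["DesignResult", "flatten_ratio", "probe_disc_samples"]

BETA_BOUNDS = (0.0, 10.0)


@dataclass(frozen=True)
class DesignResult:
    """Optimal ring/square scale ratio and the achieved flatness objective."""

    ratio: float
    objective: float
    probe_radius: float
    z0a: float
    warning: str | None = None

    def to_dict(self) -> dict:
        return {
            "ratio_t2_over_t1": self.ratio,
            "max_abs_deviation_per_unit_t1": self.objective,
            "probe_radius_a": self.probe_radius,
            "z0a": self.z0a,
            "warning": self.warning,
        }


def probe_disc_samples(probe_radius: float, n_r: int = 60, n_theta: int = 24):
    """Polar sample lattice over the probe disc (first octant suffices by D4
    symmetry of the square kernel and rotational symmetry of the ring, but the
    full quadrant is sampled for robustness)."""
    radii = np.linspace(0.0, probe_radius, n_r + 1)[1:]
    angles = np.linspace(0.0, np.pi / 4.0, n_theta)
    rr, aa = np.meshgrid(radii, angles)
    return rr.ravel() * np.cos(aa.ravel()), rr.ravel() * np.sin(aa.ravel())


def flatten_ratio(
    z0a: float = 0.02,
    probe_radius: float = 0.2,
    tol: float = 1e-6,
) -> DesignResult:
    """Minimize the worst-case center deviation over ``beta = t2/t1``.

    Scalar bounded minimization of ``max |f_beta - f_beta(0,0)|`` over the
    probe disc, ``beta`` in [0, 10].  Deterministic given ``tol``.  If the
    sampled objective shows multiple local minima the best bracket is still
    returned, flagged via ``warning``.
    """
    if not (0.0 < probe_radius < 0.5):
        raise ValueError("probe_radius must lie in (0, 0.5)")
    xs, ys = probe_disc_samples(probe_radius)
    sq = np.asarray(square_shape_surface(xs, ys))
    rg = np.asarray(ring_shape_exact(np.hypot(xs, ys), 0.0, z0a))
    sq0 = float(square_shape_surface(0.0, 0.0))
    rg0 = float(ring_shape_exact(0.0, 0.0, z0a))

    def objective(beta: float) -> float:
        return float(np.max(np.abs((sq - sq0) + beta * (rg - rg0))))

    res = optimize.minimize_scalar(
        objective, bounds=BETA_BOUNDS, method="bounded", options={"xatol": tol}
    )
    warning = None
    # unimodality scan: count descent/ascent sign changes on a coarse grid
    grid = np.linspace(BETA_BOUNDS[0], BETA_BOUNDS[1], 101)
    vals = np.array([objective(b) for b in grid])
    sign_changes = int(np.sum(np.diff(np.sign(np.diff(vals))) != 0))
    best_idx = int(np.argmin(vals))
    beta, obj = float(res.x), float(res.fun)
    if vals[best_idx] < obj:
        beta, obj = float(grid[best_idx]), float(vals[best_idx])
        warning = "bounded minimizer missed the global grid minimum; grid value used"
    elif sign_changes > 1:
        warning = "objective appears non-unimodal over [0, 10]; best bracket returned"
    return DesignResult(
        ratio=beta,
        objective=obj,
        probe_radius=float(probe_radius),
        z0a=float(z0a),
        warning=warning,
    )
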