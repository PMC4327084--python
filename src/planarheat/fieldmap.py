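"""Superposed surface field on grids: profiles, isotherms, homogeneity metrics.

Everything here works in reduced coordinates (units of the square side ``a``)
and in temperature increments above the baseline.  The two kernels are
combined linearly: ``dT(x, y) = t1 * square(x, y) + t2 * ring(r; z0a)``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from planarheat.ring import ring_shape_exact
from planarheat.sources import ThermalScales
from planarheat.square import _surface_limit, square_shape_surface

__all__ = [
    "FieldGrid",
    "IsothermSet",
    "HomogeneityReport",
    "total_surface_field",
    "axis_profile",
    "extract_isotherms",
    "homogeneity_report",
    "default_axes",
    "grid_to_long_csv",
    "grid_to_matrix_csv",
    "isotherms_to_csv",
]

DEFAULT_GRID_N = 201
DEFAULT_EXTENT = 1.0
DEFAULT_PROBE_RADIUS = 0.2
DEFAULT_EPSILON = 0.1


def default_axes(n: int = DEFAULT_GRID_N, extent: float = DEFAULT_EXTENT):
    """Node-centered axes over [-extent, extent]; odd ``n`` pins the origin."""
    ax = np.linspace(-extent, extent, n)
    return ax, ax.copy()


@dataclass(frozen=True, eq=False)
class FieldGrid:
    """Surface temperature-increase field sampled on a rectangular grid.

    ``values[i, j]`` is the increment at ``(x_axis[j], y_axis[i])`` in deg C.
    """

    x_axis: np.ndarray
    y_axis: np.ndarray
    values: np.ndarray
    scales: ThermalScales
    z0a: float

    def __post_init__(self) -> None:
        x, y, v = self.x_axis, self.y_axis, self.values
        if np.any(np.diff(x) <= 0) or np.any(np.diff(y) <= 0):
            raise ValueError("grid axes must be strictly increasing")
        if v.shape != (y.size, x.size):
            raise ValueError(
                f"values shape {v.shape} does not match axes ({y.size}, {x.size})"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("grid contains non-finite values")

    def interpolate(self, x, y):
        """Bilinear interpolation of the field at (x, y)."""
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (self.y_axis, self.x_axis), self.values, method="linear"
        )
        pts = np.stack(np.broadcast_arrays(np.asarray(y, float), np.asarray(x, float)), axis=-1)
        out = interp(pts)
        if np.ndim(x) == 0 and np.ndim(y) == 0:
            return float(out.reshape(()))
        return out


@dataclass(frozen=True)
class IsothermSet:
    """Contours per temperature level; polylines are (N, 2) arrays of (x, y)."""

    levels: tuple
    contours: dict
    warnings: tuple = ()


@dataclass(frozen=True)
class HomogeneityReport:
    """Flatness metrics of the field over a central probe disc."""

    center_value: float
    max_abs_deviation: float
    probe_radius: float
    epsilon: float
    homogeneous_area_fraction: float

    def to_dict(self) -> dict:
        return {
            "center_value_C": self.center_value,
            "max_abs_deviation_C": self.max_abs_deviation,
            "probe_radius_a": self.probe_radius,
            "epsilon_C": self.epsilon,
            "homogeneous_area_fraction": self.homogeneous_area_fraction,
        }


def _combined_surface(scales: ThermalScales, z0a: float, x, y):
    """t1*square + t2*ring on broadcastable surface coordinates."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    out = np.zeros(np.broadcast(x, y).shape)
    if scales.t1 != 0.0:
        # unguarded closed form: exact-corner grid nodes take the continuous
        # limit instead of raising DegeneratePointError
        out = out + scales.t1 * np.asarray(_surface_limit(x, y))
    if scales.t2 != 0.0:
        out = out + scales.t2 * np.asarray(
            ring_shape_exact(np.hypot(x, y), 0.0, z0a)
        )
    if out.ndim == 0:
        return float(out)
    return out


def total_surface_field(
    scales: ThermalScales,
    z0a: float = 0.02,
    x_axis: np.ndarray | None = None,
    y_axis: np.ndarray | None = None,
) -> FieldGrid:
    """Evaluate the combined surface field ``t1*square + t2*ring`` on a grid.

    ``z0a`` is the reduced ring standoff; a small positive value keeps grid
    nodes at radius 1/2 off the wire singularity.  Default axes are 201 nodes
    over [-1, 1] in units of ``a``.
    """
    if x_axis is None or y_axis is None:
        dx, dy = default_axes()
        x_axis = dx if x_axis is None else np.asarray(x_axis, float)
        y_axis = dy if y_axis is None else np.asarray(y_axis, float)
    else:
        x_axis = np.asarray(x_axis, float)
        y_axis = np.asarray(y_axis, float)
    xx, yy = np.meshgrid(x_axis, y_axis)
    try:
        values = _combined_surface(scales, z0a, xx, yy)
    except Exception as exc:  # annotate with grid context
        raise type(exc)(f"{exc} (while evaluating grid field, z0a={z0a})") from exc
    values = np.asarray(values, float)
    if values.ndim == 0:
        values = np.full((y_axis.size, x_axis.size), float(values))
    return FieldGrid(x_axis=x_axis, y_axis=y_axis, values=values, scales=scales, z0a=z0a)


def axis_profile(
    scales: ThermalScales,
    z0a: float = 0.02,
    axis: str = "x",
    s_values: np.ndarray | None = None,
) -> np.ndarray:
    """Per-source contributions and total along the x or y axis.

    Returns a structured array with fields ``s``, ``dT1``, ``dT2``, ``dT``
    (all deg C except ``s``, in units of ``a``).  By symmetry x and y profiles
    of both sources coincide, but the parameter is honored for clarity.
    """
    if axis not in ("x", "y"):
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    if s_values is None:
        s_values = np.linspace(-1.0, 1.0, DEFAULT_GRID_N)
    s = np.asarray(s_values, float)
    if not np.all(np.isfinite(s)):
        raise ValueError("s_values must be finite")
    x = s if axis == "x" else np.zeros_like(s)
    y = np.zeros_like(s) if axis == "x" else s
    d1 = scales.t1 * np.asarray(square_shape_surface(x, y))
    d2 = scales.t2 * np.asarray(ring_shape_exact(np.abs(s), 0.0, z0a))
    out = np.zeros(
        s.shape, dtype=[("s", float), ("dT1", float), ("dT2", float), ("dT", float)]
    )
    out["s"] = s
    out["dT1"] = d1
    out["dT2"] = d2
    out["dT"] = d1 + d2
    return out


def extract_isotherms(grid: FieldGrid, levels) -> IsothermSet:
    """Marching-squares isotherms of a field grid at the given delta-T levels.

    Contour vertices are linearly interpolated along cell edges and mapped to
    grid coordinates; levels outside the grid's value range produce an empty
    contour list plus a warning record instead of an error.
    """
    levels = tuple(float(lv) for lv in np.atleast_1d(levels))
    vmin, vmax = float(grid.values.min()), float(grid.values.max())
    contours: dict = {}
    notes = []
    for lv in levels:
        if not (vmin <= lv <= vmax):
            notes.append(
                f"level {lv:g} outside grid range [{vmin:g}, {vmax:g}]; no contours"
            )
            contours[lv] = []
            continue
        raw = measure.find_contours(grid.values, lv)
        polys = []
        idx_y = np.arange(grid.y_axis.size)
        idx_x = np.arange(grid.x_axis.size)
        for arr in raw:
            xs = np.interp(arr[:, 1], idx_x, grid.x_axis)
            ys = np.interp(arr[:, 0], idx_y, grid.y_axis)
            polys.append(np.column_stack([xs, ys]))
        contours[lv] = polys
    if notes:
        warnings.warn("; ".join(notes), stacklevel=2)
    return IsothermSet(levels=levels, contours=contours, warnings=tuple(notes))


def homogeneity_report(
    field,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    epsilon: float = DEFAULT_EPSILON,
    z0a: float | None = None,
) -> HomogeneityReport:
    """Quantify field flatness over the central disc of reduced radius ``probe_radius``.

    ``field`` is either a :class:`FieldGrid` (grid nodes inside the disc are
    probed; the center value is re-evaluated exactly from the grid's scales)
    or a callable ``f(x, y)`` (probed on a dense polar lattice).
    """
    if probe_radius <= 0.0:
        raise ValueError("probe_radius must be positive")
    if isinstance(field, FieldGrid):
        center = _combined_surface(field.scales, field.z0a, 0.0, 0.0)
        xx, yy = np.meshgrid(field.x_axis, field.y_axis)
        mask = xx**2 + yy**2 <= probe_radius**2
        if not np.any(mask):
            raise ValueError("probe disc contains no grid nodes")
        samples = field.values[mask]
    else:
        radii = np.linspace(0.0, probe_radius, 81)[1:]
        angles = np.linspace(0.0, 2.0 * np.pi, 121, endpoint=False)
        rr, aa = np.meshgrid(radii, angles)
        xs = rr * np.cos(aa)
        ys = rr * np.sin(aa)
        center = float(field(0.0, 0.0))
        samples = np.asarray(
            [field(float(x), float(y)) for x, y in zip(xs.ravel(), ys.ravel())]
        )
        samples = np.append(samples, center)
    dev = np.abs(samples - center)
    return HomogeneityReport(
        center_value=float(center),
        max_abs_deviation=float(dev.max()),
        probe_radius=float(probe_radius),
        epsilon=float(epsilon),
        homogeneous_area_fraction=float(np.mean(dev <= epsilon)),
    )


def _fmt(v: float) -> str:
    return f"{v:.9g}"


def grid_to_long_csv(grid: FieldGrid) -> str:
    """Long-format CSV: one ``x,y,delta_T_C`` row per node, 9 significant digits."""
    buf = io.StringIO()
    buf.write("x,y,delta_T_C\n")
    for i, y in enumerate(grid.y_axis):
        for j, x in enumerate(grid.x_axis):
            buf.write(f"{_fmt(x)},{_fmt(y)},{_fmt(grid.values[i, j])}\n")
    return buf.getvalue()


def grid_to_matrix_csv(grid: FieldGrid) -> str:
    """Compact matrix CSV: header row of x, then one row per y: y, values..."""
    buf = io.StringIO()
    buf.write("y\\x," + ",".join(_fmt(x) for x in grid.x_axis) + "\n")
    for i, y in enumerate(grid.y_axis):
        buf.write(_fmt(y) + "," + ",".join(_fmt(v) for v in grid.values[i]) + "\n")
    return buf.getvalue()


def isotherms_to_csv(isos: IsothermSet) -> str:
    """CSV with header ``level_C,contour_id,vertex_id,x,y``."""
    buf = io.StringIO()
    buf.write("level_C,contour_id,vertex_id,x,y\n")
    for lv in isos.levels:
        for cid, poly in enumerate(isos.contours[lv]):
            for vid, (x, y) in enumerate(poly):
                buf.write(f"{_fmt(lv)},{cid},{vid},{_fmt(x)},{_fmt(y)}\n")
    return buf.getvalue()
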