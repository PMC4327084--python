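"""JSON configuration loading and validation for the simulator CLI.

A config parameterizes each heater either electrically (media conductivities
plus square/ring electrical parameters) or directly through the thermal
scales (t1, t2), mirroring the two entry points of the API.  Exactly one of
the two parameterizations must be present per heater.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from planarheat.sources import (
    Media,
    RingHeater,
    SquareHeater,
    ThermalScales,
    ValidationError,
)

__all__ = ["ConfigError", "SimulationConfig", "load_config", "resolve_config"]

# keys accepted at each level; used for validation and CLI flag generation
SQUARE_KEYS = ("a", "d", "rho", "U")
RING_KEYS = ("a", "z0", "S", "R", "U")
SCALE_KEYS = ("T0", "t1", "t2")
SIM_KEYS = ("grid_n", "extent", "z0a", "probe_radius", "epsilon", "levels")


class ConfigError(ValueError):
    """Invalid configuration; ``key`` names the offending entry."""

    def __init__(self, key: str, message: str):
        super().__init__(f"config key '{key}': {message}")
        self.key = key


@dataclass
class SimulationConfig:
    """Fully resolved simulation inputs."""

    scales: ThermalScales
    z0a: float = 0.02
    grid_n: int = 201
    extent: float = 1.0
    probe_radius: float = 0.2
    epsilon: float = 0.1
    levels: list = field(default_factory=list)
    raw: dict = field(default_factory=dict)


def _get_number(d: dict, key: str, qualified: str) -> float:
    if key not in d:
        raise ConfigError(qualified, "missing required key")
    v = d[key]
    if not isinstance(v, (int, float)) or isinstance(v, bool):
        raise ConfigError(qualified, f"expected a number, got {v!r}")
    return float(v)


def resolve_config(raw: dict) -> SimulationConfig:
    """Validate a raw config dict and resolve it to thermal scales + settings."""
    if not isinstance(raw, dict):
        raise ConfigError("<root>", "config must be a JSON object")

    has_scales = "scales" in raw
    has_square = "square" in raw
    has_ring = "ring" in raw

    if has_scales and (has_square or has_ring):
        raise ConfigError(
            "scales", "provide either 'scales' or electrical heater blocks, not both"
        )
    if not has_scales and not (has_square or has_ring):
        raise ConfigError(
            "scales", "config must contain 'scales' or at least one heater block"
        )

    try:
        if has_scales:
            block = raw["scales"]
            if not isinstance(block, dict):
                raise ConfigError("scales", "must be an object")
            for k in block:
                if k not in SCALE_KEYS:
                    raise ConfigError(f"scales.{k}", "unknown key")
            scales = ThermalScales(
                T0=float(block.get("T0", 0.0)),
                t1=float(block.get("t1", 0.0)),
                t2=float(block.get("t2", 0.0)),
            )
        else:
            kappa_e = _get_number(raw, "kappa_e", "kappa_e")
            kappa_i = _get_number(raw, "kappa_i", "kappa_i")
            media = Media(kappa_e=kappa_e, kappa_i=kappa_i)
            square = ring = None
            if has_square:
                sq = raw["square"]
                square = SquareHeater(
                    a=_get_number(sq, "a", "square.a"),
                    d=_get_number(sq, "d", "square.d"),
                    rho=_get_number(sq, "rho", "square.rho"),
                    U=_get_number(sq, "U", "square.U"),
                )
            if has_ring:
                rg = raw["ring"]
                a_ring = rg.get("a", raw.get("square", {}).get("a"))
                if a_ring is None:
                    raise ConfigError("ring.a", "missing required key")
                ring = RingHeater(
                    a=float(a_ring),
                    z0=_get_number(rg, "z0", "ring.z0"),
                    S=_get_number(rg, "S", "ring.S"),
                    R_total=_get_number(rg, "R", "ring.R"),
                    U=_get_number(rg, "U", "ring.U"),
                )
            scales = ThermalScales.from_heaters(
                media, square=square, ring=ring, T0=float(raw.get("T0", 0.0))
            )
    except ValidationError as exc:
        raise ConfigError("<heater>", str(exc)) from exc

    sim = raw.get("sim", {})
    if not isinstance(sim, dict):
        raise ConfigError("sim", "must be an object")
    for k in sim:
        if k not in SIM_KEYS:
            raise ConfigError(f"sim.{k}", "unknown key")
    # z0a: explicit sim value wins; otherwise derive from ring geometry
    z0a = sim.get("z0a")
    if z0a is None:
        if has_ring and "z0" in raw.get("ring", {}) and "a" in raw.get("ring", {}):
            z0a = float(raw["ring"]["z0"]) / float(raw["ring"]["a"])
        else:
            z0a = 0.02
    z0a = float(z0a)
    if z0a < 0:
        raise ConfigError("sim.z0a", "must be >= 0")
    grid_n = int(sim.get("grid_n", 201))
    if grid_n < 3:
        raise ConfigError("sim.grid_n", "must be >= 3")
    extent = float(sim.get("extent", 1.0))
    if extent <= 0:
        raise ConfigError("sim.extent", "must be > 0")
    probe_radius = float(sim.get("probe_radius", 0.2))
    if not (0 < probe_radius):
        raise ConfigError("sim.probe_radius", "must be > 0")
    epsilon = float(sim.get("epsilon", 0.1))
    if epsilon <= 0:
        raise ConfigError("sim.epsilon", "must be > 0")
    levels = sim.get("levels", [])
    if not isinstance(levels, list) or not all(
        isinstance(v, (int, float)) and not isinstance(v, bool) for v in levels
    ):
        raise ConfigError("sim.levels", "must be a list of numbers")

    return SimulationConfig(
        scales=scales,
        z0a=z0a,
        grid_n=grid_n,
        extent=extent,
        probe_radius=probe_radius,
        epsilon=epsilon,
        levels=[float(v) for v in levels],
        raw=raw,
    )


def load_config(path: str | Path, overrides: dict | None = None) -> SimulationConfig:
    """Read a JSON config file, apply dotted-key overrides, and resolve it."""
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError("<file>", f"not valid JSON: {exc}") from exc
    if overrides:
        for dotted, value in overrides.items():
            node = raw
            parts = dotted.split(".")
            for p in parts[:-1]:
                node = node.setdefault(p, {})
                if not isinstance(node, dict):
                    raise ConfigError(dotted, "override path crosses a non-object")
            node[parts[-1]] = value
    return resolve_config(raw)
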