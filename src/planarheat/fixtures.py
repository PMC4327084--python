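"""Seeded generator of randomized, physically valid parameter sets for tests.

Physics code contains no randomness; all stochastic content lives here, driven
by a named, seedable generator so identical seeds yield byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["FixtureSpec", "generate_fixtures", "fixtures_json"]

DEFAULT_RANGES = {
    "kappa_e": (0.02, 0.05),      # gases
    "kappa_i": (0.2, 0.7),        # soft tissue
    "square.a": (0.005, 0.05),    # 5-50 mm heater
    "square.d_over_a": (1e-4, 0.05),
    "square.rho": (1e-6, 1e-3),
    "square.U": (0.1, 5.0),
    "ring.z0_over_a": (0.005, 0.08),
    "ring.S": (1e-9, 1e-7),
    "ring.R": (0.5, 50.0),
    "ring.U": (0.1, 5.0),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Reproducible fixture request: same seed -> identical cases."""

    seed: int
    n_cases: int = 10
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        for key in DEFAULT_RANGES:
            lo, hi = self.ranges.get(key, DEFAULT_RANGES[key])
            if not (0 < lo <= hi):
                raise ValueError(f"range for {key} must satisfy 0 < lo <= hi")


def _uniform(rng: np.random.Generator, bounds) -> float:
    lo, hi = bounds
    return float(rng.uniform(lo, hi))


def generate_fixtures(spec: FixtureSpec) -> list[dict]:
    """Draw ``n_cases`` valid electrical configs from the spec's ranges."""
    rng = np.random.default_rng(spec.seed)
    r = {**DEFAULT_RANGES, **spec.ranges}
    cases = []
    for i in range(spec.n_cases):
        a = _uniform(rng, r["square.a"])
        case = {
            "case_id": i,
            "kappa_e": _uniform(rng, r["kappa_e"]),
            "kappa_i": _uniform(rng, r["kappa_i"]),
            "square": {
                "a": a,
                "d": a * _uniform(rng, r["square.d_over_a"]),
                "rho": _uniform(rng, r["square.rho"]),
                "U": _uniform(rng, r["square.U"]),
            },
            "ring": {
                "a": a,
                "z0": a * _uniform(rng, r["ring.z0_over_a"]),
                "S": _uniform(rng, r["ring.S"]),
                "R": _uniform(rng, r["ring.R"]),
                "U": _uniform(rng, r["ring.U"]),
            },
        }
        cases.append(case)
    return cases


def fixtures_json(spec: FixtureSpec) -> str:
    """Deterministic JSON serialization (sorted keys, fixed float repr)."""
    return json.dumps(generate_fixtures(spec), indent=2, sort_keys=True)
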