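import json
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from planarheat import ThermalScales, total_surface_field

#: exact center value of the square-sheet potential: 4 ln(1 + sqrt 2)
SQUARE_CENTER = 4.0 * np.log(1.0 + np.sqrt(2.0))

#: the documented example scenario: t1 = 0.65, t2 = 0.5
FIG_T1 = 0.65
FIG_T2 = 0.5


@pytest.fixture(scope="session")
def fig_scales():
    return ThermalScales(T0=0.0, t1=FIG_T1, t2=FIG_T2)


@pytest.fixture(scope="session")
def fig_grid(fig_scales):
    """Combined field on the default 201x201 grid at z0a = 0.02."""
    return total_surface_field(fig_scales, z0a=0.02)


@pytest.fixture
def scales_config(tmp_path):
    """Write a scales-parameterized JSON config and return its path."""

    def _write(t1=FIG_T1, t2=FIG_T2, T0=39.1, **sim):
        cfg = {"scales": {"T0": T0, "t1": t1, "t2": t2}}
        if sim:
            cfg["sim"] = sim
        p = tmp_path / "config.json"
        p.write_text(json.dumps(cfg))
        return p

    return _write
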