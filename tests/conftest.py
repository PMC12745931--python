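"""Shared fixtures: small nests, grids and boundary helpers.

Everything is generated programmatically; expensive objects are session-
scoped so the suite builds each of them once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nestherm import thermal as th
from nestherm.config import with_overrides
from nestherm.geometry import build_domain, pack_eggs
from nestherm.synthetic import make_reference_nest


def all_faces_dirichlet(grid: th.SimulationGrid, values: np.ndarray) -> dict:
    """Dirichlet on every face; ``values`` is (n_times,) broadcast per cell."""
    nx, ny, nz = grid.shape
    n_cells = {"x": ny * nz, "y": nx * nz, "z": nx * ny}
    return {
        face: th.FaceBC(np.repeat(values[:, None], n_cells[face[0]], axis=1))
        for face in th._FACES
    }


@pytest.fixture(scope="session")
def small_geometry():
    return build_domain(0.60, 51)


@pytest.fixture(scope="session")
def packed_layout(small_geometry):
    return pack_eggs(small_geometry, 51, seed=1)


@pytest.fixture(scope="session")
def small_config():
    """A 3-day, 12-egg configuration for fast end-to-end runs."""
    cfg = make_reference_nest(seed=3)
    return with_overrides(
        cfg,
        geometry={"clutch_size": 12, "nest_depth_m": 0.50},
        scenario={"duration_days": 3.0},
    )


@pytest.fixture(scope="session")
def small_run(small_config):
    from nestherm.run import run_nest

    return run_nest(small_config)


@pytest.fixture
def hourly_series():
    def make(values, start="2020-12-01"):
        values = np.asarray(values, dtype=float)
        idx = pd.date_range(start, periods=len(values), freq="h")
        return pd.Series(values, index=idx)

    return make
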