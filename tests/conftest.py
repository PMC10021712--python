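import warnings

import numpy as np
import pandas as pd
import pytest

warnings.filterwarnings("ignore", message=".*ArviZ is undergoing.*")

from smrmap.io_geo import Adjacency  # noqa: E402
from smrmap.synthetic import SimulationConfig, simulate_study  # noqa: E402


@pytest.fixture
def path_graph():
    """Path graph 1-2-3-4 with values (1, 2, 3, 4): Moran's I = 1/3."""
    adj = Adjacency.from_pairs(["1", "2", "3", "4"], [("1", "2"), ("2", "3"), ("3", "4")])
    values = pd.Series([1.0, 2.0, 3.0, 4.0], index=["1", "2", "3", "4"])
    return values, adj


@pytest.fixture
def checkerboard():
    """2x2 rook lattice with checkerboard values: Moran's I = -1."""
    adj = Adjacency.from_pairs(
        ["a", "b", "c", "d"], [("a", "b"), ("a", "c"), ("b", "d"), ("c", "d")]
    )
    values = pd.Series([1.0, 0.0, 0.0, 1.0], index=["a", "b", "c", "d"])
    return values, adj


@pytest.fixture(scope="session")
def small_study():
    """6x6 lattice study, independent risks — shared across read-only tests."""
    cfg = SimulationConfig(grid_shape=(6, 6), n_middle=9, n_top=9, seed=42)
    return simulate_study(cfg)


def rook_lattice(rows: int, cols: int) -> Adjacency:
    ids = [f"{r}_{c}" for r in range(rows) for c in range(cols)]
    pairs = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                pairs.append((f"{r}_{c}", f"{r}_{c + 1}"))
            if r + 1 < rows:
                pairs.append((f"{r}_{c}", f"{r + 1}_{c}"))
    return Adjacency.from_pairs(ids, pairs)


def moran_bruteforce(x: np.ndarray, w: np.ndarray) -> float:
    """Literal double-loop Moran's I, the independent oracle."""
    n = len(x)
    z = x - x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * z[i] * z[j]
            s0 += w[i, j]
    return (num / s0) / (sum(zi * zi for zi in z) / n)
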