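import numpy as np
import pytest

from effdist import CostRaster, FocalNodes, VariogramSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_raster(rng):
    """Random 6x6 cost raster with full-range values."""
    v = rng.integers(1, 1001, size=(6, 6))
    v[0, 0], v[-1, -1] = 1, 1000
    return CostRaster(v)


@pytest.fixture
def chain_raster():
    """1-D chain embedded as costs (2, 4, 6) — wrapped where a square grid
    is required, tests build the 1x3 case directly from edge lists."""
    return np.array([2.0, 4.0, 6.0])


@pytest.fixture
def spec():
    return VariogramSpec(sill=0.025, range_param=10.0)


def corner_nodes(dim: int) -> FocalNodes:
    """Two opposite-corner focal nodes for a dim x dim raster."""
    return FocalNodes(np.array([[0, 0], [dim - 1, dim - 1]]))
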