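import numpy as np
import pytest

from mspkit import AnalysisGrid, GridLayer, make_grid
from mspkit.synthetic import SyntheticSpec, build_case_study

CRS = "EPSG:3035"


@pytest.fixture
def grid20():
    """20 x 20 cells: 10 km x 10 km at the 500 m reference resolution."""
    return make_grid((0.0, 0.0, 10_000.0, 10_000.0), 500.0, CRS)


@pytest.fixture
def grid4():
    return make_grid((0.0, 0.0, 2_000.0, 2_000.0), 500.0, CRS)


@pytest.fixture
def layer_factory():
    def make(values, grid, name="layer"):
        return GridLayer(name, np.asarray(values, dtype=float), grid)

    return make


@pytest.fixture(scope="session")
def synthetic_case():
    return build_case_study(SyntheticSpec(seed=0))


def masked_grid(grid: AnalysisGrid, mask: np.ndarray) -> AnalysisGrid:
    return AnalysisGrid(grid.extent, grid.resolution, grid.crs, mask)
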