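import numpy as np
import pytest

from rangeshift import synth
from rangeshift.grids import GridDefinition, PredictorStack, RasterGrid


@pytest.fixture
def small_grid() -> GridDefinition:
    return GridDefinition(
        n_rows=10, n_cols=10, x_min=100.0, y_max=30.0,
        cell_width=0.1, cell_height=0.1,
    )


@pytest.fixture
def gradient_raster(small_grid) -> RasterGrid:
    """Values increase left to right: column index broadcast over rows."""
    values = np.tile(np.arange(10, dtype=float), (10, 1))
    return RasterGrid(values=values, grid=small_grid)


@pytest.fixture(scope="session")
def default_world():
    """The package's default simulated world (single strong niche on Bio7)."""
    return synth.simulate_dataset(None, seed=1)


@pytest.fixture
def tiny_stack(small_grid) -> PredictorStack:
    stack = PredictorStack()
    rng = np.random.default_rng(0)
    for name in ("Bio7", "Bio12"):
        stack.add(name, RasterGrid(values=rng.random((10, 10)), grid=small_grid))
    return stack
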