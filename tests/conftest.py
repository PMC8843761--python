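import numpy as np
import pytest

from kernelscape.raster import RasterGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_grid():
    """10x10 grid with 1-m cells at the origin (convenient for hand math)."""
    return RasterGrid(np.zeros((10, 10)), cell_size=1.0, origin=(0.0, 10.0))


def make_grid(values, cell_size=1.0):
    values = np.asarray(values, dtype=float)
    return RasterGrid(values, cell_size=cell_size,
                      origin=(0.0, values.shape[0] * cell_size))
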