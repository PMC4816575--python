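import numpy as np
import pytest

from cloudclim.grid import GeoGrid, GridTransform


@pytest.fixture
def transform():
    return GridTransform(0.0, 0.0, 0.01, 0.01)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_grid(values, mask=None, transform=GridTransform(0.0, 0.0, 0.01, 0.01)):
    return GeoGrid(np.asarray(values, float), mask=mask, transform=transform)
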