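import numpy as np
import pytest

from fieldspat.design import SpatialDesign, full_grid, sample_locations


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def grid5():
    """All 25 cells of a 5x5 grid."""
    return full_grid(5)


@pytest.fixture
def design100():
    """A 100-point sample of the 15x15 training grid."""
    return sample_locations(15, 100, 42)


@pytest.fixture
def pair_at_distance():
    """Factory: a 2-point design separated by a given distance along x."""

    def make(d):
        G = int(np.ceil(d)) + 1
        return SpatialDesign(G, np.array([[1.0, 1.0], [1.0 + d, 1.0]]))

    return make
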