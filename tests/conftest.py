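import numpy as np
import pytest

from eventseg import build_adjacency, grid_coordinates


@pytest.fixture(scope="session")
def grid10():
    """10x10x10 lattice at 0.5 cm with its 6-connectivity adjacency."""
    coords = grid_coordinates((10, 10, 10), 0.5)
    return coords, build_adjacency(coords)


@pytest.fixture(scope="session")
def grid5():
    coords = grid_coordinates((5, 5, 5), 0.5)
    return coords, build_adjacency(coords)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
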