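import numpy as np
import pytest

from gclayer import anatomy


@pytest.fixture(scope="session")
def geom():
    """Default-sized local network geometry (180 MFs, 480 GCs, 40 um ball)."""
    return anatomy.place_cells(seed=11)


@pytest.fixture(scope="session")
def conn4(geom):
    return anatomy.wire_network(geom, 4, seed=12)


@pytest.fixture(scope="session")
def conn16(geom):
    return anatomy.wire_network(geom, 16, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
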