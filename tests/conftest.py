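import numpy as np
import pytest

from cortexdyn import make_geometry, simulate_smooth_map


@pytest.fixture(scope="session")
def geom60():
    return make_geometry(60, seed=7)


@pytest.fixture(scope="session")
def geom180():
    return make_geometry(180, seed=1)


@pytest.fixture(scope="session")
def smooth_pair(geom60):
    a = simulate_smooth_map(geom60, 0.3, seed=11)
    b = simulate_smooth_map(geom60, 0.3, seed=12)
    return a, b


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def freq_grid(lo=1.0, hi=65.0):
    n = int(round((hi - lo) / 0.1)) + 1
    return lo + 0.1 * np.arange(n)
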