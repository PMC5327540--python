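import numpy as np
import pytest

from eyeshine.spectral import DEFAULT_GRID, SpectralCurve


@pytest.fixture
def grid():
    return DEFAULT_GRID.copy()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def flat_curve(grid):
    return SpectralCurve(grid, np.ones_like(grid), quantity="photon_radiance")
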