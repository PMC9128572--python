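import numpy as np
import pytest

from erocio import GaussianSignalParams, ImagingSystem, PixelGrid


@pytest.fixture
def grid16():
    return PixelGrid(16, 16)


@pytest.fixture
def bke_system():
    """The amplitude-study system: h = 16, w_m = 3.87 on a 64x64 grid."""
    return ImagingSystem(grid=PixelGrid(64, 64), h=16.0, w_m=3.87)


@pytest.fixture
def small_system(grid16):
    return ImagingSystem(grid=grid16, h=2.0, w_m=1.5)


@pytest.fixture
def center_signal():
    return GaussianSignalParams(A_s=9.0, w_s=1.0, r_s=(32.0, 32.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
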