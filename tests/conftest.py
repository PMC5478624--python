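import numpy as np
import pytest

from seedbed3d import CameraIntrinsics, HeightField


@pytest.fixture
def intrinsics() -> CameraIntrinsics:
    """A simple symmetric calibration used across geometry tests."""
    return CameraIntrinsics(fx_d=580.0, fy_d=580.0, cx=320.0, cy=240.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_field(z, pitch=1.0, valid=None) -> HeightField:
    return HeightField(z=np.asarray(z, dtype=float), pitch_x=pitch, pitch_y=pitch,
                       valid=valid)


@pytest.fixture
def sine_field() -> HeightField:
    """Amplitude-3 sinusoid over exactly 8 whole periods, finely sampled.

    Cosine phase centred on the grid keeps the wave exactly orthogonal to a
    linear trend, so plane detrending is neutral.
    """
    n = 4096
    x = (np.arange(n) + 0.5) / n  # cell-centred samples over [0, 1)
    z = 3.0 * np.cos(2 * np.pi * 8 * x)
    return make_field(np.tile(z, (4, 1)))


@pytest.fixture
def two_level_field() -> HeightField:
    """Alternating +/-1 mm checkerboard-style surface."""
    z = np.fromfunction(lambda i, j: np.where((i + j) % 2 == 0, 1.0, -1.0), (20, 20))
    return make_field(z)
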