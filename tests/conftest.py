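import numpy as np
import pytest

from lithotex.heightmap import HeightMap
from lithotex.synth import GeneratorConfig


@pytest.fixture
def flat_map():
    return HeightMap(np.zeros((100, 100)), spacing=0.05)


@pytest.fixture
def sinusoid_map():
    """1-D sinusoid along x: amplitude 0.1 mm, period 1 mm."""

    def make(amplitude=0.1, period=1.0, orientation_deg=0.0, n=200, spacing=0.025):
        x = np.arange(n) * spacing
        X, Y = np.meshgrid(x, x)
        th = np.deg2rad(orientation_deg)
        u = -X * np.sin(th) + Y * np.cos(th)
        return HeightMap(amplitude * np.sin(2 * np.pi * u / period), spacing)

    return make


@pytest.fixture
def fast_cfg():
    """Small, coarse substrate for fast generator tests (5 x 5 mm at 50 um)."""
    return GeneratorConfig(size_mm=(5.0, 5.0), spacing=0.05, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
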