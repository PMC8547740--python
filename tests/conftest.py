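import numpy as np
import pytest

from asymtopo.grid import VoxelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def bump_field(shape, bumps):
    """Sum of Gaussian bumps: bumps = [(center, sigma_vox, amplitude), ...]."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    out = np.zeros(shape)
    for center, sigma, amp in bumps:
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        out += amp * np.exp(-d2 / (2.0 * sigma ** 2))
    return out


@pytest.fixture
def make_bump_grid():
    def _make(shape, bumps, **kwargs):
        return VoxelGrid(bump_field(shape, bumps), **kwargs)

    return _make


@pytest.fixture
def random_int_grid(rng):
    """Factory for small random integer-valued grids (tie-rich)."""

    def _make(shape=(5, 5, 5), low=-5, high=6):
        return VoxelGrid(rng.integers(low, high, size=shape).astype(float))

    return _make
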