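import numpy as np
import pytest

from luquant import (ProtocolConfig, PSFModel, VoxelGrid)
from luquant.projector import Projector


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cylinder():
    """A small water cylinder with an off-centre hot rod; grid divisible by 2
    so it can feed the coarse-grid scatter estimator."""
    shape = (32, 32, 16)
    ref = VoxelGrid(np.zeros(shape), 4.8)
    cx, cy, cz = ref.coords_mm()
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    body = (gx**2 + gy**2 <= 60.0**2).astype(float)[:, :, None] * np.ones(shape[2])
    rod = ((gx - 20) ** 2 + (gy + 10) ** 2 <= 15.0**2).astype(float)[:, :, None] \
        * np.ones(shape[2])
    activity = VoxelGrid(0.05 * body + 1.0 * rod * body, 4.8)
    mu = VoxelGrid(0.137 * body, 4.8)
    return activity, mu


@pytest.fixture
def small_protocol():
    return ProtocolConfig(n_views=16, dwell_s=20.0, pixel_mm=4.8,
                          orbit_radii_cm=np.full(16, 12.0))


@pytest.fixture
def small_projector(small_cylinder, small_protocol):
    _, mu = small_cylinder
    return Projector(mu, small_protocol, PSFModel())
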