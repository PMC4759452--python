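"""System model: HU conversion, PSF, and the matched projector pair."""

import numpy as np
import pytest

from luquant import (MuConversion, ProtocolConfig, PSFModel, VoxelGrid,
                     psf_sigma_mm)
from luquant.projector import Projector, forward_project, hu_to_mu

from _oracles import ray_march_axis0_view


class TestHuToMu:
    def test_water_and_air_anchors(self):
        conv = MuConversion()
        assert hu_to_mu(0.0, conv) == pytest.approx(0.137, abs=1e-12)
        assert hu_to_mu(-1000.0, conv) == 0.0

    def test_continuous_at_breakpoint(self):
        conv = MuConversion(hu_breakpoint=50.0)
        below = hu_to_mu(50.0 - 1e-9, conv)
        above = hu_to_mu(50.0 + 1e-9, conv)
        assert below == pytest.approx(above, abs=1e-9)

    def test_clamped_at_zero_and_vectorized(self):
        out = hu_to_mu(np.array([-2000.0, -1000.0, 0.0, 1000.0]))
        assert out[0] == 0.0 and out.shape == (4,)
        assert np.all(np.diff(out) >= 0)


class TestPsfSigma:
    def test_intercept_and_degenerate_slope(self):
        psf = PSFModel(fwhm0_mm=4.0, slope_mm_per_cm=0.0)
        sig0 = psf_sigma_mm(0.0, psf)
        assert sig0 == pytest.approx(4.0 / (2 * np.sqrt(2 * np.log(2))))
        assert psf_sigma_mm(30.0, psf) == sig0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            psf_sigma_mm(-1.0, PSFModel())

    @pytest.mark.parametrize("distance_cm", [0.0, 10.0, 25.0])
    def test_fwhm_recovered_by_half_maximum_search(self, distance_cm):
        # numeric FWHM oracle: sample the Gaussian finely, measure half-max width
        psf = PSFModel(fwhm0_mm=4.0, slope_mm_per_cm=0.5)
        sigma = psf_sigma_mm(distance_cm, psf)
        x = np.linspace(-60, 60, 200001)
        g = np.exp(-(x**2) / (2 * sigma**2))
        width = np.ptp(x[g >= 0.5])
        assert width == pytest.approx(4.0 + 0.5 * distance_cm, rel=1e-3)


def _protocol(n_views=4, radius=12.0):
    return ProtocolConfig(n_views=n_views, orbit_radii_cm=np.full(n_views, radius))


class TestForwardProjection:
    def test_zero_activity_gives_zero_projection(self):
        act = VoxelGrid(np.zeros((16, 16, 8)), 4.8)
        mu = VoxelGrid(0.1 * np.ones((16, 16, 8)), 4.8)
        proj = forward_project(act, mu, 0, _protocol())
        assert np.all(proj == 0.0)

    def test_single_voxel_no_attenuation_matches_ray_march(self, rng):
        act = np.zeros((16, 16, 8))
        act[5, 9, 3] = 1.0
        grid = VoxelGrid(act, 4.8)
        proj = forward_project(grid, None, 0, _protocol(), include_attenuation=False,
                               include_psf=False)
        oracle = ray_march_axis0_view(act, np.zeros_like(act), 4.8, attenuate=False)
        np.testing.assert_allclose(proj, oracle, atol=1e-6 * oracle.max())

    def test_attenuated_voxel_matches_hand_computed_line_integral(self):
        # unit voxel at depth inside uniform mu: attenuation factor is
        # exp(-mu * (n_voxels_to_exit - 1/2) * dl), written out by hand
        act = np.zeros((16, 16, 8))
        act[7, 4, 3] = 1.0
        mu_val = 0.12
        mu = VoxelGrid(mu_val * np.ones_like(act), 4.8)
        proj = forward_project(VoxelGrid(act, 4.8), mu, 0, _protocol(),
                               include_psf=False)
        n_exit = 16 - 1 - 4  # voxels between source plane and +y exit
        expected = (4.8**3 / 1000.0) * np.exp(-mu_val * (n_exit + 0.5) * 0.48)
        assert proj[7, 3] == pytest.approx(expected, rel=1e-9)
        assert proj.sum() == pytest.approx(expected, rel=1e-9)

    def test_random_volume_matches_ray_march_oracle(self, rng):
        act = rng.uniform(size=(12, 12, 6))
        mu = rng.uniform(0, 0.2, size=(12, 12, 6))
        proj = forward_project(VoxelGrid(act, 4.8), VoxelGrid(mu, 4.8), 0,
                               _protocol(), include_psf=False)
        oracle = ray_march_axis0_view(act, mu, 4.8)
        np.testing.assert_allclose(proj, oracle, rtol=1e-9)

    def test_linearity(self, small_projector, rng):
        x = rng.uniform(size=small_projector.shape)
        z = rng.uniform(size=small_projector.shape)
        lhs = small_projector.forward(2.0 * x + 3.0 * z, 1)
        rhs = 2.0 * small_projector.forward(x, 1) + 3.0 * small_projector.forward(z, 1)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-10, atol=1e-12)

    def test_attenuation_never_increases_pixels(self, small_cylinder, small_protocol, rng):
        act, mu = small_cylinder
        with_att = Projector(mu, small_protocol, None)
        without = Projector(None, small_protocol, None, grid_like=mu)
        for v in (0, 3, 7):
            pa = with_att.forward(act.values, v)
            p0 = without.forward(act.values, v)
            assert np.all(pa <= p0 + 1e-12)

    def test_psf_preserves_total_counts(self, small_protocol, rng):
        act = rng.uniform(size=(32, 32, 16))
        blurred = Projector(None, small_protocol, PSFModel(), grid_like=VoxelGrid(act, 4.8))
        sharp = Projector(None, small_protocol, None, grid_like=VoxelGrid(act, 4.8))
        for v in (0, 5):
            assert blurred.forward(act, v).sum() == pytest.approx(
                sharp.forward(act, v).sum(), rel=1e-6)

    def test_shape_mismatch_rejected(self, small_projector):
        with pytest.raises(ValueError, match="shape"):
            small_projector.forward(np.zeros((8, 8, 8)), 0)


class TestAdjointness:
    @pytest.mark.parametrize("attenuation,psf", [(False, False), (True, False),
                                                 (False, True), (True, True)])
    def test_dot_product_identity(self, attenuation, psf, rng):
        shape = (32, 32, 32)
        mu = VoxelGrid(rng.uniform(0, 0.15, shape), 4.8)
        protocol = ProtocolConfig(n_views=8, orbit_radii_cm=np.full(8, 16.0))
        proj = Projector(mu if attenuation else None, protocol,
                         PSFModel() if psf else None, grid_like=mu)
        x = rng.uniform(size=shape)
        y = rng.uniform(size=proj.detector_shape)
        for v in (0, 1, 5):
            lhs = float((proj.forward(x, v) * y).sum())
            rhs = float((x * proj.back(y, v)).sum())
            assert abs(lhs - rhs) <= 1e-6 * abs(lhs)

    def test_zero_projection_backprojects_to_zero(self, small_projector):
        out = small_projector.back(np.zeros(small_projector.detector_shape), 0)
        assert np.all(out == 0.0)

    def test_sensitivity_positive_inside_fov(self, small_projector):
        sens = small_projector.sensitivity(range(16))
        centre = sens[8:24, 8:24, :]
        assert np.all(centre > 0.0)
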