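"""Phantom construction: geometry primitives and the two study phantoms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from luquant import (CalibrationConfig, TorsoConfig, VoxelGrid,
                     build_calibration_phantom, build_torso_phantom,
                     rasterize_sphere, sphere_radius_from_volume)
from luquant.phantoms import InsertSpec, TABLE_INSERTS


class TestSphereRadius:
    def test_unit_sphere(self):
        assert sphere_radius_from_volume(4.0 * np.pi / 3.0) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("volume_ml", [104.4, 0.4, 2.6, 30.3])
    def test_matches_root_finding_oracle(self, volume_ml):
        # independent oracle: invert V(r) = 4/3 pi r^3 numerically
        expected = brentq(lambda r: 4.0 * np.pi * r**3 / 3.0 - volume_ml, 1e-6, 10.0,
                          xtol=1e-13)
        assert sphere_radius_from_volume(volume_ml) == pytest.approx(expected, rel=1e-10)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_round_trips_with_sphere_volume(self, volume_ml):
        r = sphere_radius_from_volume(volume_ml)
        assert 4.0 * np.pi * r**3 / 3.0 == pytest.approx(volume_ml, rel=1e-12)

    def test_rejects_nonpositive_volume(self):
        with pytest.raises(ValueError):
            sphere_radius_from_volume(0.0)


class TestRasterizeSphere:
    def setup_method(self):
        self.grid = VoxelGrid(np.zeros((32, 32, 32)), 4.8)

    def test_zero_radius_gives_empty_mask(self):
        mask = rasterize_sphere((0, 0, 0), 0.0, self.grid)
        assert mask.values.sum() == 0.0

    def test_interior_voxels_fully_occupied(self):
        mask = rasterize_sphere((2.4, 2.4, 2.4), 20.0, self.grid, supersample=3)
        # the voxel containing the centre is strictly inside the sphere
        idx = np.unravel_index(np.argmax(mask.values), mask.shape)
        assert mask.values[idx] == 1.0

    @pytest.mark.parametrize("radius_mm", [5.0, 10.0, 20.0])
    def test_volume_matches_analytic_sphere(self, radius_mm):
        mask = rasterize_sphere((1.0, -2.0, 3.0), radius_mm, self.grid, supersample=3)
        vol = mask.values.sum() * mask.voxel_volume_ml
        analytic = 4.0 * np.pi * (radius_mm / 10.0) ** 3 / 3.0
        assert vol == pytest.approx(analytic, rel=0.01)

    def test_supersample_convergence_for_inserts(self):
        # doubling the sub-voxel sampling changes any insert's mask volume
        # by less than 0.5%
        grid = VoxelGrid(np.zeros((96, 96, 64)), 4.8)
        for ins in (TABLE_INSERTS[1], TABLE_INSERTS[6], TABLE_INSERTS[8]):
            v3 = rasterize_sphere(ins.center_mm, ins.radius_mm, grid, 3).values.sum()
            v6 = rasterize_sphere(ins.center_mm, ins.radius_mm, grid, 6).values.sum()
            assert abs(v6 - v3) / v3 < 0.005, ins.label

    def test_sphere_outside_grid_warns_and_is_empty(self):
        with pytest.warns(UserWarning, match="outside"):
            mask = rasterize_sphere((500.0, 0.0, 0.0), 5.0, self.grid)
        assert mask.values.sum() == 0.0


@pytest.fixture(scope="module")
def torso():
    return build_torso_phantom()


@pytest.fixture(scope="module")
def calibration():
    return build_calibration_phantom()


class TestTorsoPhantom:
    @pytest.fixture
    def phantom(self, torso):
        return torso

    def test_total_activity_hits_configured_value(self, phantom):
        assert phantom.total_activity_MBq() == pytest.approx(806.0, rel=0.005)

    def test_insert_to_background_ratio_is_30(self, phantom):
        core = phantom.masks["Q4"].values >= 0.999  # interior voxels only
        mean_conc = phantom.activity.values[core].mean()
        assert mean_conc / phantom.background_concentration_MBq_ml == pytest.approx(30.0, rel=1e-9)

    def test_left_lung_ratio_and_cold_right_lung(self, phantom):
        left = phantom.masks["lung_left"].values >= 0.999
        ratio = phantom.activity.values[left].mean() / phantom.background_concentration_MBq_ml
        assert ratio == pytest.approx(1.7, rel=1e-9)
        right = phantom.masks["lung_right"].values >= 0.999
        assert phantom.activity.values[right].max() == 0.0

    def test_lung_attenuation_scaled_by_density(self, phantom):
        right = phantom.masks["lung_right"].values >= 0.999
        assert np.allclose(phantom.mu.values[right], 0.3 * 0.137)

    def test_q2_q3_match_printed_table(self, phantom):
        q2 = next(i for i in phantom.inserts if i.label == "Q2")
        q3 = next(i for i in phantom.inserts if i.label == "Q3")
        assert q2.volume_ml == q3.volume_ml == 30.3
        assert (q2.activity_MBq, q3.activity_MBq) == (31.2, 30.4)

    def test_insert_spec_concentration_consistency(self):
        for ins in TABLE_INSERTS:
            assert ins.concentration_MBq_ml * ins.volume_ml == pytest.approx(
                ins.activity_MBq, rel=1e-9)

    def test_rescaling_preserves_concentration_ratios(self):
        half = build_torso_phantom(TorsoConfig(total_activity_MBq=403.0))
        full = build_torso_phantom()
        assert half.total_activity_MBq() == pytest.approx(403.0, rel=1e-9)
        np.testing.assert_allclose(half.activity.values, 0.5 * full.activity.values,
                                   rtol=1e-12)

    def test_overlapping_inserts_rejected_with_labels(self):
        bad = TorsoConfig(inserts=(
            InsertSpec("Q1", 104.4, 105.2, (0.0, 0.0, -80.0)),
            InsertSpec("Q4", 26.1, 27.2, (10.0, 0.0, -80.0)),
        ))
        with pytest.raises(ValueError, match="Q1.*Q4"):
            build_torso_phantom(bad)

    def test_construction_is_deterministic(self, phantom):
        again = build_torso_phantom()
        np.testing.assert_array_equal(phantom.activity.values, again.activity.values)
        np.testing.assert_array_equal(phantom.mu.values, again.mu.values)


class TestCalibrationPhantom:
    @pytest.fixture
    def phantom(self, calibration):
        return calibration

    def test_bottle_activity_is_concentration_times_volume(self, phantom):
        # 0.45 MBq/ml x 525 ml, both printed specifications
        assert phantom.total_activity_MBq() == pytest.approx(0.45 * 525.0, rel=0.02)

    def test_no_activity_outside_bottle(self, phantom):
        outside = phantom.masks["bottle"].values == 0.0
        assert phantom.activity.values[outside].max() == 0.0

    def test_bottle_mask_volume(self, phantom):
        vol = phantom.masks["bottle"].values.sum() * phantom.activity.voxel_volume_ml
        assert vol == pytest.approx(525.0, rel=0.02)

    def test_water_attenuation_inside_body(self, phantom):
        core = phantom.masks["body"].values >= 0.999
        assert np.allclose(phantom.mu.values[core], 0.137)

    def test_oversized_bottle_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            build_calibration_phantom(CalibrationConfig(bottle_diameter_mm=300.0))
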