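"""Volumetric sensitivity, cRC arithmetic and VOI delineation."""

import numpy as np
import pytest
from scipy import ndimage

from luquant import (InsertSpec, SensitivityFactor, VoxelGrid,
                     compute_sensitivity, concentration_recovery,
                     delineate_insert_voi, rasterize_sphere, voi_statistics)
from luquant.recon import ActivityImage


def _image(values, comp="ARS"):
    return ActivityImage(VoxelGrid(values, 4.8), {"compensation": comp})


class TestVoiStatistics:
    def test_uniform_image_binary_mask(self):
        img = _image(np.full((8, 8, 8), 3.0))
        mask = np.zeros((8, 8, 8))
        mask[2:4, 2:4, 2:4] = 1.0
        stats = voi_statistics(img, VoxelGrid(mask, 4.8))
        assert stats.total_counts == pytest.approx(3.0 * 8)
        assert stats.volume_ml == pytest.approx(8 * 4.8**3 / 1000.0)

    def test_half_mask_halves_totals_but_not_mean(self):
        rngv = np.random.default_rng(0).uniform(size=(8, 8, 8))
        mask = np.zeros((8, 8, 8))
        mask[1:5, 1:5, 1:5] = 1.0
        full = voi_statistics(_image(rngv), VoxelGrid(mask, 4.8))
        half = voi_statistics(_image(rngv), VoxelGrid(0.5 * mask, 4.8))
        assert half.total_counts == pytest.approx(0.5 * full.total_counts)
        assert half.volume_ml == pytest.approx(0.5 * full.volume_ml)
        assert half.mean_counts_per_ml == pytest.approx(full.mean_counts_per_ml)

    def test_matches_per_voxel_loop_oracle(self, rng):
        values = rng.uniform(size=(16, 16, 16))
        mask = rng.uniform(size=(16, 16, 16))
        stats = voi_statistics(_image(values), VoxelGrid(mask, 4.8))
        total = 0.0
        for i in range(16):
            for j in range(16):
                for k in range(16):
                    total += values[i, j, k] * mask[i, j, k]
        assert stats.total_counts == pytest.approx(total, abs=1e-12 * max(total, 1))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            voi_statistics(_image(np.ones((4, 4, 4))), VoxelGrid(np.zeros((4, 4, 4)), 4.8))


class TestSensitivityAndRecovery:
    def _bottle(self, level=90.0):
        values = np.zeros((16, 16, 16))
        values[4:12, 4:12, 4:12] = level
        mask = np.zeros((16, 16, 16))
        mask[4:12, 4:12, 4:12] = 1.0
        return _image(values), VoxelGrid(mask, 4.8)

    def test_svol_by_hand_arithmetic(self):
        img, mask = self._bottle()
        svol = compute_sensitivity(img, mask, C_true_MBq_ml=0.45)
        vvol = 4.8**3 / 1000.0
        assert svol.S_vol == pytest.approx((90.0 / vvol) / 0.45, rel=1e-12)

    def test_self_calibrated_bottle_recovery_is_exactly_one(self):
        img, mask = self._bottle()
        svol = compute_sensitivity(img, mask, C_true_MBq_ml=0.45)
        crc = concentration_recovery(img, mask, svol, 0.45)
        assert crc == pytest.approx(1.0, rel=1e-12)

    def test_doubling_image_doubles_svol(self):
        img, mask = self._bottle(90.0)
        img2, _ = self._bottle(180.0)
        s1 = compute_sensitivity(img, mask, 0.45)
        s2 = compute_sensitivity(img2, mask, 0.45)
        assert s2.S_vol == pytest.approx(2.0 * s1.S_vol)

    def test_zero_counts_rejected(self):
        img = _image(np.zeros((8, 8, 8)))
        mask = VoxelGrid(np.ones((8, 8, 8)), 4.8)
        with pytest.raises(ValueError, match="counts"):
            compute_sensitivity(img, mask, 0.45)

    def test_crc_plug_in_example(self):
        # R = 200, V = 4 ml, S_vol = 10, C = 10 -> cRC = 0.5
        vvol = 4.8**3 / 1000.0
        n_vox = 8
        volume_ml = n_vox * vvol
        level = 200.0 / n_vox * (4.0 / volume_ml)  # scale VOI to exactly 4 ml worth
        values = np.zeros((8, 8, 8))
        values[2:4, 2:4, 2:4] = 200.0 / n_vox
        mask = np.zeros((8, 8, 8))
        mask[2:4, 2:4, 2:4] = 4.0 / volume_ml  # fractional mask summing to 4 ml
        img = _image(values)
        svol = SensitivityFactor(10.0, "ARS")
        crc = concentration_recovery(img, VoxelGrid(mask, 4.8), svol, 10.0)
        R = 200.0 * (4.0 / volume_ml)
        expected = (R / (4.0 * 10.0)) / 10.0
        assert crc == pytest.approx(expected, rel=1e-12)

    def test_compensation_mismatch_rejected(self):
        img, mask = self._bottle()
        svol = SensitivityFactor(10.0, "A")
        with pytest.raises(ValueError, match="mismatch"):
            concentration_recovery(img, mask, svol, 0.45)

    def test_crc_invariant_to_global_rescaling(self):
        # camera sensitivity / dwell rescaling multiplies both the image and
        # S_vol, leaving cRC unchanged
        img, mask = self._bottle()
        svol = compute_sensitivity(img, mask, 0.45)
        crc1 = concentration_recovery(img, mask, svol, 0.3)
        img2 = _image(img.values * 7.5)
        svol2 = compute_sensitivity(img2, mask, 0.45)
        crc2 = concentration_recovery(img2, mask, svol2, 0.3)
        assert crc1 == pytest.approx(crc2, rel=1e-12)


class TestDelineation:
    def setup_method(self):
        self.grid = VoxelGrid(np.zeros((48, 48, 48)), 4.8)

    def test_large_sphere_volume_close_to_nominal(self):
        ins = InsertSpec("Q1", 104.4, 105.2, (4.0, -3.0, 2.0))
        voi = delineate_insert_voi(ins, self.grid)
        vol = voi.values.sum() * voi.voxel_volume_ml
        assert vol == pytest.approx(104.4, rel=0.05)

    def test_subvoxel_sphere_degenerates_with_warning(self):
        tiny = InsertSpec("T", 0.05, 0.05, (1.0, 1.0, 1.0))
        with pytest.warns(UserWarning, match="sub-voxel"):
            voi = delineate_insert_voi(tiny, self.grid)
        assert voi.values.sum() >= 1

    def test_voi_contained_in_dilated_painting_mask(self):
        ins = InsertSpec("Q5", 10.8, 11.9, (7.0, 7.0, 7.0))
        voi = delineate_insert_voi(ins, self.grid)
        paint = rasterize_sphere(ins.center_mm, ins.radius_mm, self.grid, 3)
        dilated = ndimage.binary_dilation(paint.values > 0)
        assert np.all(dilated[voi.values > 0])

    def test_centre_outside_grid_rejected(self):
        ins = InsertSpec("X", 1.0, 1.0, (1000.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="outside"):
            delineate_insert_voi(ins, self.grid)
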