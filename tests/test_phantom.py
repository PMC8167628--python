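"""Sphere packing, voxelization, and acquisition emulation."""

import numpy as np
import pytest

from beadvol.phantom import (AcquisitionConfig, BeadPack, CTVolume,
                             DEFAULT_SIZE_MIX, PackingError, add_noise,
                             analytic_volume, crop_slices_to_multiple,
                             edge_enhance, nearest_thickness, pack_beads,
                             reformat, resample_pixels, reslice, voxelize)

SPHERE_CM3 = 4.0 / 3.0 * np.pi * 5.0 ** 3 / 1000.0  # r = 5 mm


def brute_force_overlap_free(pack, eps=1e-6):
    c, r = pack.centers, pack.radii
    for i in range(len(r)):
        for j in range(i + 1, len(r)):
            if np.linalg.norm(c[i] - c[j]) < r[i] + r[j] - eps:
                return False
    return True


class TestPackBeads:
    def test_single_bead_inside_container(self):
        pack = pack_beads(1, container=(20.0, 20.0, 20.0), seed=0)
        assert len(pack) == 1
        assert np.all(pack.centers - pack.radii[:, None] >= -1e-9)
        assert np.all(pack.centers + pack.radii[:, None]
                      <= np.array(pack.container) + 1e-9)

    def test_pack_is_overlap_free(self):
        pack = pack_beads(200, container=(45.0, 45.0, 32.0), seed=5)
        assert len(pack) >= 100
        assert brute_force_overlap_free(pack)

    def test_same_seed_reproduces_pack(self):
        a = pack_beads(50, container=(30.0, 30.0, 25.0), seed=9)
        b = pack_beads(50, container=(30.0, 30.0, 25.0), seed=9)
        assert np.array_equal(a.centers, b.centers)
        assert np.array_equal(a.radii, b.radii)

    def test_overfull_container_raises(self):
        with pytest.raises(PackingError):
            pack_beads(400, container=(12.0, 12.0, 12.0), seed=0,
                       max_attempts_per_bead=40)

    def test_bad_diameter_range_rejected(self):
        with pytest.raises(ValueError):
            pack_beads(5, diameter_range=(3.2, 30.0),
                       container=(20.0, 20.0, 20.0))

    def test_default_mix_expected_volume_matches_displacement_truth(self):
        # 750 beads of the default diameter mixture have an expected
        # analytic volume matching the physical pack's 35.5 cm^3
        mean_mm3 = sum(w * 4 / 3 * np.pi * (d / 2) ** 3
                       for d, w in DEFAULT_SIZE_MIX.items())
        assert 750 * mean_mm3 / 1000 == pytest.approx(35.5, abs=0.1)

    def test_full_scale_pack_volume_near_truth(self):
        pack = pack_beads(750, seed=7)
        assert analytic_volume(pack) == pytest.approx(35.5, rel=0.2)

    def test_json_round_trip(self, tmp_path):
        pack = pack_beads(20, container=(25.0, 25.0, 20.0), seed=2)
        p = tmp_path / "pack.json"
        pack.to_json(p)
        back = BeadPack.from_json(p)
        assert np.allclose(back.centers, pack.centers)
        assert np.allclose(back.radii, pack.radii)
        assert back.container == pack.container


class TestAnalyticVolume:
    def test_single_sphere(self):
        pack = BeadPack([[10, 10, 10]], [5.0], (20, 20, 20))
        assert analytic_volume(pack) == pytest.approx(0.5235988, abs=1e-6)

    def test_additive(self):
        pack = BeadPack([[6, 6, 6], [16, 16, 16]], [5.0, 5.0], (22, 22, 22))
        assert analytic_volume(pack) == pytest.approx(2 * SPHERE_CM3, rel=1e-9)


@pytest.fixture(scope="module")
def sphere():
    pack = BeadPack([[7.0, 7.0, 7.0]], [5.0], (14.0, 14.0, 14.0))
    cfg = AcquisitionConfig(in_plane_pixel_mm=0.27, thin_slice_mm=0.27)
    vol, occ = voxelize(pack, cfg, margin_mm=1.0, nz_multiple=1)
    return vol, occ


class TestVoxelize:
    def test_pure_voxels_take_exact_material_hu(self, sphere):
        vol, occ = sphere
        assert np.all(vol.hu[occ == 1.0] == 119.9)
        assert np.all(vol.hu[occ == 0.0] == -149.7)

    def test_occupancy_sum_matches_analytic_volume(self, sphere):
        vol, occ = sphere
        v = occ.sum() * vol.voxel_volume_mm3 / 1000.0
        assert v == pytest.approx(0.5235988, rel=5e-3)

    def test_small_sphere_fine_grid_oracle(self):
        pack = BeadPack([[5.0, 5.0, 5.0]], [2.0], (10.0, 10.0, 10.0))
        cfg = AcquisitionConfig(in_plane_pixel_mm=0.27, thin_slice_mm=0.27)
        vol, occ = voxelize(pack, cfg, margin_mm=0.6, nz_multiple=1)
        v = occ.sum() * vol.voxel_volume_mm3
        assert v == pytest.approx(4 / 3 * np.pi * 8.0, rel=5e-3)

    def test_sphere_outside_grid_rejected(self):
        pack = BeadPack([[2.0, 7.0, 7.0]], [5.0], (14.0, 14.0, 14.0))
        cfg = AcquisitionConfig()
        with pytest.raises(ValueError, match="outside"):
            voxelize(pack, cfg, margin_mm=0.0, shape=(8, 8, 8))

    def test_hu_is_linear_in_occupancy(self, sphere):
        vol, occ = sphere
        assert np.allclose(vol.hu, -149.7 + occ * 269.6)

    def test_air_pockets_bias_measured_volume_downward(self):
        # air adherent at contact points lowers ROI means, so the
        # mixture-inversion volume underestimates the unchanged truth
        from beadvol.phantom import air_pocket_pack
        from beadvol.roi import mixture_roi_stack
        from beadvol.volumetry import MaterialPair, measure_roi, total_volume

        pack = pack_beads(40, container=(26.0, 26.0, 20.0), seed=6)
        cfg = AcquisitionConfig(in_plane_pixel_mm=0.4)
        air = air_pocket_pack(pack, radius_mm=0.3, fraction=1.0, seed=1)
        assert len(air) > 0
        mat = MaterialPair(119.9, -149.7)

        def measured(air_pack):
            vol, occ = voxelize(pack, cfg, margin_mm=3.0, air_pack=air_pack)
            rois = mixture_roi_stack(occ, margin_mm=2.0, spacing=(0.4, 0.4))
            ms = [measure_roi(vol, r.slice_index, r.mask) for r in rois]
            return total_volume(ms, mat, cfg.thin_slice_mm).total_volume_cm3

        assert measured(air) < measured(None)


class TestReslice:
    def test_native_thickness_is_identity(self):
        vol = CTVolume(np.random.default_rng(0).normal(size=(8, 5, 5)),
                       (1.0, 1.0, 0.625))
        out = reslice(vol, 0.625)
        assert np.array_equal(out.hu, vol.hu)

    def test_eight_thin_slices_average_to_one(self):
        vals = np.arange(8.0)
        hu = np.tile(vals[:, None, None], (1, 3, 3))
        vol = CTVolume(hu, (1.0, 1.0, 0.625))
        out = reslice(vol, 5.0)
        assert out.hu.shape == (1, 3, 3)
        assert np.allclose(out.hu, vals.mean())
        assert out.spacing[2] == pytest.approx(5.0)

    def test_mean_preserved(self):
        rng = np.random.default_rng(3)
        vol = CTVolume(rng.normal(size=(16, 6, 6)), (1.0, 1.0, 0.625))
        out = reslice(vol, 2.5)
        assert out.hu.mean() == pytest.approx(vol.hu.mean(), rel=1e-12)

    def test_non_integer_multiple_rejected(self):
        vol = CTVolume(np.zeros((8, 3, 3)), (1.0, 1.0, 0.625))
        with pytest.raises(ValueError, match="integer multiple"):
            reslice(vol, 1.0)

    def test_indivisible_stack_rejected(self):
        vol = CTVolume(np.zeros((7, 3, 3)), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="divide evenly"):
            reslice(vol, 2.0)

    def test_crop_to_multiple_refuses_object_slices(self):
        vol = CTVolume(np.zeros((7, 3, 3)), (1.0, 1.0, 1.0))
        occ = np.zeros((7, 3, 3))
        occ[6, 1, 1] = 0.5  # object in the slice that would be trimmed
        with pytest.raises(ValueError, match="object"):
            crop_slices_to_multiple(vol, 2, occ)
        occ[6, 1, 1] = 0.0
        out, occ2 = crop_slices_to_multiple(vol, 2, occ)
        assert out.hu.shape[0] == 6 and occ2.shape[0] == 6

    def test_nearest_thickness(self):
        vol = CTVolume(np.zeros((4, 3, 3)), (0.2734375, 1.0, 0.2734375))
        assert nearest_thickness(vol, 5.0) == pytest.approx(18 * 0.2734375)


class TestAddNoise:
    def test_zero_sd_is_identity(self):
        vol = CTVolume(np.full((4, 10, 10), -149.7), (1.0, 1.0, 1.0))
        assert np.array_equal(add_noise(vol, 0.0, seed=1).hu, vol.hu)

    def test_sample_sd_matches_request(self):
        vol = CTVolume(np.full((10, 100, 100), -149.7), (1.0, 1.0, 1.0))
        noisy = add_noise(vol, 22.3, seed=2)
        assert (noisy.hu - vol.hu).std() == pytest.approx(22.3, rel=0.01)

    def test_zero_mean(self):
        vol = CTVolume(np.full((10, 100, 100), -149.7), (1.0, 1.0, 1.0))
        noisy = add_noise(vol, 22.3, seed=3)
        n = vol.hu.size
        assert abs((noisy.hu - vol.hu).mean()) < 3 * 22.3 / np.sqrt(n)

    def test_deterministic_given_seed(self):
        vol = CTVolume(np.zeros((4, 10, 10)), (1.0, 1.0, 1.0))
        a = add_noise(vol, 5.0, seed=7)
        b = add_noise(vol, 5.0, seed=7)
        assert np.array_equal(a.hu, b.hu)


class TestEdgeEnhance:
    def test_zero_strength_is_identity(self):
        rng = np.random.default_rng(0)
        vol = CTVolume(rng.normal(size=(3, 20, 20)), (0.5, 0.5, 1.0))
        assert np.array_equal(edge_enhance(vol, 0.0).hu, vol.hu)

    def test_flat_field_preserved(self):
        vol = CTVolume(np.full((3, 30, 30), -149.7), (0.5, 0.5, 1.0))
        out = edge_enhance(vol, strength=1.5)
        assert np.allclose(out.hu, -149.7, atol=1e-9)

    def test_step_edge_overshoots_both_plateaus(self):
        hu = np.full((1, 20, 60), -149.7)
        hu[:, :, 30:] = 119.9
        vol = CTVolume(hu, (0.5, 0.5, 1.0))
        out = edge_enhance(vol, strength=1.0, radius_mm=0.8)
        assert out.hu.max() > 119.9 + 1.0
        assert out.hu.min() < -149.7 - 1.0

    def test_matches_1d_unsharp_oracle(self):
        from scipy import ndimage
        hu = np.full(60, -149.7)
        hu[30:] = 119.9
        row = np.tile(hu, (1, 20, 1))
        vol = CTVolume(row, (0.5, 0.5, 1.0))
        out = edge_enhance(vol, strength=1.0, radius_mm=0.8)
        blurred = ndimage.gaussian_filter1d(hu, sigma=0.8 / 0.5,
                                            mode="nearest")
        expected = hu + (hu - blurred)
        assert np.allclose(out.hu[0, 10], expected, atol=1e-9)


class TestReformatAndResample:
    @pytest.fixture()
    def random_volume(self):
        rng = np.random.default_rng(4)
        return CTVolume(rng.normal(size=(8, 12, 10)), (0.3, 0.4, 0.625),
                        origin=(1.0, 2.0, 3.0))

    def test_reformat_round_trip(self, random_volume):
        cor = reformat(random_volume, "coronal")
        back = reformat(cor, "coronal")
        assert np.array_equal(back.hu, random_volume.hu)
        assert back.spacing == random_volume.spacing

    def test_reformat_preserves_global_mean(self, random_volume):
        for plane in ("coronal", "sagittal"):
            out = reformat(random_volume, plane)
            assert out.hu.mean() == pytest.approx(random_volume.hu.mean(),
                                                  rel=1e-12)

    def test_reformat_then_reslice(self, random_volume):
        out = reformat(random_volume, "coronal", out_thickness_mm=0.8)
        assert out.hu.shape[0] == 6  # 12 y-rows in blocks of 2
        assert out.spacing[2] == pytest.approx(0.8)

    def test_unknown_plane_rejected(self, random_volume):
        with pytest.raises(ValueError):
            reformat(random_volume, "oblique")

    def test_resample_identity(self, random_volume):
        iso = CTVolume(random_volume.hu, (0.4, 0.4, 0.625))
        out = resample_pixels(iso, 0.4)
        assert np.array_equal(out.hu, iso.hu)

    def test_2x2_block_average(self):
        hu = np.arange(16.0).reshape(1, 4, 4)
        vol = CTVolume(hu, (1.0, 1.0, 1.0))
        out = resample_pixels(vol, 2.0)
        expected = np.array([[[2.5, 4.5], [10.5, 12.5]]])
        assert np.allclose(out.hu, expected)
        assert out.hu.mean() == pytest.approx(vol.hu.mean(), rel=1e-12)

    def test_upsampling_rejected(self):
        vol = CTVolume(np.zeros((1, 4, 4)), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="coarsening"):
            resample_pixels(vol, 0.5)
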