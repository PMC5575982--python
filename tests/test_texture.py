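"""Texture synthesis: donor, compositing, pattern generation, noise, tumor."""

import numpy as np
import pytest

from liverphantom.anatomy import TumorSpec
from liverphantom.errors import InvalidArgumentError, RescaleError
from liverphantom.grid import VoxelGrid, default_grid
from liverphantom.texture import (
    add_rayleigh_noise,
    compose_AB,
    correlated_field,
    generate_pattern,
    insert_tumor,
    make_donor_texture,
    rescale_mean,
    tumor_depression,
)


class TestDonorTexture:
    def test_muscle_roi_statistics(self):
        donor = make_donor_texture(default_grid(4.0), seed=7)
        roi = donor.muscle_roi
        assert min(roi.shape) * default_grid(4.0).spacing_mm >= 40.0 - 6.7
        assert 95.0 <= roi.mean() <= 105.0
        assert 10.0 <= roi.std() <= 20.0

    def test_deterministic_given_seed(self):
        a = make_donor_texture(default_grid(4.0), seed=7)
        b = make_donor_texture(default_grid(4.0), seed=7)
        assert (a.volume.values == b.volume.values).all()
        c = make_donor_texture(default_grid(4.0), seed=8)
        assert (a.volume.values != c.volume.values).any()

    def test_zero_sd_gives_constant_field(self):
        g = VoxelGrid(dims=(16, 16, 16), spacing_mm=2.0)
        field = correlated_field(g, seed=3, sd=0.0)
        assert (field == 100.0).all()

    def test_organ_masks_cover_the_seven_mapped_organs(self):
        donor = make_donor_texture(default_grid(4.0), seed=7)
        assert set(donor.organ_masks) == {
            "liver", "gallbladder", "pancreas", "spleen", "stomach",
            "kidneys", "heart"}
        for mask in donor.organ_masks.values():
            assert mask.any()


class TestRescaleAndCompose:
    def test_rescale_factor(self):
        vals = np.full((4, 4, 4), 200.0)
        mask = np.ones((4, 4, 4), bool)
        out, factor = rescale_mean(vals, mask, 160.0)
        assert factor == pytest.approx(0.8)
        assert out[mask].mean() == pytest.approx(160.0, rel=1e-6)

    def test_rescale_identity(self):
        vals = np.full((4, 4, 4), 160.0)
        _, factor = rescale_mean(vals, np.ones((4, 4, 4), bool), 160.0)
        assert factor == pytest.approx(1.0)

    def test_rescale_zero_mean_fails(self):
        with pytest.raises(RescaleError):
            rescale_mean(np.zeros((3, 3, 3)), np.ones((3, 3, 3), bool), 160.0)

    @pytest.mark.parametrize("a,b", [(95.0, 160.0), (25.0, 170.0)])
    def test_organ_mean_is_a_plus_b(self, a, b, rng):
        vals = np.zeros((8, 8, 8), np.float32)
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        detail = rng.uniform(50, 250, size=(8, 8, 8))
        detail, _ = rescale_mean(detail, mask, b)
        compose_AB(vals, a, detail, mask)
        assert vals[mask].mean() == pytest.approx(a + b, rel=1e-6)
        assert (vals[~mask] == 0).all()  # compositing is mask-local

    def test_zero_detail_gives_uniform_a(self):
        vals = np.zeros((4, 4, 4), np.float32)
        mask = np.ones((4, 4, 4), bool)
        compose_AB(vals, 40.0, np.zeros((4, 4, 4)), mask)
        assert (vals == 40.0).all()


class TestRayleighNoise:
    def test_sample_mean_and_variance(self):
        mask = np.ones((60, 60, 60), bool)  # > 1e5 samples
        out = add_rayleigh_noise(np.zeros(mask.shape, np.float32), mask, 5.0, seed=3)
        assert out[mask].mean() == pytest.approx(5.0, abs=0.1)
        sigma = 5.0 * np.sqrt(2.0 / np.pi)
        assert out[mask].var() == pytest.approx((2 - np.pi / 2) * sigma ** 2,
                                                rel=0.05)

    def test_zero_level_is_identity(self):
        vals = np.arange(27.0).reshape(3, 3, 3).astype(np.float32)
        out = add_rayleigh_noise(vals, np.ones((3, 3, 3), bool), 0.0, seed=0)
        assert (out == vals).all()

    def test_negative_level_rejected(self):
        with pytest.raises(InvalidArgumentError):
            add_rayleigh_noise(np.zeros((3, 3, 3)), np.ones((3, 3, 3), bool),
                               -1.0, seed=0)


class TestPatternGeneration:
    @pytest.fixture
    def donor_roi(self, rng):
        return rng.uniform(80, 120, size=(12, 12, 12)).astype(np.float32)

    def test_single_5cube_soi(self, donor_roi):
        soi = np.zeros((9, 9, 9), bool)
        soi[2:7, 2:7, 2:7] = True
        detail, state = generate_pattern(soi, donor_roi, seed=5, return_state=True)
        five = [p for p in state.placements if p[0] == 5]
        assert len(five) == 1
        assert (state.pre_filter != 0).sum() == 125

    def test_every_voxel_assigned_exactly_once(self, donor_roi):
        soi = np.zeros((10, 10, 10), bool)
        soi[1:7, 2:8, 1:7] = True  # 6^3 -> one 5^3 patch plus 3^3/1^3 fill
        detail, state = generate_pattern(soi, donor_roi, seed=5, return_state=True)
        sizes = sorted({p[0] for p in state.placements})
        assert 5 in sizes and 1 in sizes
        counts = np.zeros(soi.shape, int)
        bbox_off = np.array([s.start for s in state.bbox])
        for size, _, corner in state.placements:
            i, j, k = np.array(corner)  # absolute corner
            counts[i:i + size, j:j + size, k:k + size] += 1
        assert (counts[soi] == 1).all()
        assert (counts[~soi] == 0).all()

    def test_patches_verbatim_from_donor(self, donor_roi):
        soi = np.zeros((12, 12, 12), bool)
        soi[1:11, 1:11, 1:11] = True
        _, state = generate_pattern(soi, donor_roi, seed=9, return_state=True)
        off = np.array([s.start for s in state.bbox])
        for size, dcorner, corner in state.placements:
            si, sj, sk = np.array(corner) - off
            di, dj, dk = dcorner
            got = state.pre_filter[si:si + size, sj:sj + size, sk:sk + size]
            want = donor_roi[di:di + size, dj:dj + size, dk:dk + size]
            assert (got == want).all()

    def test_deterministic(self, donor_roi):
        soi = np.zeros((10, 10, 10), bool)
        soi[1:9, 1:9, 1:9] = True
        a = generate_pattern(soi, donor_roi, seed=11)
        b = generate_pattern(soi, donor_roi, seed=11)
        c = generate_pattern(soi, donor_roi, seed=12)
        assert (a == b).all()
        assert (a != c).any()

    def test_smoothing_is_mask_restricted(self, donor_roi):
        soi = np.zeros((10, 10, 10), bool)
        soi[2:8, 2:8, 2:8] = True
        detail = generate_pattern(soi, donor_roi, seed=4)
        assert (detail[~soi] == 0).all()
        assert detail[soi].min() >= donor_roi.min() - 1e-3

    def test_empty_soi_rejected(self, donor_roi):
        with pytest.raises(InvalidArgumentError):
            generate_pattern(np.zeros((8, 8, 8), bool), donor_roi, seed=0)


class TestTumorProfile:
    @pytest.mark.parametrize("rho,expected", [
        (0.0, 100.0),
        (15.0, 0.0),
        (15.0 / np.sqrt(2.0), 25.0),
        (20.0, 0.0),
    ])
    def test_quartic_depression(self, rho, expected):
        assert tumor_depression(rho) == pytest.approx(expected, abs=1e-9)

    def test_smooth_at_rim(self):
        eps = 1e-4
        slope = (tumor_depression(15.0) - tumor_depression(15.0 - eps)) / eps
        assert abs(slope) < 1e-2

    def test_center_is_local_mean_minus_delta0(self):
        g = VoxelGrid(dims=(40, 40, 40), spacing_mm=2.0)
        vals = np.full(g.shape, 255.0, np.float32)
        liver = np.ones(g.shape, bool)
        spec = TumorSpec(center_mm=(40.0, 40.0, 40.0))
        out, local_mean = insert_tumor(vals, g, spec, liver)
        assert local_mean == pytest.approx(255.0)
        cidx = tuple(np.round(g.world_to_index(spec.center_mm)).astype(int))
        assert out[cidx] == pytest.approx(155.0, abs=0.5)
        # rim joins the untouched texture
        rim = tuple(np.round(g.world_to_index((40.0 + 15.9, 40.0, 40.0))).astype(int))
        assert out[rim] == pytest.approx(255.0, abs=1e-4)


class TestReferenceBuild:
    def test_liver_mean_near_a_plus_b(self, demo_build):
        m = demo_build.anatomy.masks["liver"] & ~demo_build.anatomy.tumor_mask
        mean = demo_build.reference.values[m].mean()
        assert mean == pytest.approx(255.0, rel=0.02)

    def test_lung_mean_is_a_plus_noise_level(self, demo_build):
        mean = demo_build.reference.values[demo_build.anatomy.masks["lungs"]].mean()
        assert mean == pytest.approx(23.0, abs=0.2)

    @pytest.mark.parametrize("organ,expected", [
        ("spleen", 195.0), ("muscle", 180.0), ("stomach", 225.0),
    ])
    def test_structure_means(self, demo_build, organ, expected):
        mean = demo_build.reference.values[demo_build.anatomy.masks[organ]].mean()
        assert mean == pytest.approx(expected, rel=0.02)

    def test_mapping_quality_recorded(self, demo_build):
        mapping = demo_build.extras["mapping"]
        assert set(mapping) == {"liver", "gallbladder", "pancreas", "spleen",
                                "stomach", "kidneys", "heart"}
        for organ, info in mapping.items():
            assert info["dice"] >= 0.90, organ

    def test_full_build_reproducible(self, demo_build):
        import warnings

        from liverphantom.pipeline import RunConfig, build_reference
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again = build_reference(RunConfig(grid_scale=4.0, seed=7))
        assert (again.reference.values == demo_build.reference.values).all()
        assert (again.anatomy.labels.labels == demo_build.anatomy.labels.labels).all()
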