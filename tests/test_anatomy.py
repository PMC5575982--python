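"""Reference anatomy: rasterization, calibration, tumor placement."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from liverphantom.anatomy import (
    LIVER_TARGET_ML,
    AnatomyConfig,
    TumorSpec,
    build_anatomy,
    build_reference_labels,
    calibrate_mask,
    place_tumor,
)
from liverphantom.errors import CalibrationError, InvalidConfigError, PlacementError
from liverphantom.grid import VoxelGrid, default_grid


@pytest.fixture(scope="module")
def demo_anatomy():
    return build_anatomy(default_grid(4.0))


class TestLabelPartition:
    def test_all_structures_present(self, demo_anatomy, table):
        names = {r.name for r in table if r.name != "air"}
        assert set(demo_anatomy.masks) == names
        for name, mask in demo_anatomy.masks.items():
            assert mask.any(), name

    def test_masks_partition_labeled_voxels(self, demo_anatomy):
        total = sum(int(m.sum()) for m in demo_anatomy.masks.values())
        assert total == int((demo_anatomy.labels.labels != 0).sum())

    def test_every_label_resolves_to_one_record(self, demo_anatomy, table):
        for lid in demo_anatomy.labels.present_ids():
            assert int(lid) in table

    def test_liver_is_connected(self, demo_anatomy):
        _, n = ndimage.label(demo_anatomy.masks["liver"])
        assert n == 1

    def test_paired_organs_are_bilateral(self, demo_anatomy):
        """Kidneys are two bodies; lungs are two main bodies (the airway and
        heart carve extra fragments at coarse resolution)."""
        lbl, n = ndimage.label(demo_anatomy.masks["kidneys"])
        assert n == 2
        lbl, n = ndimage.label(demo_anatomy.masks["lungs"])
        assert n >= 2
        sizes = np.sort(ndimage.sum_labels(np.ones_like(lbl), lbl,
                                           index=np.arange(1, n + 1)))[::-1]
        assert sizes[:2].sum() >= 0.9 * sizes.sum()

    def test_layout_orientation(self, demo_anatomy):
        """Lungs superior, liver right (small x), spine posterior midline."""
        g = demo_anatomy.labels.grid
        com = {n: np.array(ndimage.center_of_mass(demo_anatomy.masks[n])) * g.spacing_mm
               for n in ("lungs", "liver", "spine", "intestine_wall")}
        assert com["lungs"][2] > com["intestine_wall"][2]  # lungs above bowel
        assert com["liver"][0] < g.extent_mm[0] / 2  # right side (+x is left)
        assert com["spine"][1] < g.extent_mm[1] / 2  # posterior

    def test_missing_required_shape_is_invalid(self):
        cfg = AnatomyConfig()
        cfg = dataclasses.replace(
            cfg, shapes={k: v for k, v in cfg.shapes.items() if k != "lungs"})
        with pytest.raises(InvalidConfigError):
            build_reference_labels(default_grid(4.0), cfg)

    def test_shape_outside_fov_is_invalid(self):
        cfg = AnatomyConfig()
        shapes = dict(cfg.shapes)
        shapes["spleen"] = dict(shapes["spleen"], center=(500.0, 170.0, 150.0))
        with pytest.raises(InvalidConfigError):
            build_reference_labels(default_grid(4.0),
                                   dataclasses.replace(cfg, shapes=shapes))


class TestLiverCalibration:
    def test_default_liver_volume(self, full_anatomy):
        assert full_anatomy.info["liver_volume_ml"] == pytest.approx(
            LIVER_TARGET_ML, abs=0.05)

    def test_calibration_is_idempotent(self, full_anatomy):
        g = full_anatomy.labels.grid
        mask, scale = calibrate_mask(full_anatomy.masks["liver"], g,
                                     LIVER_TARGET_ML, tol_ml=0.05)
        assert scale == pytest.approx(1.0, abs=1e-3)
        assert abs(int(mask.sum()) * g.voxel_volume_ml - LIVER_TARGET_ML) <= 0.05


class TestCalibrateMask:
    def test_sphere_to_tumor_volume_gives_15mm_radius(self):
        g = VoxelGrid(dims=(48, 48, 48), spacing_mm=1.6719)
        x, y, z = g.world_grid()
        # asymmetric center: keeps lattice shells from flipping in groups
        cx, cy, cz = 24 * g.spacing_mm + 0.37, 24 * g.spacing_mm + 0.91, \
            24 * g.spacing_mm + 1.53
        template = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= 20.0 ** 2
        mask, scale = calibrate_mask(template, g, 14.137, tol_ml=0.05)
        radius = (3.0 * mask.sum() * g.voxel_volume_mm3 / (4.0 * np.pi)) ** (1 / 3)
        assert radius == pytest.approx(15.0, rel=0.02)

    def test_already_at_target_keeps_scale_one(self):
        g = VoxelGrid(dims=(32, 32, 32), spacing_mm=2.0)
        x, y, z = g.world_grid()
        c = 32.0
        template = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= 12.0 ** 2
        target = template.sum() * g.voxel_volume_ml
        mask, scale = calibrate_mask(template, g, target)
        assert scale == 1.0
        assert (mask == template).all()

    def test_unreachable_target_fails(self):
        g = VoxelGrid(dims=(16, 16, 16), spacing_mm=2.0)
        template = np.zeros(g.shape, bool)
        template[6:10, 6:10, 6:10] = True
        with pytest.raises(CalibrationError):
            calibrate_mask(template, g, 5000.0)


class TestTumorPlacement:
    def test_brute_force_voxel_count_oracle(self, full_anatomy):
        """Rasterized sphere == direct voxel-center membership count."""
        g = full_anatomy.labels.grid
        spec = full_anatomy.tumor
        ax = g.world_axes()
        inside = (
            (ax[0][:, None, None] - spec.center_mm[0]) ** 2
            + (ax[1][None, :, None] - spec.center_mm[1]) ** 2
            + (ax[2][None, None, :] - spec.center_mm[2]) ** 2
        ) <= spec.radius_mm ** 2
        assert int(inside.sum()) == int(full_anatomy.tumor_mask.sum())
        vol = inside.sum() * g.voxel_volume_mm3 / 1000.0
        assert vol == pytest.approx(4.0 / 3.0 * np.pi * 1.5 ** 3, rel=0.02)

    def test_default_center_keeps_interior_margin(self, full_anatomy):
        g = full_anatomy.labels.grid
        dt = ndimage.distance_transform_edt(full_anatomy.masks["liver"],
                                            sampling=g.spacing_mm)
        cidx = tuple(np.round(g.world_to_index(full_anatomy.tumor.center_mm)).astype(int))
        assert dt[cidx] >= full_anatomy.tumor.radius_mm + full_anatomy.tumor.margin_mm

    def test_zero_radius_rejected(self, demo_anatomy):
        with pytest.raises(PlacementError):
            place_tumor(demo_anatomy.masks["liver"], demo_anatomy.labels.grid,
                        TumorSpec(radius_mm=0.0))

    def test_boundary_center_rejected(self, demo_anatomy):
        g = demo_anatomy.labels.grid
        liver = demo_anatomy.masks["liver"]
        edge = liver & ~ndimage.binary_erosion(liver)
        center = g.index_to_world(np.argwhere(edge)[0])
        with pytest.raises(PlacementError):
            place_tumor(liver, g, TumorSpec(center_mm=tuple(center)))

    def test_tumor_entirely_inside_liver(self, demo_anatomy):
        assert not (demo_anatomy.tumor_mask & ~demo_anatomy.masks["liver"]).any()
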