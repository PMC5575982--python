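"""Parametric reference anatomy at end of exhalation (EOE).

The reference label volume is built from geometric primitives (superellipsoids,
capsules, extruded superellipse bands) laid out on the fixed ~428x428x251 mm
field of view.  The geometry is deliberately schematic — organ *shapes* carry
no anatomical claim — but the layout is topologically sensible (lungs superior,
liver right-superior under the diaphragm dome, spine/cord posterior midline,
intestine inferior) and the liver is volume-calibrated, so volumes and
center-of-mass kinematics measured downstream are well defined.

Overlaps are resolved by a fixed precedence: voxels are painted in ascending
precedence (body < category II < category III < bones < category I), so the
label array is a partition by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import CalibrationError, InvalidConfigError, PlacementError
from .grid import LabelVolume, VoxelGrid
from .structures import StructureTable

#: reference liver volume the default configuration is calibrated to, in mL.
LIVER_TARGET_ML = 1975.90

# field-of-view center in world mm (x, y); z spans ~[0, 251].
_XC = 214.0
_YC = 214.0


# ---------------------------------------------------------------------------
# shape primitives (evaluated lazily on sparse world meshgrids)
# ---------------------------------------------------------------------------

def superellipsoid(xyz, center, semi, p=2.0):
    """|dx/a|^p + |dy/b|^p + |dz/c|^p <= 1."""
    x, y, z = xyz
    f = (
        np.abs((x - center[0]) / semi[0]) ** p
        + np.abs((y - center[1]) / semi[1]) ** p
        + np.abs((z - center[2]) / semi[2]) ** p
    )
    return f <= 1.0


def superellipse_f(xy, center, semi, p=2.5):
    """2-D superellipse functional (1.0 on the boundary)."""
    x, y = xy
    return (
        np.abs((x - center[0]) / semi[0]) ** p
        + np.abs((y - center[1]) / semi[1]) ** p
    )


def capsule(xyz, p0, p1, radius):
    """All points within ``radius`` of the segment p0-p1."""
    x, y, z = xyz
    p0 = np.asarray(p0, float)
    d = np.asarray(p1, float) - p0
    dd = float(d @ d)
    rx, ry, rz = x - p0[0], y - p0[1], z - p0[2]
    t = (rx * d[0] + ry * d[1] + rz * d[2]) / max(dd, 1e-12)
    t = np.clip(t, 0.0, 1.0)
    dist2 = (rx - t * d[0]) ** 2 + (ry - t * d[1]) ** 2 + (rz - t * d[2]) ** 2
    return dist2 <= radius ** 2


def _zcyl_r(xyz, axis_xy):
    x, y, _ = xyz
    return np.sqrt((x - axis_xy[0]) ** 2 + (y - axis_xy[1]) ** 2)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TumorSpec:
    """Spherical hypointense liver lesion.

    ``center_mm=None`` resolves to the liver's vertical (centroid) axis,
    ``pole_offset_mm`` inferior to the superior pole.  ``margin_mm`` is the
    minimum clearance between the tumor surface and the liver boundary.
    """

    center_mm: tuple[float, float, float] | None = None
    radius_mm: float = 15.0
    delta0: float = 100.0
    margin_mm: float = 12.0
    pole_offset_mm: float = 30.0


def default_shapes() -> dict:
    """Shape parameter set of the default anatomy (world mm)."""
    return {
        "body": dict(kind="trunk", center=(_XC, _YC), semi=(165.0, 115.0), p=2.5,
                     z=(4.0, 246.0)),
        "muscle": dict(kind="band", f=(0.55, 0.94), z=(10.0, 240.0)),
        "intestine_wall": dict(kind="superellipsoid", center=(214.0, 212.0, 58.0),
                               semi=(150.0, 80.0, 46.0), p=3.0),
        "intestine_air": dict(kind="superellipsoid", center=(214.0, 212.0, 58.0),
                              semi=(136.0, 66.0, 34.0), p=3.0),
        "spine_complex": dict(kind="spine", axis=(_XC, 124.0), r_cord=4.5,
                              r_marrow=8.5, r_spine=14.0, z=(4.0, 246.0)),
        "lungs": dict(kind="pair",
                      left=dict(center=(289.0, 205.0, 178.0), semi=(52.0, 62.0, 58.0)),
                      right=dict(center=(139.0, 205.0, 195.0), semi=(55.0, 60.0, 50.0))),
        "airway_tree": dict(kind="airway", trachea_xy=(_XC, 205.0), r=7.0,
                            z=(205.0, 246.0), carina=(214.0, 205.0, 212.0),
                            bronchi=[(265.0, 200.0, 188.0), (163.0, 200.0, 190.0)],
                            r_bronchus=5.5),
        "esophagus_wall": dict(kind="tube", axis=(_XC, 160.0), r=(3.5, 6.5),
                               z=(120.0, 246.0)),
        "rib": dict(kind="band", f=(0.82, 0.92), z=(140.0, 246.0), rib_period=28.0),
        "mobile_marrow": dict(kind="band", f=(0.76, 0.82), z=(140.0, 246.0),
                              rib_period=28.0),
        "cartilage": dict(kind="band", f=(0.82, 0.94), z=(150.0, 235.0),
                          x_abs=(16.0, 42.0), anterior=True),
        "cortical_bone": dict(kind="band", f=(0.82, 0.94), z=(150.0, 235.0),
                              x_abs=(0.0, 16.0), anterior=True),
        "liver": dict(kind="superellipsoid", center=(146.0, 205.0, 150.0),
                      semi=(78.0, 68.0, 66.0), p=2.5),
        "gallbladder": dict(kind="superellipsoid", center=(150.0, 245.0, 112.0),
                            semi=(14.0, 18.0, 24.0), p=2.0),
        "pancreas": dict(kind="superellipsoid", center=(214.0, 228.0, 128.0),
                         semi=(58.0, 16.0, 13.0), p=2.0),
        "spleen": dict(kind="superellipsoid", center=(290.0, 170.0, 150.0),
                       semi=(28.0, 24.0, 34.0), p=2.0),
        "stomach": dict(kind="superellipsoid", center=(268.0, 245.0, 155.0),
                        semi=(38.0, 32.0, 28.0), p=2.0),
        "kidneys": dict(kind="pair",
                        left=dict(center=(272.0, 160.0, 100.0), semi=(22.0, 18.0, 34.0)),
                        right=dict(center=(156.0, 160.0, 100.0), semi=(22.0, 18.0, 34.0))),
        "heart": dict(kind="heart", center=(245.0, 235.0, 195.0),
                      semi_outer=(44.0, 40.0, 42.0), semi_myo=(35.0, 31.0, 33.0),
                      semi_blood=(23.0, 20.0, 22.0)),
    }


@dataclass
class AnatomyConfig:
    shapes: dict = field(default_factory=default_shapes)
    liver_target_ml: float | None = LIVER_TARGET_ML
    calibration_tol_ml: float = 0.05
    tumor: TumorSpec = field(default_factory=TumorSpec)

    def jittered(self, seed: int, rel_semi: float = 0.06,
                 shift_mm: float = 5.0) -> "AnatomyConfig":
        """Perturbed copy used as the donor anatomy (no liver calibration).

        Semi-axes are scaled by up to ±``rel_semi`` and centers shifted by up
        to ±``shift_mm`` per axis, deterministically from ``seed``; the trunk,
        bands and spine are left alone so the donor stays a valid body.
        """
        rng = np.random.default_rng(seed)
        shapes = {}
        for name, spec in self.shapes.items():
            spec = {k: (dict(v) if isinstance(v, dict) else v) for k, v in spec.items()}
            if spec["kind"] in ("superellipsoid", "heart"):
                subspecs = [spec]
            elif spec["kind"] == "pair":
                subspecs = [spec["left"], spec["right"]]
            else:
                shapes[name] = spec
                continue
            for sub in subspecs:
                for key in list(sub):
                    if key.startswith("semi"):
                        f = 1.0 + rng.uniform(-rel_semi, rel_semi, size=3)
                        sub[key] = tuple(np.asarray(sub[key]) * f)
                    if key == "center":
                        dv = rng.uniform(-shift_mm, shift_mm, size=3)
                        sub[key] = tuple(np.asarray(sub[key]) + dv)
            shapes[name] = spec
        return dataclasses.replace(self, shapes=shapes, liver_target_ml=None)


# paint order = ascending precedence; later entries overwrite earlier ones.
_PAINT_ORDER = [
    "body", "muscle", "intestine_wall", "static_marrow",           # cat II
    "lungs", "intestine_air", "airway_tree", "esophagus_wall",     # cat III
    "rib", "mobile_marrow", "cartilage", "cortical_bone",          # cat IV
    "spine", "cord",
    "liver", "gallbladder", "pancreas", "spleen", "stomach",       # cat I
    "kidneys", "pericardium", "myocardium", "heart_blood",
]

# cat-I shapes painted after the liver: they carve it, so liver calibration
# has to target the post-carve volume.
_LIVER_CARVERS = ["gallbladder", "pancreas", "spleen", "stomach", "kidneys", "heart"]


class _ShapeEval:
    """Evaluates named structure masks from a shape dict on one grid."""

    def __init__(self, grid: VoxelGrid, shapes: dict):
        self.grid = grid
        self.shapes = shapes
        self.xyz = grid.world_grid()
        body = shapes["body"]
        self._fbody = superellipse_f(self.xyz[:2], body["center"], body["semi"], body["p"])
        z = self.xyz[2]
        self._in_trunk_z = (z >= body["z"][0]) & (z <= body["z"][1])

    def body_mask(self):
        return (self._fbody <= 1.0) & self._in_trunk_z

    def mask(self, name: str, scale: float = 1.0):
        xyz, z = self.xyz, self.xyz[2]
        owner = {"spine": "spine_complex", "cord": "spine_complex",
                 "static_marrow": "spine_complex", "pericardium": "heart",
                 "myocardium": "heart", "heart_blood": "heart"}.get(name, name)
        if owner not in self.shapes:
            raise InvalidConfigError(f"no shape defined for structure {name!r}")
        if name in ("spine", "cord", "static_marrow"):
            sp = self.shapes["spine_complex"]
            r = _zcyl_r(xyz, sp["axis"])
            zr = (z >= sp["z"][0]) & (z <= sp["z"][1])
            if name == "cord":
                return (r < sp["r_cord"]) & zr
            if name == "static_marrow":
                return (r >= sp["r_cord"]) & (r < sp["r_marrow"]) & zr
            return (r >= sp["r_marrow"]) & (r < sp["r_spine"]) & zr
        if name in ("pericardium", "myocardium", "heart_blood"):
            h = self.shapes["heart"]
            key = {"pericardium": "semi_outer", "myocardium": "semi_myo",
                   "heart_blood": "semi_blood"}[name]
            return superellipsoid(xyz, h["center"], h[key], 2.0)
        spec = self.shapes[name]
        kind = spec["kind"]
        if kind == "superellipsoid":
            semi = np.asarray(spec["semi"]) * scale
            return superellipsoid(xyz, spec["center"], semi, spec["p"])
        if kind == "pair":
            m = False
            for side in ("left", "right"):
                s = spec[side]
                m = m | superellipsoid(xyz, s["center"], s["semi"], 2.0)
            return m
        if kind == "trunk":
            return self.body_mask()
        if kind == "band":
            f = self._fbody
            m = (f >= spec["f"][0]) & (f < spec["f"][1])
            m = m & (z >= spec["z"][0]) & (z <= spec["z"][1])
            if "rib_period" in spec:
                m = m & (np.sin(2.0 * np.pi * z / spec["rib_period"]) > 0.1)
            if "x_abs" in spec:
                dx = np.abs(xyz[0] - self.shapes["body"]["center"][0])
                m = m & (dx >= spec["x_abs"][0]) & (dx < spec["x_abs"][1])
            if spec.get("anterior"):
                m = m & (xyz[1] > self.shapes["body"]["center"][1])
            return np.broadcast_to(False, self.grid.shape) | m
        if kind == "tube":
            r = _zcyl_r(xyz, spec["axis"])
            return (r >= spec["r"][0]) & (r < spec["r"][1]) \
                & (z >= spec["z"][0]) & (z <= spec["z"][1])
        if kind == "airway":
            r = _zcyl_r(xyz, spec["trachea_xy"])
            m = (r < spec["r"]) & (z >= spec["z"][0]) & (z <= spec["z"][1])
            for tip in spec["bronchi"]:
                m = m | capsule(xyz, spec["carina"], tip, spec["r_bronchus"])
            return m
        if kind == "heart":
            return superellipsoid(xyz, spec["center"], spec["semi_outer"], 2.0)
        raise InvalidConfigError(f"unknown shape kind {kind!r} for {name!r}")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def calibrate_mask(mask: np.ndarray, grid: VoxelGrid, target_ml: float,
                   tol_ml: float = 0.05, max_iter: int = 80):
    """Isotropically rescale a binary mask about its centroid to a target volume.

    Returns ``(scaled_mask, scale)``.  The template's signed distance field
    is sampled at shrunk/stretched coordinates (sub-voxel boundary, so the
    rasterized volume varies in single-voxel steps with scale), with the
    scale found by bisection until the voxel-counted volume is within
    ``tol_ml`` of the target.
    """
    if not (target_ml > 0):
        raise InvalidConfigError("target volume must be positive")
    mask = np.asarray(mask, bool)
    n0 = int(mask.sum())
    if n0 == 0:
        raise InvalidConfigError("template mask is empty")
    vox_ml = grid.voxel_volume_ml
    centroid = np.array(ndimage.center_of_mass(mask))

    sdf = (ndimage.distance_transform_edt(mask)
           - ndimage.distance_transform_edt(~mask)).astype(np.float32)
    idx = np.indices(mask.shape, dtype=np.float32)

    def rasterize(scale: float) -> np.ndarray:
        coords = centroid[:, None, None, None] + (idx - centroid[:, None, None, None]) / scale
        return ndimage.map_coordinates(sdf, coords, order=1,
                                       mode="constant", cval=-1e3) > 0.0

    def vol(scale: float) -> float:
        return float(rasterize(scale).sum()) * vox_ml

    v0 = n0 * vox_ml
    if abs(v0 - target_ml) <= tol_ml:
        return mask, 1.0
    s_lo, s_hi = 1.0, 1.0
    ratio = (target_ml / v0) ** (1.0 / 3.0)
    if ratio > 1.0:
        s_hi = ratio * 1.25
        if vol(s_hi) < target_ml:
            raise CalibrationError("target volume not reachable inside the grid")
    else:
        s_lo = ratio * 0.8
    best_s, best_err = 1.0, abs(v0 - target_ml)
    for _ in range(max_iter):
        s = 0.5 * (s_lo + s_hi)
        v = vol(s)
        if abs(v - target_ml) < best_err:
            best_s, best_err = s, abs(v - target_ml)
        if best_err <= tol_ml or (s_hi - s_lo) < 1e-9:
            break
        if v < target_ml:
            s_lo = s
        else:
            s_hi = s
    if best_err > tol_ml:
        raise CalibrationError(
            f"calibration stalled at |V - target| = {best_err:.3f} mL > {tol_ml} mL"
        )
    return rasterize(best_s), best_s


def _calibrate_scalar(vol_of_scale, target_ml: float, tol_ml: float,
                      s_range=(0.7, 1.4), max_iter: int = 80) -> float:
    """Bisection on a monotone scale -> volume(mL) map."""
    s_lo, s_hi = s_range
    v_lo, v_hi = vol_of_scale(s_lo), vol_of_scale(s_hi)
    if not (v_lo <= target_ml <= v_hi):
        raise CalibrationError(
            f"target {target_ml} mL outside attainable range [{v_lo:.1f}, {v_hi:.1f}]"
        )
    best_s, best_err = 1.0, np.inf
    for _ in range(max_iter):
        s = 0.5 * (s_lo + s_hi)
        v = vol_of_scale(s)
        if abs(v - target_ml) < best_err:
            best_s, best_err = s, abs(v - target_ml)
        if best_err <= tol_ml or (s_hi - s_lo) < 1e-10:
            break
        if v < target_ml:
            s_lo = s
        else:
            s_hi = s
    if best_err > tol_ml:
        raise CalibrationError(
            f"calibration stalled at |V - target| = {best_err:.3f} mL > {tol_ml} mL"
        )
    return best_s


def build_reference_labels(grid: VoxelGrid | None = None,
                           config: AnatomyConfig | None = None,
                           table: StructureTable | None = None):
    """Rasterize the reference-phase label volume.

    Returns ``(LabelVolume, masks, info)`` where ``masks`` maps structure name
    to its boolean mask (a view of label equality) and ``info`` records the
    liver calibration scale and volume.  Raises ``InvalidConfigError`` if any
    table structure ends up empty or a shape leaves the FOV.
    """
    grid = grid or VoxelGrid()
    config = config or AnatomyConfig()
    table = table or StructureTable.default()
    _check_shapes_in_fov(grid, config.shapes)
    ev = _ShapeEval(grid, config.shapes)

    liver_scale = 1.0
    if config.liver_target_ml is not None:
        liver_scale = _calibrate_liver(grid, ev, config)

    labels = np.zeros(grid.shape, dtype=np.int16)
    body = ev.body_mask()
    for name in _PAINT_ORDER:
        scale = liver_scale if name == "liver" else 1.0
        m = ev.mask(name, scale=scale) & body
        labels[m] = table[name].id

    lv = LabelVolume(grid, labels)
    masks = {}
    for rec in table:
        if rec.name == "air":
            continue
        m = lv.mask(rec.id)
        if not m.any():
            raise InvalidConfigError(f"structure {rec.name!r} has no voxels")
        masks[rec.name] = m
    info = {
        "liver_scale": liver_scale,
        "liver_volume_ml": float(masks["liver"].sum()) * grid.voxel_volume_ml,
    }
    return lv, masks, info


def _check_shapes_in_fov(grid: VoxelGrid, shapes: dict) -> None:
    ext = grid.extent_mm
    for name, spec in shapes.items():
        subs = [spec]
        if spec.get("kind") == "pair":
            subs = [spec["left"], spec["right"]]
        for sub in subs:
            if "center" not in sub or len(sub["center"]) != 3:
                continue
            c = np.asarray(sub["center"], float)
            semi_key = "semi_outer" if "semi_outer" in sub else "semi"
            semi = np.asarray(sub.get(semi_key, (0, 0, 0)), float)
            if np.any(c - semi < -grid.spacing_mm) or np.any(c + semi > np.asarray(ext) + grid.spacing_mm):
                raise InvalidConfigError(f"shape {name!r} extends outside the grid FOV")


def _calibrate_liver(grid: VoxelGrid, ev: _ShapeEval, config: AnatomyConfig) -> float:
    """Scale the liver primitive so the painted (post-carve) mask hits target."""
    carve = False
    for name in _LIVER_CARVERS:
        carve = carve | ev.mask(name)
    carve = carve | ~ev.body_mask()
    tol = max(config.calibration_tol_ml, grid.voxel_volume_ml)

    def vol(scale: float) -> float:
        m = ev.mask("liver", scale=scale) & ~carve
        return float(m.sum()) * grid.voxel_volume_ml

    return _calibrate_scalar(vol, config.liver_target_ml, tol)


def place_tumor(liver_mask: np.ndarray, grid: VoxelGrid,
                spec: TumorSpec | None = None):
    """Resolve the tumor center and rasterize its spherical mask.

    The sphere must keep ``margin_mm`` of liver tissue between its surface and
    the liver boundary (checked on the liver's Euclidean distance transform).
    Returns ``(tumor_mask, resolved_spec)``.
    """
    spec = spec or TumorSpec()
    if not (spec.radius_mm > 0):
        raise PlacementError("tumor radius must be positive")
    liver_mask = np.asarray(liver_mask, bool)
    if not liver_mask.any():
        raise PlacementError("liver mask is empty")

    if spec.center_mm is None:
        com = ndimage.center_of_mass(liver_mask)
        ci, cj = int(round(com[0])), int(round(com[1]))
        col = np.nonzero(liver_mask[ci, cj, :])[0]
        if col.size == 0:
            raise PlacementError("liver centroid column does not intersect the liver")
        pole_z = grid.origin_mm[2] + col.max() * grid.spacing_mm
        center = (grid.origin_mm[0] + ci * grid.spacing_mm,
                  grid.origin_mm[1] + cj * grid.spacing_mm,
                  pole_z - spec.pole_offset_mm)
        spec = dataclasses.replace(spec, center_mm=center)
    center = np.asarray(spec.center_mm, float)

    dt = ndimage.distance_transform_edt(liver_mask, sampling=grid.spacing_mm)
    cidx = np.round(grid.world_to_index(center)).astype(int)
    if np.any(cidx < 0) or np.any(cidx >= np.asarray(grid.shape)):
        raise PlacementError("tumor center lies outside the grid")
    clearance = float(dt[tuple(cidx)])
    required = spec.radius_mm + spec.margin_mm
    if clearance < required:
        raise PlacementError(
            f"tumor needs {required:.1f} mm of liver clearance, found {clearance:.1f} mm"
        )

    x, y, z = grid.world_grid()
    rho2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    tumor = rho2 <= spec.radius_mm ** 2
    if not tumor.any():
        raise PlacementError("tumor mask is empty at this grid resolution")
    return tumor, spec


@dataclass
class Anatomy:
    """Bundle of the reference anatomy build."""

    labels: LabelVolume
    masks: dict
    tumor_mask: np.ndarray
    tumor: TumorSpec
    info: dict
    table: StructureTable


def build_anatomy(grid: VoxelGrid | None = None,
                  config: AnatomyConfig | None = None,
                  table: StructureTable | None = None,
                  with_tumor: bool = True) -> Anatomy:
    """Labels + resolved tumor in one call (the usual entry point)."""
    grid = grid or VoxelGrid()
    config = config or AnatomyConfig()
    table = table or StructureTable.default()
    labels, masks, info = build_reference_labels(grid, config, table)
    if with_tumor:
        tumor_mask, tumor = place_tumor(masks["liver"], grid, config.tumor)
    else:
        tumor_mask, tumor = np.zeros(grid.shape, bool), config.tumor
    return Anatomy(labels, masks, tumor_mask, tumor, info, table)
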