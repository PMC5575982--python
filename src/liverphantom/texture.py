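"""Synthetic MR appearance of the reference (EOE) volume.

The reference volume composites four tissue categories:

* category I organs get a deformably mapped donor texture with the A + B
  rule (uniform base ``A`` plus detail rescaled to mean ``B``),
* category II soft tissue is textured by iterative transplantation of 5^3,
  then 3^3, then 1^3 donor-muscle patches until every voxel is covered
  exactly once, followed by a mask-restricted 5^3 moving average,
* category III structures are uniform, with additive Rayleigh noise on the
  lungs and intestinal air,
* category IV bone is filled with placeholder muscle/body texture here and
  re-rendered with its uniform intensity per phase by the motion engine.

A spherical hypointense tumor with a quartic radial profile is inserted last.

The donor is itself synthetic: a jittered copy of the parametric anatomy
carrying a Gaussian-correlated random field (mean 100, sd 15, 4 mm
correlation length) with dark quasi-tubular vessel tracks in the liver — a
stand-in for a patient T1 VIBE scan.  Real donor volumes can be substituted
through the same :class:`DonorTexture` container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import demons
from .anatomy import Anatomy, AnatomyConfig, TumorSpec, build_anatomy, capsule
from .errors import InvalidArgumentError, MappingError, RescaleError
from .grid import ImageVolume, VoxelGrid
from .structures import (
    HEART_PARTS,
    MAPPED_ORGANS,
    NOISY_STRUCTURES,
    StructureTable,
)


# ---------------------------------------------------------------------------
# donor texture
# ---------------------------------------------------------------------------

@dataclass
class DonorTexture:
    """MR-like donor volume with per-organ masks and a muscle texture ROI."""

    volume: ImageVolume
    organ_masks: dict
    muscle_roi_slices: tuple

    @property
    def muscle_roi(self) -> np.ndarray:
        """The donor muscle texture block (values inside the ROI box)."""
        return self.volume.values[self.muscle_roi_slices]


def correlated_field(grid: VoxelGrid, seed, mean: float = 100.0, sd: float = 15.0,
                     correlation_mm: float = 4.0) -> np.ndarray:
    """Gaussian-correlated random field, clipped at zero."""
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(grid.shape).astype(np.float32)
    if sd <= 0:
        return np.full(grid.shape, mean, dtype=np.float32)
    smooth = ndimage.gaussian_filter(white, sigma=correlation_mm / grid.spacing_mm)
    smooth /= max(float(smooth.std()), 1e-12)
    return np.clip(mean + sd * smooth, 0.0, None).astype(np.float32)


def _vessel_mask(grid: VoxelGrid, liver_mask: np.ndarray, rng,
                 n_vessels: int = 8, radius_mm: float = 2.5) -> np.ndarray:
    """Random quasi-tubular tracks (2-segment polylines) inside the liver."""
    idx = np.argwhere(liver_mask)
    if idx.size == 0:
        return np.zeros(grid.shape, bool)
    xyz = grid.world_grid()
    mask = np.zeros(grid.shape, bool)
    for _ in range(n_vessels):
        pts = idx[rng.integers(0, len(idx), size=3)] * grid.spacing_mm
        pts = pts + np.asarray(grid.origin_mm)
        mask |= capsule(xyz, pts[0], pts[1], radius_mm)
        mask |= capsule(xyz, pts[1], pts[2], radius_mm)
    return mask & liver_mask


def make_donor_texture(grid: VoxelGrid, seed: int,
                       config: AnatomyConfig | None = None,
                       roi_center_mm=(310.0, 140.0, 120.0),
                       roi_size_mm: float = 48.0) -> DonorTexture:
    """Synthesize the donor scan: jittered anatomy + correlated texture.

    The muscle ROI is an axis-aligned ``roi_size_mm`` cube in a posterior
    soft-tissue region away from the vessel tracks; it samples the same
    homogeneous texture process and only serves as the patch source for
    category II pattern generation.
    """
    base = config or AnatomyConfig()
    donor_cfg = base.jittered(seed)
    anatomy = build_anatomy(grid, donor_cfg, with_tumor=False)
    rng = np.random.default_rng([int(seed), 0x0D0])

    values = correlated_field(grid, rng.integers(0, 2**31))
    vessels = _vessel_mask(grid, anatomy.masks["liver"], rng)
    values[vessels] *= 0.45

    organ_masks = {}
    for organ in MAPPED_ORGANS:
        if organ == "heart":
            m = np.zeros(grid.shape, bool)
            for part in HEART_PARTS:
                m |= anatomy.masks[part]
            organ_masks[organ] = m
        else:
            organ_masks[organ] = anatomy.masks[organ]

    half = roi_size_mm / 2.0
    lo = grid.world_to_index(np.asarray(roi_center_mm) - half)
    hi = grid.world_to_index(np.asarray(roi_center_mm) + half)
    sl = tuple(
        slice(max(0, int(np.ceil(l))), min(n, int(np.floor(h)) + 1))
        for l, h, n in zip(lo, hi, grid.shape)
    )
    roi_dims = tuple(s.stop - s.start for s in sl)
    if min(roi_dims) * grid.spacing_mm < 40.0 - grid.spacing_mm:
        raise InvalidArgumentError("donor muscle ROI must span at least 40 mm per axis")
    return DonorTexture(ImageVolume(grid, values), organ_masks, sl)


# ---------------------------------------------------------------------------
# intensity compositing
# ---------------------------------------------------------------------------

def rescale_mean(values: np.ndarray, mask: np.ndarray, target_mean: float):
    """Multiplicatively rescale masked values so their mean equals ``target``.

    Returns ``(rescaled_copy, factor)``.  Pure scaling preserves zero and the
    relative contrast of the detail texture.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise RescaleError("mask is empty")
    current = float(np.asarray(values)[mask].mean())
    if current <= 0:
        raise RescaleError(f"masked mean must be positive, got {current}")
    factor = target_mean / current
    out = np.array(values, dtype=np.float32, copy=True)
    out[mask] *= factor
    return out, factor


def compose_AB(volume: np.ndarray, base_a: float, detail: np.ndarray,
               mask: np.ndarray) -> np.ndarray:
    """In place: masked voxels become A + detail; others untouched."""
    mask = np.asarray(mask, bool)
    volume[mask] = base_a + np.asarray(detail)[mask]
    return volume


def add_rayleigh_noise(values: np.ndarray, mask: np.ndarray, mean_level: float,
                       seed) -> np.ndarray:
    """Add i.i.d. Rayleigh noise with the given sample mean to masked voxels.

    The Rayleigh scale is sigma = mean * sqrt(2 / pi), so the distribution's
    mean equals ``mean_level`` and its variance (2 - pi/2) sigma^2.
    """
    if mean_level < 0:
        raise InvalidArgumentError("mean noise level must be >= 0")
    out = np.array(values, dtype=np.float32, copy=True)
    if mean_level == 0:
        return out
    mask = np.asarray(mask, bool)
    rng = np.random.default_rng(seed)
    sigma = mean_level * np.sqrt(2.0 / np.pi)
    out[mask] += rng.rayleigh(scale=sigma, size=int(mask.sum())).astype(np.float32)
    return out


# ---------------------------------------------------------------------------
# category II pattern generation
# ---------------------------------------------------------------------------

@dataclass
class PatternState:
    """Provenance of one pattern-generation run (for verification)."""

    seed: int
    placements: list = field(default_factory=list)  # (size, donor_corner, soi_corner)
    pre_filter: np.ndarray | None = None
    bbox: tuple | None = None


def _window_sums(avail: np.ndarray, s: int) -> np.ndarray:
    """s^3 window sums at every top-left corner (integral image)."""
    c = avail.astype(np.int32)
    for ax in range(3):
        c = np.cumsum(c, axis=ax)
    c = np.pad(c, ((1, 0), (1, 0), (1, 0)))
    a = c[s:, s:, s:]
    return (
        a
        - c[:-s, s:, s:] - c[s:, :-s, s:] - c[s:, s:, :-s]
        + c[:-s, :-s, s:] + c[:-s, s:, :-s] + c[s:, :-s, :-s]
        - c[:-s, :-s, :-s]
    )


def generate_pattern(soi_mask: np.ndarray, donor_roi: np.ndarray, seed,
                     patch_sizes=(5, 3, 1), max_rejects: int = 200,
                     return_state: bool = False):
    """Iterative patch-transplant texture for one structure of interest.

    Random 5^3 donor blocks are copied to random fully-unassigned 5^3 sites
    inside the SOI until a scale is exhausted (verified by an exhaustive
    sliding-window scan once ``max_rejects`` consecutive random draws fail),
    then 3^3, then single voxels, so every SOI voxel is assigned exactly once.
    A mask-restricted 5^3 moving average smooths the result.  Deterministic
    given ``seed``; returns the detail volume (zeros outside the SOI), plus a
    :class:`PatternState` when ``return_state`` is set.
    """
    soi_mask = np.asarray(soi_mask, bool)
    if not soi_mask.any():
        raise InvalidArgumentError("SOI mask is empty")
    donor_roi = np.asarray(donor_roi, dtype=np.float32)
    if min(donor_roi.shape) < max(s for s in patch_sizes if s > 1):
        raise InvalidArgumentError("donor muscle ROI smaller than the largest patch")
    rng = np.random.default_rng(seed)
    state = PatternState(seed=seed)

    obj = ndimage.find_objects(soi_mask.astype(np.int8))[0]
    soi = soi_mask[obj]
    out = np.zeros(soi.shape, dtype=np.float32)
    avail = soi.copy()
    bbox_origin = np.array([s.start for s in obj])

    def place(size, si, sj, sk):
        di = rng.integers(0, donor_roi.shape[0] - size + 1)
        dj = rng.integers(0, donor_roi.shape[1] - size + 1)
        dk = rng.integers(0, donor_roi.shape[2] - size + 1)
        out[si:si + size, sj:sj + size, sk:sk + size] = \
            donor_roi[di:di + size, dj:dj + size, dk:dk + size]
        avail[si:si + size, sj:sj + size, sk:sk + size] = False
        state.placements.append((size, (di, dj, dk),
                                 tuple(bbox_origin + (si, sj, sk))))

    for size in (s for s in patch_sizes if s > 1):
        dom = tuple(n - size + 1 for n in soi.shape)
        if min(dom) < 1:
            continue
        rejects = 0
        exhausted = False
        while not exhausted:
            si = rng.integers(0, dom[0])
            sj = rng.integers(0, dom[1])
            sk = rng.integers(0, dom[2])
            if avail[si:si + size, sj:sj + size, sk:sk + size].all():
                place(size, si, sj, sk)
                rejects = 0
                continue
            rejects += 1
            if rejects < max_rejects:
                continue
            # exhaustive passes: enumerate remaining valid sites, visit in
            # random order, re-validating (earlier placements in the same
            # pass invalidate neighbors); stop when none remain.
            while True:
                sums = _window_sums(avail, size)
                corners = np.argwhere(sums == size ** 3)
                if corners.size == 0:
                    exhausted = True
                    break
                rng.shuffle(corners)
                placed_any = False
                for si, sj, sk in corners:
                    if avail[si:si + size, sj:sj + size, sk:sk + size].all():
                        place(size, si, sj, sk)
                        placed_any = True
                if not placed_any:
                    exhausted = True
                    break

    # final 1^3 pass: every remaining voxel gets one random donor voxel.
    rem = np.argwhere(avail)
    if rem.size:
        flat = donor_roi.ravel()
        picks = rng.integers(0, flat.size, size=len(rem))
        out[rem[:, 0], rem[:, 1], rem[:, 2]] = flat[picks]
        for (si, sj, sk), p in zip(rem, picks):
            state.placements.append(
                (1, tuple(np.unravel_index(p, donor_roi.shape)),
                 tuple(bbox_origin + (si, sj, sk))))
        avail[rem[:, 0], rem[:, 1], rem[:, 2]] = False
    assert not avail.any()

    state.pre_filter = out.copy()
    state.bbox = obj

    # mask-restricted normalized 5^3 moving average
    num = ndimage.uniform_filter(out * soi, size=5)
    den = ndimage.uniform_filter(soi.astype(np.float32), size=5)
    smoothed = np.where(soi, num / np.maximum(den, 1e-12), 0.0).astype(np.float32)

    detail = np.zeros(soi_mask.shape, dtype=np.float32)
    detail[obj] = smoothed
    if return_state:
        return detail, state
    return detail


# ---------------------------------------------------------------------------
# category I deformable mapping
# ---------------------------------------------------------------------------

def _bbox_union(masks, shape, margin):
    lo = np.array(shape)
    hi = np.zeros(3, int)
    for m in masks:
        idx = np.argwhere(m)
        if idx.size == 0:
            continue
        lo = np.minimum(lo, idx.min(axis=0))
        hi = np.maximum(hi, idx.max(axis=0) + 1)
    lo = np.maximum(lo - margin, 0)
    hi = np.minimum(hi + margin, shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def map_category1_texture(donor: DonorTexture, organ: str, phantom_mask: np.ndarray,
                          grid: VoxelGrid, target_mean_b: float,
                          params: "demons.DemonsParams | None" = None,
                          dice_floor: float = 0.90):
    """Warp a donor organ texture onto the phantom organ mask.

    Runs the mask-driven Demons registration (donor organ -> phantom mask) on
    a cropped working box, pulls the donor texture through the resulting
    backward field, fills any uncovered phantom voxels from their nearest
    covered neighbor, and rescales the detail to mean ``target_mean_b`` over
    the phantom mask.  Raises :class:`MappingError` if the registration Dice
    ends below ``dice_floor``.

    Returns ``(detail, info)`` with the warped-support volume, Dice and the
    percent volume difference to the phantom mask in ``info``.
    """
    moving = np.asarray(donor.organ_masks[organ], bool)
    fixed = np.asarray(phantom_mask, bool)
    margin = max(8, int(round(20.0 / grid.spacing_mm)))
    box = _bbox_union([moving, fixed], grid.shape, margin)

    field, info = demons.demons_register(
        moving[box], fixed[box], grid.spacing_mm, params)
    if info["dice"] < dice_floor:
        raise MappingError(
            f"{organ}: registration diverged (Dice {info['dice']:.3f} < {dice_floor})"
        )
    warped, support = demons.apply_field_to_texture(
        donor.volume.values[box], moving[box], field, grid.spacing_mm)

    fixed_c = fixed[box]
    uncovered = fixed_c & ~support
    if uncovered.any():
        _, (ii, jj, kk) = ndimage.distance_transform_edt(
            ~support, return_indices=True)
        warped = np.where(support, warped, warped[ii, jj, kk])

    detail_c = np.where(fixed_c, warped, 0.0).astype(np.float32)
    detail = np.zeros(grid.shape, dtype=np.float32)
    detail[box] = detail_c
    detail, factor = rescale_mean(detail, fixed, target_mean_b)

    support_ml = float(support.sum()) * grid.voxel_volume_ml
    info = dict(info)
    info.update(
        support_volume_ml=support_ml,
        mask_volume_ml=float(fixed.sum()) * grid.voxel_volume_ml,
        volume_difference_pct=demons.volume_difference(support, fixed_c),
        rescale_factor=factor,
    )
    return detail, info


# ---------------------------------------------------------------------------
# tumor
# ---------------------------------------------------------------------------

def tumor_depression(rho_mm, radius_mm: float = 15.0, delta0: float = 100.0):
    """Quartic radial depression: delta0 (1 - (rho/r)^2)^2 inside, 0 outside.

    Value and slope both vanish at the rim, giving a smooth liver/tumor
    transition; the center is depressed by exactly ``delta0``.
    """
    rho = np.asarray(rho_mm, dtype=float)
    u2 = np.clip((rho / radius_mm) ** 2, 0.0, 1.0)
    return delta0 * (1.0 - u2) ** 2


def insert_tumor(values: np.ndarray, grid: VoxelGrid, spec: TumorSpec,
                 liver_mask: np.ndarray, local_ball_mm: float = 30.0):
    """Subtract the tumor profile from the textured liver.

    The local liver level is the mean intensity over liver voxels within a
    ``local_ball_mm`` ball of the tumor center.  Inside the tumor the texture
    is blended toward that level with the same quartic weight before the
    depression is subtracted, so the center intensity equals exactly
    ``local_mean - delta0`` while the rim joins the untouched texture
    smoothly.  Returns ``(new_values, local_mean)``.
    """
    center = np.asarray(spec.center_mm, float)
    x, y, z = grid.world_grid()
    rho2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    ball = (rho2 <= local_ball_mm ** 2) & np.asarray(liver_mask, bool)
    if not ball.any():
        raise InvalidArgumentError("no liver voxels near the tumor center")
    local_mean = float(np.asarray(values)[ball].mean())

    out = np.array(values, dtype=np.float32, copy=True)
    inside = rho2 <= spec.radius_mm ** 2
    rho = np.sqrt(rho2[inside])
    w = (1.0 - (rho / spec.radius_mm) ** 2) ** 2
    tex = out[inside]
    out[inside] = tex + w * (local_mean - tex) - spec.delta0 * w
    return out, local_mean


# ---------------------------------------------------------------------------
# full reference build
# ---------------------------------------------------------------------------

def assign_cat4_hosts(anatomy: Anatomy) -> dict:
    """Decide the placeholder host ('muscle' or 'body') per bone structure.

    Majority label within a 2-voxel dilation shell; ties and shells touching
    neither default to 'body'.
    """
    table = anatomy.table
    muscle_id, body_id = table["muscle"].id, table["body"].id
    hosts = {}
    for rec in table.of_category("IV"):
        mask = anatomy.masks[rec.name]
        shell = ndimage.binary_dilation(mask, iterations=2) & ~mask
        lbl = anatomy.labels.labels[shell]
        n_muscle = int((lbl == muscle_id).sum())
        n_body = int((lbl == body_id).sum())
        hosts[rec.name] = "muscle" if n_muscle > n_body else "body"
    return hosts


def build_reference_volume(anatomy: Anatomy, donor: DonorTexture,
                           table: StructureTable | None = None, seed: int = 0,
                           noise_mean: float = 5.0,
                           demons_params: "demons.DemonsParams | None" = None):
    """Composite the full reference-phase MR volume.

    Returns ``(ImageVolume, extras)`` where ``extras`` holds per-organ mapping
    quality, the category IV host assignment and the tumor's local liver mean.
    """
    table = table or anatomy.table
    grid = anatomy.labels.grid
    labels = anatomy.labels.labels
    values = np.zeros(grid.shape, dtype=np.float32)
    extras = {"mapping": {}, "cat4_hosts": {}, "seed": seed}
    ss = np.random.SeedSequence(entropy=int(seed) % (2**31))
    child = {name: s for name, s in zip(
        ("noise", "muscle", "body", "static_marrow", "intestine_wall"),
        ss.spawn(5))}

    # ambient air
    values[labels == 0] = table["air"].base_A

    # category III: uniform A (+ Rayleigh noise on lungs / intestinal air)
    for rec in table.of_category("III"):
        if rec.name == "air":
            continue
        values[anatomy.masks[rec.name]] = rec.base_A
    noise_rng = np.random.default_rng(child["noise"])
    for name in NOISY_STRUCTURES:
        values = add_rayleigh_noise(values, anatomy.masks[name], noise_mean,
                                    noise_rng.integers(0, 2**31))

    # category IV placeholders join their host SOI
    hosts = assign_cat4_hosts(anatomy)
    extras["cat4_hosts"] = hosts
    soi = {
        "muscle": anatomy.masks["muscle"].copy(),
        "body": anatomy.masks["body"].copy(),
        "static_marrow": anatomy.masks["static_marrow"],
        "intestine_wall": anatomy.masks["intestine_wall"],
    }
    for bone, host in hosts.items():
        soi[host] |= anatomy.masks[bone]

    # category II pattern generation + A + B compositing
    roi = donor.muscle_roi
    for name in ("muscle", "body", "static_marrow", "intestine_wall"):
        rec = table[name]
        detail = generate_pattern(soi[name], roi, child[name])
        detail, _ = rescale_mean(detail, soi[name], rec.detail_B)
        compose_AB(values, rec.base_A, detail, soi[name])

    # category I deformable texture mapping + A + B compositing
    for organ in MAPPED_ORGANS:
        if organ == "heart":
            mask = np.zeros(grid.shape, bool)
            for part in HEART_PARTS:
                mask |= anatomy.masks[part]
            b = table["myocardium"].detail_B
        else:
            mask = anatomy.masks[organ]
            b = table[organ].detail_B
        detail, info = map_category1_texture(donor, organ, mask, grid, b,
                                             params=demons_params)
        extras["mapping"][organ] = info
        if organ == "heart":
            for part in HEART_PARTS:
                rec = table[part]
                part_detail, _ = rescale_mean(detail, anatomy.masks[part],
                                              rec.detail_B)
                compose_AB(values, rec.base_A, part_detail, anatomy.masks[part])
        else:
            compose_AB(values, table[organ].base_A, detail, mask)

    # tumor last
    if anatomy.tumor_mask.any():
        values, local_mean = insert_tumor(values, grid, anatomy.tumor,
                                          anatomy.masks["liver"])
        extras["tumor_local_mean"] = local_mean

    np.clip(values, 0.0, None, out=values)
    return ImageVolume(grid, values), extras
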