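"""Respiratory deformation: forward DVF synthesis, inversion, repair, warping
and per-phase assembly of the 4-D series.

The forward (reference -> phase) field is a per-structure rigid translation
model: each structure carries a fraction (kappa_si, kappa_ap) of the preset's
diaphragm/chest amplitude, scaled through the motion-time curve m(t).  The
piecewise-constant field is blended by Dirichlet relaxation: the exact rigid
vectors are pinned inside each category I organ core (mask eroded by 6 mm),
in the posterior spine complex (zero) and in the outer anterior chest-wall
shell (full AP amplitude), while diffusion passes drive the free region
toward the harmonic interpolation of those values — the gentlest transitions
the core geometry allows, which keeps the map invertible.  Ambient air rides
the nearest body-surface motion with exponential decay, so the expanding
chest pushes into co-moving air instead of folding the field at the skin.

Because every contribution scales with m(t), the unit field (m = 1) is built
once per preset and phases only rescale it; backward fields are obtained by
fixed-point inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidArgumentError, InversionError
from .grid import DisplacementField, ImageVolume, LabelVolume, PhaseSeries, VoxelGrid
from .structures import (
    CHEST_WALL_BONES,
    MOTION_CURVE,
    MotionPreset,
    SPINE_COMPLEX,
    StructureTable,
    get_preset,
    phase_times,
)


@dataclass(frozen=True)
class MotionParams:
    """Numerical knobs of the forward-field synthesis (lengths in mm)."""

    erosion_mm: float = 6.0
    shell_depth_mm: float = 15.0
    air_decay_mm: float = 30.0
    #: blending runs as Dirichlet relaxation: this many coarse-grid diffusion
    #: passes (plus 1/8 as many fine passes) with the rigid core vectors
    #: re-imposed after each, so blended transitions live between eroded
    #: cores and the forward map stays invertible.
    relax_steps: int = 100


def _resample_to(arr: np.ndarray, shape, order: int = 1) -> np.ndarray:
    """Resample an array to an arbitrary shape (linear, endpoint-aligned)."""
    if arr.shape == tuple(shape):
        return arr.copy()
    coords = np.meshgrid(*[
        np.linspace(0.0, s0 - 1.0, s1) for s0, s1 in zip(arr.shape, shape)
    ], indexing="ij", sparse=False)
    return ndimage.map_coordinates(arr, coords, order=order, mode="nearest")


def _relax_passes(comps, fixed, fval, sigma_vox: float, steps: int) -> None:
    for _ in range(int(steps)):
        for c in range(3):
            comps[c][...] = ndimage.gaussian_filter(comps[c], sigma_vox)
            comps[c][fixed[c]] = fval[c][fixed[c]]


def _dirichlet_relax(comps, fixed, fval, sigma_fine_vox: float,
                     fine_steps: int, coarse_steps: int,
                     coarse_factor: int = 4) -> None:
    """Relax toward the Dirichlet (harmonic) interpolation of pinned values.

    Long-range equilibration runs on a ``coarse_factor``-downsampled grid
    (cheap), the result is upsampled and polished with a few fine passes, and
    the pinned values are re-imposed exactly at the end.
    """
    shape = comps[0].shape
    cshape = tuple(max(8, s // coarse_factor) for s in shape)
    if coarse_steps > 0 and all(c < s for c, s in zip(cshape, shape)):
        cc = [_resample_to(c, cshape) for c in comps]
        cfix, cval = [], []
        for f, v in zip(fixed, fval):
            fw = _resample_to(f.astype(np.float32), cshape)
            cfix.append(fw > 0.6)
            # normalized resampling keeps pinned values unbiased at core edges
            cval.append(_resample_to(v * f, cshape) / np.maximum(fw, 1e-3))
        _relax_passes(cc, cfix, cval, 1.0, coarse_steps)
        for c in range(3):
            comps[c][...] = _resample_to(cc[c], shape)
    _relax_passes(comps, fixed, fval, sigma_fine_vox, max(1, fine_steps))
    for c in range(3):
        comps[c][fixed[c]] = fval[c][fixed[c]]


class MotionModel:
    """Precomputed unit forward field (m = 1) for one preset on one anatomy."""

    def __init__(self, labels: LabelVolume, table: StructureTable,
                 preset: MotionPreset, params: MotionParams | None = None):
        self.grid = labels.grid
        self.table = table
        self.preset = preset
        self.params = params or MotionParams()
        ids = labels.present_ids()
        for i in ids:
            if int(i) not in table:
                raise InvalidArgumentError(f"label {int(i)} not in the structure table")
        self.unit_vectors = self._build_unit(labels)

    # -- construction ----------------------------------------------------
    @staticmethod
    def _eroded(mask: np.ndarray, spacing_mm: float, erosion_mm: float = 6.0):
        """(bounding slices, eroded core within them) of a structure mask."""
        obj = ndimage.find_objects(mask.astype(np.int8))[0]
        obj = tuple(slice(max(0, s.start - 1), min(n, s.stop + 1))
                    for s, n in zip(obj, mask.shape))
        dt = ndimage.distance_transform_edt(mask[obj], sampling=spacing_mm)
        return obj, dt >= erosion_mm

    def _build_unit(self, labels: LabelVolume) -> np.ndarray:
        grid, table, preset, params = self.grid, self.table, self.preset, self.params
        sp = grid.spacing_mm
        lab = labels.labels
        base_a, ksi, kap = table.lookup_arrays()

        amp_si = preset.diaphragm_mm
        amp_ap = preset.chest_ap_mm
        uy = (kap[lab] * amp_ap).astype(np.float32)
        uz = (-ksi[lab] * amp_si).astype(np.float32)
        ux = np.zeros_like(uy)

        body = lab != 0
        depth = ndimage.distance_transform_edt(body, sampling=sp)
        jj = np.arange(grid.shape[1])[None, :, None]
        j_com = float(ndimage.center_of_mass(body)[1])
        shell_ids = [table[n].id for n in ("body", "muscle", *CHEST_WALL_BONES)]
        shell = (
            body
            & (depth <= params.shell_depth_mm)
            & np.broadcast_to(jj > j_com, grid.shape)
            & np.isin(lab, shell_ids)
        )
        uy[shell] = amp_ap
        self.anterior_shell = shell

        # Dirichlet regions: rigid vectors inside 6 mm-eroded category I
        # cores and the spine complex (zero); the outer part of the anterior
        # shell keeps the full AP amplitude.
        cores = []
        # a transition band needs at least ~2 voxels; on coarse grids the
        # erosion depth is floored accordingly.
        ero = max(params.erosion_mm, 2.0 * sp)
        spine = np.isin(lab, [table[n].id for n in SPINE_COMPLEX])
        cores.append(self._eroded(spine, sp, ero) + ((0.0, 0.0, 0.0),))
        # where another organ's core would sit hard against the liver's, the
        # softer organ yields (its core is released in the contact zone) so
        # two rigid bodies never pinch the transition to folding.
        liver_mask = lab == table["liver"].id
        liver_dt = ndimage.distance_transform_edt(~liver_mask, sampling=sp)
        contact = liver_dt <= ero + 4.0
        for rec in table.of_category("I"):
            mask = lab == rec.id
            if not mask.any():
                continue
            obj, core = self._eroded(mask, sp, ero)
            if rec.name not in ("liver", "gallbladder"):
                core &= ~contact[obj]
            # opening blunts sharp core tips (organ poles), whose pinned
            # points would otherwise anchor steep local gradients.
            core = ndimage.binary_opening(core, iterations=2)
            if core.any():
                cores.append((obj, core, (0.0, rec.kappa_ap * amp_ap,
                                          -rec.kappa_si * amp_si)))
        shell_core = shell & (depth <= params.shell_depth_mm - ero)
        if shell_core.any():
            obj = ndimage.find_objects(shell_core.astype(np.int8))[0]
            cores.append((obj, shell_core[obj], (None, amp_ap, None)))

        # dense pin masks / values per component
        comps = (ux, uy, uz)
        fixed = [np.zeros(grid.shape, bool) for _ in range(3)]
        fval = [np.zeros(grid.shape, np.float32) for _ in range(3)]
        for obj, core, v in cores:
            for c, vc in enumerate(v):
                if vc is not None:
                    fixed[c][obj][core] = True
                    fval[c][obj][core] = vc

        # coarse-to-fine Dirichlet relaxation: diffusion passes with the core
        # vectors re-imposed after each drive the free region toward the
        # harmonic interpolation of the pinned values, whose gradients are as
        # gentle as the core geometry allows (max principle) — this is what
        # keeps the forward map diffeomorphic and its inverse computable.
        _dirichlet_relax(comps, fixed, fval, sigma_fine_vox=1.0,
                         fine_steps=max(1, int(params.relax_steps) // 8),
                         coarse_steps=int(params.relax_steps))

        # ambient air rides the nearest body-surface motion with exponential
        # decay, so the expanding chest wall pushes into co-moving air; the
        # nearest-neighbor extrapolation is then relaxed (body pinned) to
        # iron out seams between differently moving surface patches.
        air = ~body
        dist, idx_nb = ndimage.distance_transform_edt(air, sampling=sp,
                                                      return_indices=True)
        decay = np.exp(-dist[air] / params.air_decay_mm).astype(np.float32)
        nb = tuple(idx_nb[c][air] for c in range(3))
        sigma_air = max(5.0 / sp, 1.0)
        for comp in comps:
            comp[air] = comp[nb] * decay
            inside = comp[body]
            for _ in range(3):
                comp[...] = ndimage.gaussian_filter(comp, sigma_air)
                comp[body] = inside

        return np.stack([ux, uy, uz], axis=-1)

    # -- evaluation ------------------------------------------------------
    def forward(self, t: float, curve=MOTION_CURVE) -> DisplacementField:
        m = float(curve(t))
        return DisplacementField(self.grid, self.unit_vectors * np.float32(m),
                                 direction="forward")

    def structure_shift_mm(self, name: str, t: float, curve=MOTION_CURVE):
        """Nominal rigid displacement of a structure's core at time t."""
        rec = self.table[name]
        m = float(curve(t))
        return np.array([0.0, rec.kappa_ap * self.preset.chest_ap_mm * m,
                         -rec.kappa_si * self.preset.diaphragm_mm * m])


def build_forward_dvf(labels: LabelVolume, preset, t: float,
                      table: StructureTable | None = None,
                      params: MotionParams | None = None) -> DisplacementField:
    """One-shot forward field (use :class:`MotionModel` for whole series)."""
    if isinstance(preset, str):
        preset = get_preset(preset)
    table = table or StructureTable.default()
    return MotionModel(labels, table, preset, params).forward(t)


# ---------------------------------------------------------------------------
# inversion, repair, warping
# ---------------------------------------------------------------------------

def invert_dvf(forward: DisplacementField, max_iter: int = 50,
               tol_update_mm: float | None = None,
               tol_residual_mm: float | None = None,
               raise_on_fail: bool = True):
    """Fixed-point inversion: u_b <- -u_f(x + u_b(x)).

    Iterates until the max update falls below 0.01 voxel (or ``max_iter``),
    then checks the composition residual ``|u_f(x + u_b) + u_b|_inf`` over
    voxels whose pullback stays in-grid; a residual above 0.05 voxel raises
    :class:`InversionError` unless ``raise_on_fail`` is false.

    Returns ``(backward_field, info)``.
    """
    grid = forward.grid
    sp = grid.spacing_mm
    if tol_update_mm is None:
        tol_update_mm = 0.01 * sp
    if tol_residual_mm is None:
        tol_residual_mm = 0.05 * sp
    fwd = forward.vectors.astype(np.float32, copy=False)
    idx = np.indices(grid.shape, dtype=np.float32)

    ub = -fwd.copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        coords = idx + np.moveaxis(ub, -1, 0) / sp
        new = np.empty_like(ub)
        for c in range(3):
            new[..., c] = -ndimage.map_coordinates(fwd[..., c], coords, order=1,
                                                   mode="nearest")
        delta = float(np.max(np.abs(new - ub)))
        ub = new
        if delta < tol_update_mm:
            break

    resid, in_grid = _composition_residual(fwd, ub, sp)
    residual = float(resid[in_grid].max()) if in_grid.any() else 0.0

    # The plain iteration contracts wherever the forward Jacobian's spectral
    # radius is < 1; in small high-shear pockets it can stall even though the
    # map is invertible, so voxels still above tolerance get a vectorized
    # per-voxel Newton polish on  F(w) = u_f(x + w) + w = 0.
    n_refined = 0
    flag = in_grid & (resid > 0.5 * tol_residual_mm)
    if flag.any():
        ub = _newton_refine(fwd, ub, flag, sp)
        resid, in_grid = _composition_residual(fwd, ub, sp)
        residual = float(resid[in_grid].max()) if in_grid.any() else 0.0
        n_refined = int(flag.sum())

    info = {"iterations": n_iter, "residual_mm": residual,
            "residual_vox": residual / sp, "newton_refined": n_refined}
    if residual > tol_residual_mm and raise_on_fail:
        raise InversionError(
            f"DVF inversion residual {residual:.3f} mm exceeds "
            f"{tol_residual_mm:.3f} mm after {n_iter} iterations",
            residual_mm=residual,
        )
    return DisplacementField(grid, ub, direction="backward"), info


def _composition_residual(fwd: np.ndarray, ub: np.ndarray, sp: float):
    """Max-abs component of u_f(x + u_b) + u_b, and the in-grid pullback mask."""
    idx = np.indices(fwd.shape[:3], dtype=np.float32)
    coords = idx + np.moveaxis(ub, -1, 0) / sp
    in_grid = np.ones(fwd.shape[:3], bool)
    for c in range(3):
        in_grid &= (coords[c] >= 0) & (coords[c] <= fwd.shape[c] - 1)
    resid = np.zeros(fwd.shape[:3], np.float32)
    for c in range(3):
        comp = ndimage.map_coordinates(fwd[..., c], coords, order=1, mode="nearest")
        np.maximum(resid, np.abs(comp + ub[..., c]), out=resid)
    return resid, in_grid


def _newton_refine(fwd: np.ndarray, ub: np.ndarray, flag: np.ndarray,
                   sp: float, iters: int = 12) -> np.ndarray:
    """Per-voxel Newton iterations on the flagged voxels (independent roots)."""
    grad = np.empty(fwd.shape[:3] + (3, 3), np.float32)
    for c in range(3):
        for ax in range(3):
            grad[..., c, ax] = np.gradient(fwd[..., c], sp, axis=ax)
    pts = np.argwhere(flag).astype(np.float32)
    w = ub[flag].astype(np.float64)
    eye = np.eye(3)
    for _ in range(iters):
        coords = (pts + w / sp).T
        uf = np.stack([ndimage.map_coordinates(fwd[..., c], coords, order=1,
                                               mode="nearest") for c in range(3)],
                      axis=-1)
        r = uf + w
        jac = np.stack([
            ndimage.map_coordinates(grad[..., c, ax], coords, order=1,
                                    mode="nearest")
            for c in range(3) for ax in range(3)
        ], axis=-1).reshape(-1, 3, 3)
        a = eye + jac
        ok = np.abs(np.linalg.det(a)) > 1e-3
        step = np.zeros_like(w)
        if ok.any():
            step[ok] = np.linalg.solve(a[ok], r[ok, :, None])[..., 0]
        nrm = np.linalg.norm(step, axis=1, keepdims=True)
        np.clip(nrm, None, 2.0 * sp, out=nrm)
        step = np.where(nrm > 0, step * nrm / np.maximum(
            np.linalg.norm(step, axis=1, keepdims=True), 1e-12), step)
        w -= step
    out = ub.copy()
    out[flag] = w.astype(np.float32)
    return out


_N26 = [(di, dj, dk)
        for di in (-1, 0, 1) for dj in (-1, 0, 1) for dk in (-1, 0, 1)
        if (di, dj, dk) != (0, 0, 0)]


def _shift(a: np.ndarray, off) -> np.ndarray:
    """Edge-replicated shift (neighbor value at x + off)."""
    pad = np.pad(a, 1, mode="edge")
    i, j, k = off
    n = a.shape
    return pad[1 + i:1 + i + n[0], 1 + j:1 + j + n[1], 1 + k:1 + k + n[2]]


def repair_dvf(field: DisplacementField, dev_mm: float = 2.0,
               agree_mm: float = 0.5, agree_count: int = 20,
               max_sweeps: int = 2):
    """Morphological DVF repair: fill isolated holes / remove spur voxels.

    A voxel is flagged per component when it deviates from its 3^3
    neighborhood median by more than ``dev_mm`` while at least ``agree_count``
    of its 26 neighbors agree with that median within ``agree_mm`` (so
    coherent clusters are left alone); flagged values are replaced by the
    median.  At most ``max_sweeps`` sweeps.  Returns ``(field, n_repaired)``.
    """
    vec = field.vectors.astype(np.float32, copy=True)
    total = 0
    for _ in range(max_sweeps):
        repaired = 0
        for c in range(3):
            comp = vec[..., c]
            med = ndimage.median_filter(comp, size=3, mode="nearest")
            agree = np.zeros(comp.shape, np.int16)
            for off in _N26:
                agree += (np.abs(_shift(comp, off) - med) <= agree_mm)
            flag = (np.abs(comp - med) > dev_mm) & (agree >= agree_count)
            n = int(flag.sum())
            if n:
                comp[flag] = med[flag]
                repaired += n
        total += repaired
        if repaired == 0:
            break
    return DisplacementField(field.grid, vec, field.direction), total


def warp_volume(reference: ImageVolume, backward: DisplacementField,
                order: int = 3, fill_value: float = 40.0) -> ImageVolume:
    """Pull reference intensities through a backward field.

    Tricubic (B-spline, interpolating) by default; out-of-grid pullbacks are
    filled with the ambient-air intensity.
    """
    grid = reference.grid
    if not grid.compatible(backward.grid):
        raise InvalidArgumentError("volume and field must share one grid")
    sp = grid.spacing_mm
    idx = np.indices(grid.shape, dtype=np.float64)
    coords = idx + np.moveaxis(backward.vectors.astype(np.float64), -1, 0) / sp
    out = ndimage.map_coordinates(reference.values.astype(np.float64), coords,
                                  order=order, mode="nearest")
    in_grid = np.ones(grid.shape, bool)
    for c in range(3):
        in_grid &= (coords[c] >= 0) & (coords[c] <= grid.shape[c] - 1)
    out[~in_grid] = fill_value
    return ImageVolume(grid, out.astype(np.float32))


def warp_labels(labels: LabelVolume, backward: DisplacementField) -> LabelVolume:
    """Nearest-neighbor pullback of structure labels (air outside)."""
    grid = labels.grid
    if not grid.compatible(backward.grid):
        raise InvalidArgumentError("labels and field must share one grid")
    idx = np.indices(grid.shape, dtype=np.float32)
    coords = idx + np.moveaxis(backward.vectors, -1, 0) / grid.spacing_mm
    out = ndimage.map_coordinates(labels.labels, coords, order=0,
                                  mode="constant", cval=0)
    return LabelVolume(grid, out)


# ---------------------------------------------------------------------------
# phase assembly
# ---------------------------------------------------------------------------

#: the weighted smoothing kernel is a 5^3 truncated Gaussian on the native
#: 1.6719 mm grid; its physical scale (sigma 1.25 voxels, +-2 voxel window)
#: is held fixed in mm so coarser working grids apply the same smoothing.
_KERNEL_SIGMA_MM = 1.25 * 1.6719
_KERNEL_HALFWIDTH_MM = 2.0 * 1.6719


def _gaussian_taps(spacing_mm: float) -> np.ndarray:
    half = int(_KERNEL_HALFWIDTH_MM / spacing_mm + 1e-6)
    x = np.arange(-half, half + 1, dtype=np.float64) * spacing_mm
    w = np.exp(-x ** 2 / (2.0 * _KERNEL_SIGMA_MM ** 2))
    return w / w.sum()


def weighted_smooth_5(values: np.ndarray, spacing_mm: float = 1.6719) -> np.ndarray:
    """Separable center-weighted moving average (5^3 on the native grid)."""
    taps = _gaussian_taps(spacing_mm)
    out = values.astype(np.float32, copy=True)
    if len(taps) == 1:
        return out
    for ax in range(3):
        out = ndimage.correlate1d(out, taps, axis=ax, mode="nearest")
    return out


class MotionEngine:
    """Warps one reference build through the breathing cycle."""

    def __init__(self, reference: ImageVolume, labels: LabelVolume,
                 table: StructureTable, preset, params: MotionParams | None = None,
                 curve=MOTION_CURVE):
        if isinstance(preset, str):
            preset = get_preset(preset)
        self.reference = reference
        self.labels = labels
        self.table = table
        self.preset = preset
        self.curve = curve
        self.model = MotionModel(labels, table, preset, params)

        lab = labels.labels
        self._static_marrow = lab == table["static_marrow"].id
        spine_union = np.isin(lab, [table[n].id for n in SPINE_COMPLEX])
        self._fusion_shell = (
            ndimage.binary_dilation(spine_union) & ~ndimage.binary_erosion(spine_union)
        )
        self._cat4 = [(table[r.name].id, r.base_A)
                      for r in table.of_category("IV")]
        self._air_a = table["air"].base_A

    def assemble_phase(self, t: float, keep_fields: bool = False):
        """Render one phase volume.

        Pipeline: forward field -> repair -> invert -> warp volume + labels ->
        per-phase uniform category IV -> static-marrow re-insertion -> 3^3
        fusion filter on the spine/marrow interface shell -> weighted 5^3
        smoothing everywhere else.  Returns ``(ImageVolume, info)``.
        """
        m = float(self.curve(t))
        info = {"t_s": t, "amplitude_fraction": m}
        if m == 0.0:
            warped = self.reference.copy()
            phase_labels = self.labels.copy()
            backward = DisplacementField.zero(self.labels.grid, "backward")
            forward = DisplacementField.zero(self.labels.grid, "forward")
            info["inversion"] = {"iterations": 0, "residual_mm": 0.0,
                                 "residual_vox": 0.0}
        else:
            forward = self.model.forward(t, self.curve)
            forward, n_rep = repair_dvf(forward)
            info["repaired_voxels"] = n_rep
            backward, inv = invert_dvf(forward)
            info["inversion"] = inv
            warped = warp_volume(self.reference, backward,
                                 fill_value=self._air_a)
            phase_labels = warp_labels(self.labels, backward)

        vals = warped.values
        for sid, a in self._cat4:
            vals[phase_labels.labels == sid] = a
        vals[self._static_marrow] = self.reference.values[self._static_marrow]
        fused = ndimage.uniform_filter(vals, size=3)
        vals[self._fusion_shell] = fused[self._fusion_shell]
        smoothed = weighted_smooth_5(vals, warped.grid.spacing_mm)
        vals = np.where(self._fusion_shell, vals, smoothed).astype(np.float32)

        out = ImageVolume(warped.grid, vals)
        if keep_fields:
            info["forward"] = forward
            info["backward"] = backward
        return out, info

    def build_series(self, n_phases: int = 10, cycle_s: float = 5.0,
                     keep_fields: bool = False) -> PhaseSeries:
        times = phase_times(n_phases, cycle_s)
        phases, infos = [], []
        for t in times:
            vol, info = self.assemble_phase(t, keep_fields=keep_fields)
            phases.append(vol)
            infos.append(info)
        meta = {
            "preset": self.preset.name,
            "diaphragm_cm": self.preset.diaphragm_cm,
            "chest_ap_cm": self.preset.chest_ap_cm,
            "n_phases": n_phases,
            "cycle_s": cycle_s,
            "grid_dims": list(self.labels.grid.dims),
            "spacing_mm": self.labels.grid.spacing_mm,
            "phase_info": infos,
        }
        return PhaseSeries(phases, times, meta)


def build_4d_series(reference: ImageVolume, labels: LabelVolume,
                    table: StructureTable, preset, seed: int | None = None,
                    params: MotionParams | None = None,
                    n_phases: int = 10, cycle_s: float = 5.0) -> PhaseSeries:
    """10-phase 4-D series for one breathing preset (thin wrapper)."""
    engine = MotionEngine(reference, labels, table, preset, params)
    series = engine.build_series(n_phases=n_phases, cycle_s=cycle_s)
    if seed is not None:
        series.metadata["seed"] = int(seed)
    return series
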