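"""Quantitative validation: tumor segmentation, volume and COM kinematics.

The tumor is re-segmented in every rendered phase by an algorithmic surrogate
for manual contouring: within a search ball around the tumor's nominal phase
position, voxels whose depression below the local liver background (median of
the ball's outer shell) exceeds half the tumor's center depth are kept, and
the largest connected component is returned.  The half-depth rule selects the
analytic radius r sqrt(1 - 2^-1/2) ~= 0.54 r, so the absolute segmented
volume (~2.2 cm^3 for r = 15 mm) is by design smaller than the full sphere;
volume *stability* across phases and COM excursions are the meaningful
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .anatomy import TumorSpec
from .errors import InvalidArgumentError, SegmentationError
from .grid import ImageVolume, PhaseSeries, VoxelGrid


def measure_volume(mask: np.ndarray, grid: VoxelGrid) -> float:
    """Voxel count times voxel volume, in cm^3."""
    return int(np.asarray(mask, bool).sum()) * grid.voxel_volume_mm3 / 1000.0


def center_of_mass(mask: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Unweighted mean of member-voxel world centers, in mm."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise InvalidArgumentError("cannot take the COM of an empty mask")
    com_idx = ndimage.center_of_mass(mask)
    return grid.index_to_world(com_idx)


def _pick_lesion_component(candidate: np.ndarray, rho: np.ndarray,
                           lesion_radius_mm: float) -> np.ndarray:
    """Connected component at the ball center, clipped to the lesion radius.

    Hepatic vessel tracks are also hypointense and can exceed the half-depth
    threshold; a contourer delineates the lesion at its known position, so
    the component containing (or nearest to) the center is chosen and bounded
    by the nominal lesion extent.
    """
    lbl, n = ndimage.label(candidate)
    center_rho = np.broadcast_to(rho, candidate.shape)
    in_core = candidate & (center_rho <= max(lesion_radius_mm / 3.0, 3.0))
    if in_core.any():
        ids, counts = np.unique(lbl[in_core], return_counts=True)
        keep = int(ids[np.argmax(counts)])
    else:  # fall back to the component closest to the center
        dmin = ndimage.minimum(center_rho, lbl, index=np.arange(1, n + 1))
        keep = int(np.argmin(dmin)) + 1
    return (lbl == keep) & (center_rho <= lesion_radius_mm)


def segment_tumor(volume: ImageVolume, center_mm, ball_radius_mm: float = 30.0,
                  depth_threshold: float = 50.0, shell_width_mm: float = 5.0,
                  smooth_mm: float = 0.0,
                  lesion_radius_mm: float = 15.0) -> np.ndarray:
    """Threshold-based tumor segmentation around a nominal center.

    The liver background level is the median over the search ball's outer
    shell, and voxels depressed below it by more than ``depth_threshold``
    form the candidate set; the connected component at the ball center,
    clipped to ``lesion_radius_mm``, is returned as a full-grid boolean mask
    (hypointense vessels elsewhere in the ball also pass the threshold).
    Optional Gaussian pre-smoothing (``smooth_mm``) is off by default: the
    rendered phases are already filtered, and extra smoothing flattens the
    depression contour faster than it suppresses the (4 mm-correlated)
    texture noise.
    """
    grid = volume.grid
    center = np.asarray(center_mm, float)
    lo = np.floor(grid.world_to_index(center - ball_radius_mm)).astype(int) - 2
    hi = np.ceil(grid.world_to_index(center + ball_radius_mm)).astype(int) + 3
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, grid.shape)
    if np.any(hi - lo < 1):
        raise SegmentationError("search ball lies outside the grid")
    box = tuple(slice(a, b) for a, b in zip(lo, hi))

    vals = volume.values[box].astype(np.float32)
    if smooth_mm > 0:
        vals = ndimage.gaussian_filter(vals, smooth_mm / grid.spacing_mm)
    ax = [grid.origin_mm[c] + (np.arange(lo[c], hi[c])) * grid.spacing_mm
          for c in range(3)]
    x, y, z = np.meshgrid(*ax, indexing="ij", sparse=True)
    rho = np.sqrt((x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2)
    ball = rho <= ball_radius_mm
    shell = ball & (rho >= ball_radius_mm - shell_width_mm)
    if not shell.any() or not ball.any():
        raise SegmentationError("degenerate search ball")
    background = float(np.median(vals[shell]))
    candidate = ball & ((background - vals) > depth_threshold)
    if not candidate.any():
        raise SegmentationError("no tumor found in the search ball")
    picked = _pick_lesion_component(candidate, rho, lesion_radius_mm)
    mask = np.zeros(grid.shape, bool)
    mask[box] = picked
    return mask


def segment_tumor_fine(volume: ImageVolume, center_mm, factor: int = 2,
                       ball_radius_mm: float = 30.0,
                       depth_threshold: float = 50.0,
                       shell_width_mm: float = 5.0,
                       lesion_radius_mm: float = 15.0):
    """Half-depth segmentation on a ``factor``-times supersampled lattice.

    Same rule as :func:`segment_tumor`, evaluated on a trilinearly
    interpolated fine lattice — the sub-voxel analogue of contouring on
    interpolated display slices.  Quantization noise of the plain voxel count
    (one cell = 0.037 cm^3 on the half-resolution grid) drops by factor^3.
    Returns ``(volume_cm3, com_mm)``.
    """
    grid = volume.grid
    center = np.asarray(center_mm, float)
    lo = np.floor(grid.world_to_index(center - ball_radius_mm)).astype(int) - 2
    hi = np.ceil(grid.world_to_index(center + ball_radius_mm)).astype(int) + 3
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, grid.shape)
    if np.any(hi - lo < 2):
        raise SegmentationError("search ball lies outside the grid")
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    vals = volume.values[box].astype(np.float32)

    f = int(factor)
    fine = ndimage.zoom(vals, f, order=1, grid_mode=True, mode="nearest")
    sp_f = grid.spacing_mm / f
    ax = [grid.origin_mm[c] + (lo[c] - 0.5) * grid.spacing_mm
          + (np.arange(fine.shape[c]) + 0.5) * sp_f for c in range(3)]
    x, y, z = np.meshgrid(*ax, indexing="ij", sparse=True)
    rho = np.sqrt((x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2)
    ball = rho <= ball_radius_mm
    shell = ball & (rho >= ball_radius_mm - shell_width_mm)
    if not shell.any():
        raise SegmentationError("degenerate search ball")
    background = float(np.median(fine[shell]))
    candidate = ball & ((background - fine) > depth_threshold)
    if not candidate.any():
        raise SegmentationError("no tumor found in the search ball")
    mask = _pick_lesion_component(candidate, rho, lesion_radius_mm)
    vol_cm3 = float(mask.sum()) * sp_f ** 3 / 1000.0
    idx = np.argwhere(mask)
    com = np.array([ax[c][idx[:, c]].mean() for c in range(3)])
    return vol_cm3, com


@dataclass
class TumorMeasurement:
    """Per-phase tumor metrics of one 4-D series."""

    preset: str
    phase_times_s: list
    volumes_cm3: list
    com_mm: list
    si_excursion_cm: float = 0.0
    ap_excursion_cm: float = 0.0
    max_volume_dev_cm3: float = 0.0
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "preset": self.preset,
            "phase_times_s": list(map(float, self.phase_times_s)),
            "volumes_cm3": list(map(float, self.volumes_cm3)),
            "com_mm": [list(map(float, c)) for c in self.com_mm],
            "si_excursion_cm": float(self.si_excursion_cm),
            "ap_excursion_cm": float(self.ap_excursion_cm),
            "max_volume_dev_cm3": float(self.max_volume_dev_cm3),
            "metadata": self.metadata,
        }


def measure_series(series: PhaseSeries, tumor: TumorSpec,
                   nominal_shift_mm=None) -> TumorMeasurement:
    """Segment and measure the tumor across all phases.

    ``nominal_shift_mm(t)`` provides the expected tumor displacement at time
    ``t`` (used only to center the search ball); defaults to the reference
    position for every phase.
    """
    volumes, coms = [], []
    for t, vol in zip(series.phase_times_s, series.phases):
        shift = np.zeros(3) if nominal_shift_mm is None else np.asarray(
            nominal_shift_mm(t), float)
        v, com = segment_tumor_fine(vol, np.asarray(tumor.center_mm) + shift)
        volumes.append(v)
        coms.append(com)
    coms = np.asarray(coms)
    i_eoi = int(np.argmin(np.abs(np.asarray(series.phase_times_s) - 2.0)))
    si = abs(coms[i_eoi, 2] - coms[0, 2]) / 10.0
    ap = abs(coms[i_eoi, 1] - coms[0, 1]) / 10.0
    max_dev = float(np.max(np.abs(np.asarray(volumes) - volumes[0])))
    return TumorMeasurement(
        preset=series.metadata.get("preset", "?"),
        phase_times_s=list(series.phase_times_s),
        volumes_cm3=volumes,
        com_mm=coms.tolist(),
        si_excursion_cm=float(si),
        ap_excursion_cm=float(ap),
        max_volume_dev_cm3=max_dev,
        metadata={k: v for k, v in series.metadata.items() if k != "phase_info"},
    )
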