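"""Raster containers shared by every stage of the phantom pipeline.

All volumes live on a :class:`VoxelGrid`: an isotropic, axis-aligned raster
with 0-based indices and the anatomical convention +x left, +y anterior,
+z superior.  Superior–inferior (SI) motion is therefore along z and
anterior–posterior (AP) motion along y.  The world coordinate of voxel
``(i, j, k)`` is ``origin + (i, j, k) * spacing`` (voxel centers).

Arrays are indexed ``values[i, j, k]`` in (x, y, z) order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

#: Default raster: 256 x 256 x 150 voxels at isotropic 1.6719 mm.
DEFAULT_DIMS = (256, 256, 150)
DEFAULT_SPACING_MM = 1.6719


@dataclass(frozen=True)
class VoxelGrid:
    """Isotropic 3-D raster with world-coordinate semantics."""

    dims: tuple[int, int, int] = DEFAULT_DIMS
    spacing_mm: float = DEFAULT_SPACING_MM
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.dims) != 3 or any(int(d) < 8 for d in self.dims):
            raise InvalidArgumentError(f"grid dims must be a triple >= 8, got {self.dims}")
        if not (self.spacing_mm > 0):
            raise InvalidArgumentError("spacing must be positive")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing_mm ** 3

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical FOV edge lengths (n * spacing)."""
        return tuple(d * self.spacing_mm for d in self.dims)

    def world_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centers."""
        return tuple(
            self.origin_mm[a] + np.arange(self.dims[a]) * self.spacing_mm for a in range(3)
        )

    def world_grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (open) meshgrid of world voxel-center coordinates."""
        ax = self.world_axes()
        return np.meshgrid(ax[0], ax[1], ax[2], indexing="ij", sparse=True)

    def world_to_index(self, xyz_mm) -> np.ndarray:
        """Continuous index coordinates of world positions (no rounding)."""
        xyz = np.asarray(xyz_mm, dtype=float)
        return (xyz - np.asarray(self.origin_mm)) / self.spacing_mm

    def index_to_world(self, ijk) -> np.ndarray:
        return np.asarray(self.origin_mm) + np.asarray(ijk, dtype=float) * self.spacing_mm

    def compatible(self, other: "VoxelGrid", atol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and abs(self.spacing_mm - other.spacing_mm) <= atol
            and all(abs(a - b) <= atol for a, b in zip(self.origin_mm, other.origin_mm))
        )


def default_grid(scale: float = 1.0) -> VoxelGrid:
    """Grid family sharing the default physical FOV.

    ``scale=1`` is the native 256x256x150 raster at 1.6719 mm; larger scales
    coarsen the spacing while keeping the ~428x428x251 mm FOV, so anatomy,
    tumor radius and motion amplitudes keep their physical size.  ``scale=2``
    gives the half-resolution 128x128x75 grid.
    """
    if scale <= 0:
        raise InvalidArgumentError("scale must be positive")
    dims = tuple(max(8, int(round(d / scale))) for d in DEFAULT_DIMS)
    return VoxelGrid(dims=dims, spacing_mm=DEFAULT_SPACING_MM * scale)


def _check_same_grid(a: VoxelGrid, b: VoxelGrid) -> None:
    if not a.compatible(b):
        raise InvalidArgumentError("operands must share one grid")


@dataclass
class ImageVolume:
    """Scalar intensity volume (arbitrary MR units) on a grid."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise InvalidArgumentError(
                f"values shape {self.values.shape} != grid dims {self.grid.shape}"
            )

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.grid, self.values.copy())


@dataclass
class LabelVolume:
    """Integer structure-ID volume; 0 means outside the body (ambient air)."""

    grid: VoxelGrid
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise InvalidArgumentError(
                f"labels shape {self.labels.shape} != grid dims {self.grid.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise InvalidArgumentError("labels must be integer-typed")

    def mask(self, label_id: int) -> np.ndarray:
        return self.labels == label_id

    def present_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids != 0]

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.grid, self.labels.copy())


@dataclass
class DisplacementField:
    """Per-voxel 3-vector displacement in millimeters, world axes.

    ``direction`` is "forward" (reference -> phase: x maps to x + u(x)) or
    "backward" (phase -> reference: intensities are pulled from x + u(x)).
    ``vectors`` has shape ``dims + (3,)`` ordered (ux, uy, uz).
    """

    grid: VoxelGrid
    vectors: np.ndarray
    direction: str = "forward"

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors)
        if self.vectors.shape != self.grid.shape + (3,):
            raise InvalidArgumentError(
                f"vectors shape {self.vectors.shape} != dims + (3,)"
            )
        if self.direction not in ("forward", "backward"):
            raise InvalidArgumentError("direction must be 'forward' or 'backward'")

    @property
    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.vectors.astype(np.float64) ** 2, axis=-1))

    def copy(self) -> "DisplacementField":
        return DisplacementField(self.grid, self.vectors.copy(), self.direction)

    @classmethod
    def zero(cls, grid: VoxelGrid, direction: str = "forward") -> "DisplacementField":
        return cls(grid, np.zeros(grid.shape + (3,), dtype=np.float32), direction)


@dataclass
class PhaseSeries:
    """Ordered respiratory-phase series; phase 1 (index 0) is the EOE reference."""

    phases: list  # list[ImageVolume]
    phase_times_s: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.phases) != len(self.phase_times_s):
            raise InvalidArgumentError("one phase time per phase volume required")

    def __len__(self) -> int:
        return len(self.phases)

    @property
    def grid(self) -> VoxelGrid:
        return self.phases[0].grid
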