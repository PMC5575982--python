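"""Volume / label / vector-field I/O (NIfTI-1 and MetaImage via SimpleITK).

Arrays are stored internally in (x, y, z) index order; SimpleITK uses
(z, y, x), so every read/write transposes.  Grid spacing and origin round-trip
losslessly; displacement fields are written as 3-component vector images in
millimeters with their direction ("forward"/"backward") tagged in the image
metadata (MetaImage) and mirrored in a JSON sidecar for formats that do not
preserve free-form keys.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import IOFormatError
from .grid import DisplacementField, ImageVolume, LabelVolume, PhaseSeries, VoxelGrid
from .structures import phase_times

_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_ext(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(e) for e in _EXTENSIONS):
        raise IOFormatError(
            f"{path}: unsupported extension (expected one of {_EXTENSIONS})"
        )


def _grid_of(img: sitk.Image) -> VoxelGrid:
    spacing = img.GetSpacing()
    if max(spacing) - min(spacing) > 1e-5:
        raise IOFormatError("anisotropic volumes are not supported")
    return VoxelGrid(dims=tuple(img.GetSize()[:3]), spacing_mm=float(spacing[0]),
                     origin_mm=tuple(img.GetOrigin()[:3]))


def _to_sitk(values: np.ndarray, grid: VoxelGrid, vector: bool = False) -> sitk.Image:
    if vector:
        arr = np.transpose(values, (2, 1, 0, 3))
    else:
        arr = np.transpose(values, (2, 1, 0))
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr), isVector=vector)
    img.SetSpacing((grid.spacing_mm,) * 3)
    img.SetOrigin(grid.origin_mm)
    return img


def write_volume(path, volume) -> None:
    """Write an ImageVolume (float32) or LabelVolume (int16)."""
    path = Path(path)
    _check_ext(path)
    if isinstance(volume, LabelVolume):
        img = _to_sitk(volume.labels.astype(np.int16), volume.grid)
    elif isinstance(volume, ImageVolume):
        img = _to_sitk(volume.values.astype(np.float32), volume.grid)
    else:
        raise IOFormatError(f"cannot write object of type {type(volume).__name__}")
    sitk.WriteImage(img, str(path))


def _read_image(path) -> sitk.Image:
    path = Path(path)
    _check_ext(path)
    if not path.exists():
        raise IOFormatError(f"{path}: no such file")
    try:
        return sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise IOFormatError(f"{path}: unreadable image ({exc})") from exc


def read_volume(path) -> ImageVolume:
    img = _read_image(path)
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 3:
        raise IOFormatError(f"{path}: expected a 3-D scalar volume")
    return ImageVolume(_grid_of(img), np.transpose(arr, (2, 1, 0)).astype(np.float32))


def read_labels(path) -> LabelVolume:
    img = _read_image(path)
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 3:
        raise IOFormatError(f"{path}: expected a 3-D label volume")
    return LabelVolume(_grid_of(img), np.transpose(arr, (2, 1, 0)).astype(np.int16))


def write_field(path, field: DisplacementField) -> None:
    path = Path(path)
    _check_ext(path)
    img = _to_sitk(field.vectors.astype(np.float32), field.grid, vector=True)
    img.SetMetaData("displacement_direction", field.direction)
    img.SetMetaData("displacement_units", "mm")
    sitk.WriteImage(img, str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .mha
    sidecar = sidecar.parent / (sidecar.name + ".field.json")
    sidecar.write_text(json.dumps({"direction": field.direction, "units": "mm"}))


def read_field(path, direction: str | None = None) -> DisplacementField:
    path = Path(path)
    img = _read_image(path)
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise IOFormatError(f"{path}: expected a 3-component vector field")
    if direction is None:
        if img.HasMetaDataKey("displacement_direction"):
            direction = img.GetMetaData("displacement_direction")
        else:
            sidecar = path.with_suffix("").with_suffix("")
            sidecar = sidecar.parent / (sidecar.name + ".field.json")
            if sidecar.exists():
                direction = json.loads(sidecar.read_text()).get("direction")
        direction = direction or "forward"
    vec = np.transpose(arr, (2, 1, 0, 3)).astype(np.float32)
    return DisplacementField(_grid_of(img), vec, direction=direction)


def write_series(directory, series: PhaseSeries, fmt: str = ".nii.gz") -> None:
    """Write a phase series as numbered 3-D volumes plus metadata.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for p, vol in enumerate(series.phases, start=1):
        write_volume(directory / f"phase{p:02d}{fmt}", vol)
    meta = dict(series.metadata)
    meta["phase_times_s"] = list(map(float, series.phase_times_s))
    meta.pop("phase_info", None)
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))


def read_series(source) -> PhaseSeries:
    """Read a series from a directory of phaseNN volumes or one 4-D file."""
    source = Path(source)
    if source.is_dir():
        files = sorted(source.glob("phase*.*"))
        files = [f for f in files if any(f.name.lower().endswith(e)
                                         for e in _EXTENSIONS)]
        if not files:
            raise IOFormatError(f"{source}: no phase volumes found")
        phases = [read_volume(f) for f in files]
        meta_path = source / "metadata.json"
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        times = meta.get("phase_times_s") or phase_times(len(phases),
                                                         meta.get("cycle_s", 5.0))
        return PhaseSeries(phases, times, meta)
    img = _read_image(source)
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 4:
        raise IOFormatError(f"{source}: expected a 4-D series")
    spacing = img.GetSpacing()
    grid = VoxelGrid(dims=tuple(img.GetSize()[:3]), spacing_mm=float(spacing[0]),
                     origin_mm=tuple(img.GetOrigin()[:3]))
    phases = [ImageVolume(grid, np.transpose(arr[t], (2, 1, 0)).astype(np.float32))
              for t in range(arr.shape[0])]
    return PhaseSeries(phases, phase_times(len(phases), 5.0), {})
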