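"""Voxel-grid data model and volume/mask I/O.

All imaging stages of the pipeline operate on :class:`VoxelGrid`
(16-bit gray values) and :class:`Mask`/:class:`LabelMap` lattices that
share its shape and spacing.  Spacing is carried *per axis in
micrometres* everywhere inside the package; metric outputs switch to
mm³/mm² only in :mod:`lungmorph.metrics3d`.

Supported on-disk formats:

* multi-page TIFF and TIFF slice-stack directories (8/16-bit) — these
  carry no trustworthy spacing metadata, so a spacing must be given
  explicitly when reading;
* NRRD and MetaImage (``.mhd``/``.mha``) via SimpleITK — spacings in
  these files follow the ITK convention (millimetres) and are converted
  to μm on read (×1000) and back on write.

Axis order is ``(slice z, row y, col x)``, matching slice-stack
acquisition; the "total length of the lung" used by the stereology
module is measured along axis 0.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import SimpleITK as sitk
import tifffile

__all__ = [
    "VoxelGrid",
    "Mask",
    "LabelMap",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]

GRAY_MAX = 65535

_TIFF_SUFFIXES = {".tif", ".tiff"}
_ITK_SUFFIXES = {".nrrd", ".nhdr", ".mhd", ".mha"}


def _check_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    sp = tuple(float(s) for s in spacing)
    if len(sp) != 3 or any(s <= 0 for s in sp):
        raise ValueError(f"spacing must be 3 positive values in um, got {spacing!r}")
    return sp  # type: ignore[return-value]


@dataclass
class VoxelGrid:
    """A 3D scalar gray-value image with voxel spacing in μm."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError(f"expected a 3D volume, got shape {self.values.shape}")
        self.spacing = _check_spacing(self.spacing)
        lo, hi = float(self.values.min()), float(self.values.max())
        if lo < 0 or hi > GRAY_MAX:
            raise ValueError(f"gray values outside [0, {GRAY_MAX}]: [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class Mask:
    """Boolean lattice aligned to a :class:`VoxelGrid`."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.dtype != bool:
            raise ValueError("mask values must be boolean")
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {self.values.shape}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.values.sum())


@dataclass
class LabelMap:
    """Non-negative integer lattice; label 0 is background."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    label_names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("label values must be integers")
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D label map, got shape {self.values.shape}")
        if self.values.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def labels(self) -> np.ndarray:
        lab = np.unique(self.values)
        return lab[lab > 0]


def _read_itk(path: Path) -> VoxelGrid:
    img = sitk.ReadImage(os.fspath(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {arr.ndim}D")
    sx, sy, sz = img.GetSpacing()  # ITK order (x, y, z), mm
    spacing = (sz * 1000.0, sy * 1000.0, sx * 1000.0)
    return VoxelGrid(np.ascontiguousarray(arr), spacing, name=path.stem)


def _read_tiff_stack_dir(path: Path) -> np.ndarray:
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _TIFF_SUFFIXES
    )
    if not files:
        raise FileNotFoundError(f"no TIFF slices in {path}")
    slices = [tifffile.imread(os.fspath(p)) for p in files]
    shapes = {s.shape for s in slices}
    if len(shapes) != 1 or slices[0].ndim != 2:
        raise ValueError(f"{path}: inconsistent slice shapes {sorted(shapes)}")
    return np.stack(slices, axis=0)


def read_volume(
    path: str | os.PathLike,
    spacing: Sequence[float] | None = None,
    format_hint: str | None = None,
) -> VoxelGrid:
    """Read a volume; ``spacing`` (μm, z/y/x) is mandatory for TIFF.

    TIFF files store no reliable voxel size, and every downstream
    quantity is spacing-dependent, so reading TIFF without an explicit
    spacing is refused rather than silently defaulted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = (format_hint or "").lower()
    if path.is_dir() or fmt == "tiff_dir":
        arr = _read_tiff_stack_dir(path)
    elif path.suffix.lower() in _ITK_SUFFIXES or fmt in {"nrrd", "metaimage"}:
        grid = _read_itk(path)
        if spacing is not None:
            grid.spacing = _check_spacing(spacing)
        return grid
    elif path.suffix.lower() in _TIFF_SUFFIXES or fmt == "tiff":
        arr = tifffile.imread(os.fspath(path))
        if arr.ndim == 2:
            arr = arr[None]
    else:
        raise ValueError(f"unrecognised volume format: {path}")
    if spacing is None:
        raise ValueError(
            f"{path}: TIFF carries no voxel spacing; pass spacing=(z, y, x) in um"
        )
    return VoxelGrid(arr, _check_spacing(spacing), name=path.stem)


def write_volume(grid: VoxelGrid, path: str | os.PathLike) -> None:
    """Write a volume; format is chosen from the file suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    values = np.asarray(grid.values, dtype=np.uint16)
    if suffix in _TIFF_SUFFIXES:
        tifffile.imwrite(os.fspath(path), values)
    elif suffix in _ITK_SUFFIXES:
        img = sitk.GetImageFromArray(values)
        sz, sy, sx = grid.spacing
        img.SetSpacing((sx / 1000.0, sy / 1000.0, sz / 1000.0))
        sitk.WriteImage(img, os.fspath(path))
    else:
        raise ValueError(f"unrecognised volume format: {path}")


def write_mask(mask: Mask, path: str | os.PathLike) -> None:
    """Write a mask (foreground 255, background 0 as 8-bit)."""
    path = Path(path)
    suffix = path.suffix.lower()
    values = np.where(mask.values, 255, 0).astype(np.uint8)
    if suffix in _TIFF_SUFFIXES:
        tifffile.imwrite(os.fspath(path), values)
    elif suffix in _ITK_SUFFIXES:
        img = sitk.GetImageFromArray(values)
        sz, sy, sx = mask.spacing
        img.SetSpacing((sx / 1000.0, sy / 1000.0, sz / 1000.0))
        sitk.WriteImage(img, os.fspath(path))
    else:
        raise ValueError(f"unrecognised mask format: {path}")


def read_mask(
    path: str | os.PathLike,
    spacing: Sequence[float] | None = None,
    format_hint: str | None = None,
) -> Mask:
    grid = read_volume(path, spacing=spacing, format_hint=format_hint)
    return Mask(grid.values > 0, grid.spacing)
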