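"""ROI volume and surface-area estimators and the subtraction rule.

Volumes are voxel counts times the voxel volume.  Surface areas come
from a triangulated isosurface of the (lightly smoothed) binary mask
by default; a raw exposed-voxel-face estimator is kept as a
diagnostic, because face counting overestimates curved surfaces by a
staircase factor of about 1.5.

Terminal air-space metrics follow the subtraction rule: the volume and
surface area of the "bronchial tree" ROI are subtracted from those of
the "entire air spaces" ROI to give V_A and S_A.  The surface
subtraction is reproduced literally even though the result is not the
geometric surface of the terminal region (shared interfaces do not
cancel exactly); it reproduces the convention by which the reported
values are defined and is documented as such in docs/methods.md.

Units: spacings are μm; volumes are reported in mm³ (÷1e9) and
surfaces in mm² (÷1e6), matching the data-table columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .airseg import AirspaceSegmentation
from .gridio import Mask

__all__ = [
    "RoiMetrics",
    "mask_volume",
    "mask_surface_area",
    "roi_metrics",
    "terminal_airspace_metrics",
    "specimen_metrics",
]

ISOSURFACE = "isosurface"
VOXEL_FACE = "voxel_face"


@dataclass
class RoiMetrics:
    """Volume (mm³) and surface area (mm²) of one ROI."""

    volume: float
    surface_area: float
    method: str
    voxel_count: int

    def __post_init__(self) -> None:
        if self.volume < 0 or self.surface_area < 0:
            raise ValueError("volume and surface area must be non-negative")


def mask_volume(mask: Mask) -> float:
    """Foreground voxel count × voxel volume, in mm³."""
    return mask.count() * float(np.prod(mask.spacing)) / 1e9


def mask_surface_area(
    mask: Mask, method: str = ISOSURFACE, smooth_sigma_vox: float = 2.0
) -> float:
    """Surface area of a binary mask in mm².

    ``isosurface`` (default): marching cubes at level 0.5 on the
    indicator smoothed with a two-voxel-σ Gaussian; the smoothing
    suppresses the artificial voxel roughness that otherwise
    overestimates the area (by ~9% for a raw binary sphere), at the
    price of fusing air gaps thinner than ~3 voxels.  ``voxel_face``: exposed voxel faces ×
    face area (diagnostic, staircase-biased high).
    """
    if mask.count() == 0:
        raise ValueError("surface area of an empty mask is undefined")
    sz, sy, sx = mask.spacing
    if method == VOXEL_FACE:
        padded = np.pad(mask.values, 1)
        total = 0.0
        face_areas = (sy * sx, sz * sx, sz * sy)
        for axis, area in enumerate(face_areas):
            total += np.count_nonzero(np.diff(padded, axis=axis)) * area
        return total / 1e6
    if method != ISOSURFACE:
        raise ValueError(f"unknown surface method: {method}")
    padded = np.pad(mask.values, 1).astype(np.float32)
    if smooth_sigma_vox > 0:
        smoothed = ndimage.gaussian_filter(padded, smooth_sigma_vox)
        if smoothed.max() <= 0.5:  # feature too small to survive smoothing
            smoothed = padded
    else:
        smoothed = padded
    verts, faces, _, _ = measure.marching_cubes(
        smoothed, level=0.5, spacing=(sz, sy, sx)
    )
    return float(measure.mesh_surface_area(verts, faces)) / 1e6


def roi_metrics(mask: Mask, method: str = ISOSURFACE) -> RoiMetrics:
    count = mask.count()
    surface = mask_surface_area(mask, method) if count else 0.0
    return RoiMetrics(mask_volume(mask), surface, method, count)


def terminal_airspace_metrics(entire: RoiMetrics, tree: RoiMetrics) -> RoiMetrics:
    """V_A = V(entire) − V(tree); S_A = S(entire) − S(tree)."""
    if tree.volume > entire.volume or tree.surface_area > entire.surface_area:
        raise ValueError(
            "inconsistent ROIs: bronchial tree exceeds entire air spaces "
            f"(V {tree.volume} vs {entire.volume}, "
            f"S {tree.surface_area} vs {entire.surface_area})"
        )
    return RoiMetrics(
        entire.volume - tree.volume,
        entire.surface_area - tree.surface_area,
        entire.method,
        entire.voxel_count - tree.voxel_count,
    )


def specimen_metrics(
    seg: AirspaceSegmentation, surface_method: str = ISOSURFACE
) -> dict:
    """One specimen record: V_L from the lung outline, V_A/S_A by subtraction."""
    for name in ("entire_mask", "tree_mask", "lung_mask"):
        if getattr(seg, name) is None:
            raise ValueError(f"missing mask: {name}")
    entire = roi_metrics(seg.entire_mask, surface_method)
    tree = roi_metrics(seg.tree_mask, surface_method)
    terminal = terminal_airspace_metrics(entire, tree)
    vl = mask_volume(seg.lung_mask)
    return {
        "VL_mm3": vl,
        "VA_mm3": terminal.volume,
        "SA_mm2": terminal.surface_area,
        "entire": entire,
        "tree": tree,
        "terminal": terminal,
        "surface_method": surface_method,
    }
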