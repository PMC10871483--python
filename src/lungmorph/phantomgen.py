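"""Synthetic μCT phantoms of the developing lung, with ground truth.

No image data of the original specimens is available, so the 3D
pipeline is validated on phantoms.  The lung is one ellipsoid
partitioned into six lobar air sacs (cranial, middle, ventral and
caudal on the right; middle and caudal on the left) by vertical
fissure walls of one septum thickness that meet in a tissue hilum;
the trachea descends the hilar axis and per-lobe bronchial tubes run
radially into each sac, so each large terminal air space opens
directly from its lobar tube — the newborn topology.  Later stages
are produced by repeated *septation*: planar septa of finite
thickness are inserted through sac centroids with random orientation,
subdividing the air spaces just as sacculation/alveolarization
subdivides them in the real lung (a pore is left in every septum so
the lumen stays a single connected air space).

Stage parameterization follows the per-stage means of the packaged
specimen table: air-space chord diameter from 349 μm (neonate) down
to 51 μm (57 dpn), septum thickness 41 → 10 μm.  Chords of a convex
air space are shorter than its width, so the lung is sized by two
frozen calibration constants of the chord estimator
(``CELL_CHORD_FACTOR``, ``SEPTATION_CHORD_SHRINK``; see
docs/methods.md) such that the *measured* chord mean lands on the
stage target.  The same estimator produces the ground-truth values,
so recovery comparisons are estimator-consistent.

Contrast emulates PTA staining: tissue bright (default 30000), air
lumina dark (5000), plus partial-volume Gaussian blur and additive
noise.  All geometry, septum orientations and noise derive from one
seeded RNG, so equal seeds give bitwise-identical phantoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .gridio import GRAY_MAX, LabelMap, Mask, VoxelGrid
from . import stereology
from .metrics3d import ISOSURFACE, mask_surface_area, mask_volume

__all__ = [
    "STAGE_TABLE",
    "CHORD_DIAMETER_FACTOR",
    "PhantomSpec",
    "PhantomTruth",
    "generate_calibration",
    "generate_stage_phantom",
    "subdivide_sacs",
    "render_gray",
]

# stage -> (air-space diameter um, septum thickness um, default septation rounds)
# Diameters/septa are the per-stage group means of the packaged table.
# 13 dpc has no printed values (deflated fetal lung); it reuses the neonate
# structural parameters.
STAGE_TABLE: Mapping[str, tuple[float, float, int]] = {
    "13dpc": (349.0, 41.0, 0),
    "neonate": (349.0, 41.0, 0),
    "4dpn": (258.0, 34.0, 1),
    "7dpn": (192.0, 24.0, 1),
    "11dpn": (141.0, 25.0, 2),
    "14dpn": (126.0, 26.0, 2),
    "21dpn": (108.0, 18.0, 3),
    "28dpn": (89.0, 20.0, 3),
    "35dpn": (70.0, 16.0, 3),
    "49dpn": (52.0, 12.0, 3),
    "57dpn": (51.0, 10.0, 3),
    "adult": (79.0, 10.0, 3),
}

# measured chord / geometric diameter of an isolated sphere under the
# package's line-intercept estimator (2/3 from theory; 0.678 measured
# on voxelized calibration spheres) — a reference property of the
# estimator, not used for sizing
CHORD_DIAMETER_FACTOR = 0.678

LOBE_NAMES = (
    "right cranial",
    "right middle",
    "right ventral",
    "right caudal",
    "left middle",
    "left caudal",
)


def default_spacing(septum_um: float) -> float:
    """Per-stage voxel size: fine enough to resolve the septa (μm)."""
    return float(min(8.0, max(2.0, septum_um / 3.0)))


@dataclass
class PhantomSpec:
    stage_label: str
    sac_diameter_target: float
    septum_thickness_target: float
    subdivision_rounds: int
    spacing: float
    n_lobes: int = 6
    airway_generations: int = 3
    gray_air: int = 5000
    gray_tissue: int = 30000
    gray_background: int = 1000
    noise_sd: float = 800.0
    blur_sigma: float | None = None  # μm; default 0.3 × spacing
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.gray_tissue <= self.gray_air:
            raise ValueError("PTA-stained tissue must be brighter than air")
        if not (self.sac_diameter_target > self.septum_thickness_target > 0):
            raise ValueError("need sac diameter > septum thickness > 0")
        if self.subdivision_rounds < 0:
            raise ValueError("subdivision_rounds must be >= 0")
        if self.airway_generations < 1:
            raise ValueError("airway_generations must be >= 1")
        if not 1 <= self.n_lobes <= 6:
            raise ValueError("n_lobes must be between 1 and 6")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        # minimum resolvable feature: 2 voxels — refuse, don't blur silently
        if self.septum_thickness_target < 2 * self.spacing:
            raise ValueError(
                f"septa of {self.septum_thickness_target} um are unresolvable "
                f"at {self.spacing} um spacing (minimum 2 voxels)"
            )
        if self.blur_sigma is None:
            self.blur_sigma = 0.3 * self.spacing

    @classmethod
    def for_stage(
        cls,
        stage_label: str,
        spacing: float | None = None,
        subdivision_rounds: int | None = None,
        rng_seed: int = 0,
        **overrides,
    ) -> "PhantomSpec":
        if stage_label not in STAGE_TABLE:
            raise KeyError(f"unknown stage {stage_label!r}")
        diam, sept, rounds = STAGE_TABLE[stage_label]
        kwargs = dict(
            stage_label=stage_label,
            sac_diameter_target=diam,
            septum_thickness_target=sept,
            subdivision_rounds=rounds if subdivision_rounds is None else subdivision_rounds,
            spacing=spacing if spacing is not None else default_spacing(sept),
            rng_seed=rng_seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class PhantomTruth:
    gray: VoxelGrid
    lung_mask: Mask
    tree_mask: Mask
    terminal_mask: Mask
    sac_labels: LabelMap
    lobe_labels: LabelMap
    true_VL: float  # mm³
    true_VA: float  # mm³
    true_SA: float  # mm²
    true_mean_diameter: float  # μm (chord estimator)
    true_mean_septum: float  # μm (chord estimator)
    trachea_seed: tuple[int, int, int]
    spec: PhantomSpec = field(repr=False, default=None)


# ---------------------------------------------------------------- geometry

def _paint_ball(arr: np.ndarray, value, center, radius, spacing, origin) -> None:
    """Set voxels whose centers lie inside the sphere; bbox-limited."""
    lo, hi, coords = _bbox_coords(arr.shape, center, radius, spacing, origin)
    if coords is None:
        return
    dz, dy, dx = coords
    inside = dz * dz + dy * dy + dx * dx <= radius * radius
    region = arr[lo[0]: hi[0], lo[1]: hi[1], lo[2]: hi[2]]
    region[inside] = value


def _bbox_coords(shape, center, radius, spacing, origin):
    lo, hi, axes = [], [], []
    for ax in range(3):
        a = int(math.floor((center[ax] - radius - origin[ax]) / spacing))
        b = int(math.ceil((center[ax] + radius - origin[ax]) / spacing)) + 1
        a, b = max(a, 0), min(b, shape[ax])
        if a >= b:
            return None, None, None
        lo.append(a)
        hi.append(b)
        centers = origin[ax] + (np.arange(a, b) + 0.5) * spacing - center[ax]
        axes.append(centers)
    dz = axes[0][:, None, None]
    dy = axes[1][None, :, None]
    dx = axes[2][None, None, :]
    return lo, hi, (dz, dy, dx)


def _paint_capsule(arr: np.ndarray, value, p0, p1, radius, spacing, origin) -> None:
    """Set voxels within ``radius`` of the segment p0→p1 (rounded ends)."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    cmin = np.minimum(p0, p1) - radius
    cmax = np.maximum(p0, p1) + radius
    lo, hi = [], []
    axes = []
    for ax in range(3):
        a = int(math.floor((cmin[ax] - origin[ax]) / spacing))
        b = int(math.ceil((cmax[ax] - origin[ax]) / spacing)) + 1
        a, b = max(a, 0), min(b, arr.shape[ax])
        if a >= b:
            return
        lo.append(a)
        hi.append(b)
        axes.append(origin[ax] + (np.arange(a, b) + 0.5) * spacing)
    zz = axes[0][:, None, None]
    yy = axes[1][None, :, None]
    xx = axes[2][None, None, :]
    v = p1 - p0
    vv = float(v @ v)
    wz, wy, wx = zz - p0[0], yy - p0[1], xx - p0[2]
    if vv < 1e-12:
        t = 0.0
        d2 = wz * wz + wy * wy + wx * wx
    else:
        t = np.clip((wz * v[0] + wy * v[1] + wx * v[2]) / vv, 0.0, 1.0)
        dz = wz - t * v[0]
        dy = wy - t * v[1]
        dx = wx - t * v[2]
        d2 = dz * dz + dy * dy + dx * dx
    inside = d2 <= radius * radius
    region = arr[lo[0]: hi[0], lo[1]: hi[1], lo[2]: hi[2]]
    region[inside] = value


# ------------------------------------------------------------- calibration

def generate_calibration(
    shape: str,
    dims: Mapping[str, float],
    spacing: float,
    gray_air: int = 5000,
    gray_tissue: int = 30000,
) -> tuple[VoxelGrid, Mask, float, float]:
    """Analytic calibration shape: voxel mask + closed-form V (mm³), S (mm²).

    Shapes: ``sphere`` (radius), ``cylinder`` (radius, length, axis z),
    ``tube_with_sac`` (sac_radius sphere with a coaxial tube of
    tube_radius protruding tube_length beyond the sphere surface).
    The rendered grid shows the shape as dark air in bright tissue.
    """
    radii = [v for k, v in dims.items() if "radius" in k]
    if not radii:
        raise ValueError("dims must include a radius")
    if min(radii) < 2 * spacing:
        raise ValueError(
            f"radius {min(radii)} um is unresolvable at {spacing} um (min 2 voxels)"
        )
    pad = 3 * spacing
    if shape == "sphere":
        r = float(dims["radius"])
        extent = np.array([2 * r, 2 * r, 2 * r])
        origin = -extent / 2 - pad
        n = np.ceil((extent + 2 * pad) / spacing).astype(int)
        mask = np.zeros(tuple(n), dtype=bool)
        _paint_ball(mask, True, (0.0, 0.0, 0.0), r, spacing, origin)
        r_mm = r / 1000.0
        vol = 4.0 / 3.0 * math.pi * r_mm**3
        surf = 4.0 * math.pi * r_mm**2
    elif shape == "cylinder":
        r, length = float(dims["radius"]), float(dims["length"])
        origin = np.array([-pad, -r - pad, -r - pad])
        n = np.ceil(
            (np.array([length, 2 * r, 2 * r]) + 2 * pad) / spacing
        ).astype(int)
        mask = np.zeros(tuple(n), dtype=bool)
        zz = (origin[0] + (np.arange(n[0]) + 0.5) * spacing)[:, None, None]
        yy = (origin[1] + (np.arange(n[1]) + 0.5) * spacing)[None, :, None]
        xx = (origin[2] + (np.arange(n[2]) + 0.5) * spacing)[None, None, :]
        mask[:] = (yy**2 + xx**2 <= r**2) & (zz >= 0) & (zz <= length)
        r_mm, l_mm = r / 1000.0, length / 1000.0
        vol = math.pi * r_mm**2 * l_mm
        surf = 2 * math.pi * r_mm * l_mm + 2 * math.pi * r_mm**2
    elif shape == "tube_with_sac":
        rs = float(dims["sac_radius"])
        rt = float(dims["tube_radius"])
        lt = float(dims["tube_length"])
        if rt >= rs:
            raise ValueError("tube radius must be smaller than sac radius")
        top = rs + lt
        origin = np.array([-rs - pad, -rs - pad, -rs - pad])
        n = np.ceil(
            (np.array([top + rs + 2 * pad, 2 * rs + 2 * pad, 2 * rs + 2 * pad]))
            / spacing
        ).astype(int)
        mask = np.zeros(tuple(n), dtype=bool)
        _paint_ball(mask, True, (0.0, 0.0, 0.0), rs, spacing, origin)
        zz = (origin[0] + (np.arange(n[0]) + 0.5) * spacing)[:, None, None]
        yy = (origin[1] + (np.arange(n[1]) + 0.5) * spacing)[None, :, None]
        xx = (origin[2] + (np.arange(n[2]) + 0.5) * spacing)[None, None, :]
        mask |= (yy**2 + xx**2 <= rt**2) & (zz >= 0) & (zz <= top)
        # closed forms for the sphere ∪ coaxial-cylinder union
        zi = math.sqrt(rs**2 - rt**2)
        rs_mm, rt_mm = rs / 1000.0, rt / 1000.0
        zi_mm, top_mm = zi / 1000.0, top / 1000.0
        stickout = top_mm - zi_mm
        vol = 4.0 / 3.0 * math.pi * rs_mm**3 + math.pi * rt_mm**2 * stickout
        surf = (
            4.0 * math.pi * rs_mm**2
            - 2.0 * math.pi * rs_mm * (rs_mm - zi_mm)  # removed spherical cap
            + 2.0 * math.pi * rt_mm * stickout
            + math.pi * rt_mm**2  # end cap
        )
    else:
        raise ValueError(f"unknown calibration shape {shape!r}")

    gray = np.where(mask, gray_air, gray_tissue).astype(np.uint16)
    sp = (spacing, spacing, spacing)
    return (
        VoxelGrid(gray, sp, name=f"calibration_{shape}"),
        Mask(mask, sp),
        vol,
        surf,
    )


# --------------------------------------------------------------- septation

def subdivide_sacs(
    sacs: LabelMap,
    rounds: int,
    septum_thickness: float,
    rng: np.random.Generator | None = None,
    min_split_diameter: float | None = None,
    pore_radius: float = 0.0,
) -> LabelMap:
    """Septation: split sacs with random planar septa of finite thickness.

    Each round, every sac larger than the minimum is split by a planar
    septum of the given thickness (μm) through its centroid, with
    orientation drawn from ``rng``; the two sides become child labels
    and the septum voxels become tissue, so per-sac air volume drops by
    the inserted slab volume.  ``pore_radius > 0`` leaves a circular
    pore in each septum so subdivided air spaces stay connected (used
    by the phantom generator).  ``rounds = 0`` returns the input
    unchanged.
    """
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    if rounds == 0:
        return sacs
    sp = sacs.spacing
    if septum_thickness < min(sp):
        raise ValueError(
            f"septum of {septum_thickness} um is thinner than one voxel ({min(sp)} um)"
        )
    rng = np.random.default_rng(0) if rng is None else rng
    if min_split_diameter is None:
        min_split_diameter = max(4.0 * septum_thickness, 6.0 * min(sp))

    values = sacs.values.copy()
    voxvol = float(np.prod(sp))
    for _ in range(rounds):
        labels_now = np.unique(values)
        labels_now = labels_now[labels_now > 0]
        next_label = int(labels_now.max()) + 1 if labels_now.size else 1
        slices = ndimage.find_objects(values)
        for lab in labels_now:
            slc = slices[lab - 1]
            if slc is None:
                continue
            sub = values[slc]
            sel = sub == lab
            n_vox = int(sel.sum())
            equiv_d = (6.0 * n_vox * voxvol / math.pi) ** (1.0 / 3.0)
            if equiv_d < min_split_diameter:
                continue
            idx = np.nonzero(sel)
            coords = np.stack(
                [
                    (idx[ax] + slc[ax].start + 0.5) * sp[ax]
                    for ax in range(3)
                ],
                axis=1,
            )
            centroid = coords.mean(axis=0)
            normal = rng.normal(size=3)
            normal /= np.linalg.norm(normal)
            signed = (coords - centroid) @ normal
            in_slab = np.abs(signed) <= septum_thickness / 2.0
            side_b = signed < -septum_thickness / 2.0
            side_a = signed > septum_thickness / 2.0
            if side_a.sum() < 8 or side_b.sum() < 8:
                continue
            pore = np.zeros_like(in_slab)
            if pore_radius > 0:
                tangent = rng.normal(size=3)
                tangent -= (tangent @ normal) * normal
                tangent /= np.linalg.norm(tangent)
                rho = rng.uniform(0.0, 0.15 * equiv_d)
                pore_center = centroid + tangent * rho
                rel = coords - pore_center
                along = rel @ normal
                inplane2 = np.einsum("ij,ij->i", rel, rel) - along**2
                pore = in_slab & (inplane2 <= pore_radius**2)
            new_vals = np.full(n_vox, lab, dtype=values.dtype)
            new_vals[side_b] = next_label
            new_vals[in_slab & ~pore] = 0
            new_vals[pore & (signed < 0)] = next_label
            sub_idx = tuple(idx)
            sub[sub_idx] = new_vals
            next_label += 1
    return LabelMap(values, sp, dict(sacs.label_names))


# --------------------------------------------------------------- rendering

def render_gray(
    lung_mask: Mask,
    air_mask: Mask,
    gray_air: int = 5000,
    gray_tissue: int = 30000,
    gray_background: int = 1000,
    blur_sigma_um: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    name: str = "phantom",
) -> VoxelGrid:
    """Render masks to a 16-bit gray volume (PTA contrast polarity).

    Air voxels ≈ gray_air, tissue (lung minus air) ≈ gray_tissue,
    background below air; Gaussian blur (μm) emulates partial-volume
    smoothing, then zero-mean noise is added and values are clipped to
    the 16-bit range.
    """
    if lung_mask.shape != air_mask.shape or lung_mask.spacing != air_mask.spacing:
        raise ValueError("lung and air masks are not aligned")
    if not gray_background < gray_air < gray_tissue:
        raise ValueError("need gray_background < gray_air < gray_tissue")
    img = np.full(lung_mask.shape, float(gray_background), dtype=np.float32)
    img[lung_mask.values] = gray_tissue
    img[air_mask.values] = gray_air
    if blur_sigma_um > 0:
        sigma_vox = [blur_sigma_um / s for s in lung_mask.spacing]
        img = ndimage.gaussian_filter(img, sigma_vox)
    if noise_sd > 0:
        rng = np.random.default_rng(0) if rng is None else rng
        img = img + rng.normal(0.0, noise_sd, size=img.shape).astype(np.float32)
    np.clip(img, 0, GRAY_MAX, out=img)
    return VoxelGrid(np.rint(img).astype(np.uint16), lung_mask.spacing, name=name)


# ------------------------------------------------------------ stage phantom

# Ratio of the measured mean air chord to the lung size parameter for
# the six-lobe fissure partition at zero septation rounds, and the
# factor by which one septation round shrinks the mean chord; both
# measured once on reference phantoms and frozen (used to size the
# lung so measured chords land on the stage target).
CELL_CHORD_FACTOR = 0.451
SEPTATION_CHORD_SHRINK = 0.75


def _sector_walls_2d(ny, nx, sp, ay, ax, wall_azimuths_deg, t):
    """In-plane wall mask and sector labels for the lobar partition.

    All fissure walls are vertical half-planes through the hilar axis,
    so every transverse section shows the same partition scaled by the
    local ellipse cross-section.
    """
    yy = ((np.arange(ny) + 0.5) * sp - ay)[:, None]
    xx = ((np.arange(nx) + 0.5) * sp - ax)[None, :]
    walls = np.zeros((ny, nx), dtype=bool)
    for az in wall_azimuths_deg:
        phi = math.radians(az)
        u = (math.cos(phi), math.sin(phi))  # along the half-plane, (y, x)
        proj = yy * u[0] + xx * u[1]
        perp = np.abs(yy * (-u[1]) + xx * u[0])
        dist = np.where(proj >= 0, perp, np.hypot(yy, xx))
        walls |= dist <= t / 2.0
    phi_all = np.degrees(np.arctan2(xx, yy))  # (-180, 180], 0 = +y, 90 = +x
    return walls, phi_all


def _sector_index(phi_deg: np.ndarray, bounds: list[tuple[float, float]]) -> np.ndarray:
    out = np.zeros(phi_deg.shape, dtype=np.int32)
    for i, (lo, hi) in enumerate(bounds):
        if lo < hi:
            sel = (phi_deg > lo) & (phi_deg <= hi)
        else:  # wraps through 180/-180
            sel = (phi_deg > lo) | (phi_deg <= hi)
        out[sel] = i + 1
    return out


def generate_stage_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Build a stage phantom and its ground truth.

    Geometry: one ellipsoidal lung partitioned into lobar air sacs by
    vertical fissure walls of one septum thickness that meet in a
    tissue hilum; the trachea descends the hilar axis and per-lobe
    bronchial tubes run radially into each sac (each terminal sac
    opens directly from its lobar tube — the newborn topology).
    ``subdivision_rounds`` rounds of septation then subdivide the
    sacs.  Truth metrics come from the masks at generation resolution
    using the package's own estimators.
    """
    rng = np.random.default_rng(spec.rng_seed)
    sp = float(spec.spacing)
    t = spec.septum_thickness_target
    rounds = spec.subdivision_rounds

    # size the lung so the measured mean chord lands on the stage target
    scale = spec.sac_diameter_target / (
        CELL_CHORD_FACTOR * SEPTATION_CHORD_SHRINK**rounds
    )
    ay, ax_semi, az = 1.0 * scale, 1.1 * scale, 0.8 * scale

    if spec.n_lobes == 6:
        # right lung (x > 0): cranial, middle, ventral, caudal;
        # left lung (x < 0): middle, caudal
        wall_az = [-90.0, -45.0, 0.0, 45.0, 90.0, 180.0]
        sector_bounds = [(-90.0, -45.0), (-45.0, 0.0), (0.0, 45.0),
                         (45.0, 90.0), (90.0, 180.0), (180.0, -90.0)]
        names = {i + 1: LOBE_NAMES[i] for i in range(6)}
    else:
        step_az = 360.0 / spec.n_lobes
        wall_az = [-180.0 + i * step_az for i in range(spec.n_lobes)]
        sector_bounds = []
        for i in range(spec.n_lobes):
            lo = -180.0 + i * step_az
            hi = lo + step_az
            sector_bounds.append((lo, hi if hi <= 180 else hi - 360.0))
        names = {i + 1: f"lobe_{i + 1}" for i in range(spec.n_lobes)}

    r_tr = max(3.0 * sp, 0.06 * scale)
    r_lb = max(2.0 * sp, 0.6 * r_tr)
    sleeve = max(t, 2.0 * sp)
    trachea_len = 0.45 * scale

    pad = 3 * sp
    origin = np.array([-az - trachea_len - r_tr - sleeve - pad, -ay - pad, -ax_semi - pad])
    extent = np.array([az, ay, ax_semi]) + pad
    shape = tuple(np.ceil((extent - origin) / sp).astype(int))
    nz, ny, nx = shape
    spacing3 = (sp, sp, sp)

    zz = (origin[0] + (np.arange(nz) + 0.5) * sp)[:, None, None]
    walls2d, phi2d = _sector_walls_2d(ny, nx, sp, -origin[1], -origin[2], wall_az, t)
    sector2d = _sector_index(phi2d, sector_bounds)

    yy = (origin[1] + (np.arange(ny) + 0.5) * sp)[None, :, None]
    xx = (origin[2] + (np.arange(nx) + 0.5) * sp)[None, None, :]
    m_outer = (zz / az) ** 2 + (yy / ay) ** 2 + (xx / ax_semi) ** 2
    lung_ell = m_outer <= 1.0
    # visceral pleura + subpleural tissue; must stay resolvable (>= 3
    # voxels) so denoising cannot breach the lung boundary
    pleura = max(t, 3.0 * sp)
    m_inner = (
        (zz / (az - pleura)) ** 2
        + (yy / (ay - pleura)) ** 2
        + (xx / (ax_semi - pleura)) ** 2
    )
    interior = m_inner <= 1.0

    sac_lab = np.where(interior & ~walls2d[None, :, :], sector2d[None, :, :], 0).astype(
        np.int32
    )
    lobe_lab = np.where(lung_ell, sector2d[None, :, :], 0).astype(np.int32)

    # conducting tree: trachea down the hilar axis, lobar tubes radial
    trachea_top = np.array([-az - trachea_len, 0.0, 0.0])
    carina = np.array([0.0, 0.0, 0.0])
    segments = [(trachea_top, carina, r_tr)]
    for i, (lo, hi) in enumerate(sector_bounds):
        mid = math.radians(lo + (((hi - lo) % 360.0) or 360.0) / 2.0)
        target = np.array(
            [0.0, 0.55 * ay * math.cos(mid), 0.55 * ax_semi * math.sin(mid)]
        )
        segments.append((carina, target, r_lb))

    lumen = np.zeros(shape, dtype=bool)
    outer = np.zeros(shape, dtype=bool)
    for p0, p1, r in segments:
        _paint_capsule(outer, True, p0, p1, r + sleeve, sp, origin)
    for p0, p1, r in segments:
        _paint_capsule(lumen, True, p0, p1, r, sp, origin)

    lung = lung_ell | outer

    sac_labels = subdivide_sacs(
        LabelMap(sac_lab, spacing3, names),
        rounds,
        t,
        rng=rng,
        pore_radius=max(3.5 * sp, 2.0 * t),
    )
    terminal = sac_labels.values > 0
    tree = lumen & ~terminal

    lung_mask = Mask(lung, spacing3)
    tree_mask = Mask(tree, spacing3)
    terminal_mask = Mask(terminal, spacing3)
    air_mask = Mask(tree | terminal, spacing3)

    gray = render_gray(
        lung_mask,
        air_mask,
        gray_air=spec.gray_air,
        gray_tissue=spec.gray_tissue,
        gray_background=spec.gray_background,
        blur_sigma_um=spec.blur_sigma,
        noise_sd=spec.noise_sd,
        rng=rng,
        name=f"{spec.stage_label}_phantom",
    )

    seed_pt = trachea_top + np.array([3.0 * sp, 0.0, 0.0])
    seed = tuple(int((seed_pt[ax] - origin[ax]) / sp) for ax in range(3))
    if not tree[seed]:  # pragma: no cover - defensive
        inside = np.argwhere(tree[seed[0]])
        seed = (seed[0], int(inside[0][0]), int(inside[0][1]))

    true_sa = mask_surface_area(air_mask, ISOSURFACE) - mask_surface_area(
        tree_mask, ISOSURFACE
    )
    air_chords, sep_chords = stereology.collect_chords(
        terminal_mask, lung_mask, rng, n_lines=300, exclude_mask=tree_mask
    )
    return PhantomTruth(
        gray=gray,
        lung_mask=lung_mask,
        tree_mask=tree_mask,
        terminal_mask=terminal_mask,
        sac_labels=sac_labels,
        lobe_labels=LabelMap(lobe_lab, spacing3, names),
        true_VL=mask_volume(lung_mask),
        true_VA=mask_volume(terminal_mask),
        true_SA=true_sa,
        true_mean_diameter=float(air_chords.mean()),
        true_mean_septum=float(sep_chords.mean()) if sep_chords.size else float("nan"),
        trachea_seed=seed,
        spec=spec,
    )
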