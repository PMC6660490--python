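"""Digital thorax phantom and attenuation-map artifact injectors.

The phantom is a stylized thorax: an elliptic body cylinder with a
subcutaneous fat shell, two lung ellipsoids clipped to the body interior and
to the space above the diaphragm, a left-ventricular annulus of soft tissue
with elevated tracer uptake, a liver-like hot region below the diaphragm,
and optional arms for truncation experiments.  It is not anthropomorphic;
everything the downstream analysis measures (class volumes, ring uptake,
artifact adjacency) is preserved at this scale.

Artifact injectors realize the artifact taxonomy of segmented MR attenuation
maps: susceptibility voids near sternal wires (STN) and metallic implants
(SMA), lung/soft (LSTI) and fat/soft (FSTI) tissue inversions, photopenic
breathing bands above the diaphragm (PMA), lateral truncation of the arms,
and rigid misalignment of the whole map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Band, Box, HalfPlane, LVGeometry, Region
from .grid import GridSpec
from .volumes import BACKGROUND, FAT, LUNG, SOFT, ActivityMap, MuMap, TissueLabelMap

ARTIFACT_KINDS = ("STN", "SMA", "LSTI", "FSTI", "PMA", "TRUNCATION", "MISALIGNMENT")

# Reference thorax extent (mm) that the default organ layout was drawn for;
# default() scales organ placement to the actual grid.
_REF_XY = 332.8
_REF_Z = 166.4


class PhantomError(ValueError):
    pass


class ArtifactError(ValueError):
    pass


@dataclass(frozen=True)
class ActivityRatios:
    """Tracer uptake per compartment relative to body soft tissue = 1.
    The myocardium must be the hottest compartment."""

    myocardium: float = 8.0
    blood: float = 1.5
    liver: float = 3.0
    lung: float = 0.5
    background: float = 1.0

    def __post_init__(self):
        vals = (self.myocardium, self.blood, self.liver, self.lung, self.background)
        if any(v < 0 or not np.isfinite(v) for v in vals):
            raise PhantomError("activity ratios must be nonnegative and finite")
        if not all(self.myocardium > v for v in vals[1:]):
            raise PhantomError("myocardium ratio must be strictly largest")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and activity parameters of the stylized thorax (world mm)."""

    grid: GridSpec
    body_half_axes_mm: tuple[float, float]
    fat_shell_mm: float
    lung_centers_mm: tuple[tuple[float, float, float], tuple[float, float, float]]
    lung_half_axes_mm: tuple[float, float, float]
    lung_target_L: float
    lv_center_mm: tuple[float, float, float]
    lv_inner_mm: float
    lv_outer_mm: float
    lv_extent_mm: float
    sternum_center_mm: tuple[float, float, float]
    diaphragm_z_mm: float
    body_top_z_mm: float = np.inf  # shoulder cut: air above this plane
    activity_ratios: ActivityRatios = field(default_factory=ActivityRatios)
    arms: bool = True
    arm_radius_mm: float = 13.0

    def __post_init__(self):
        if not (self.lv_outer_mm > self.lv_inner_mm > 0):
            raise PhantomError("need LV outer radius > inner radius > 0")
        if not (0.5 < self.lung_target_L < 6.0):
            raise PhantomError("target lung volume must lie in (0.5, 6.0) L")
        if self.fat_shell_mm < 0:
            raise PhantomError("fat shell thickness must be nonnegative")
        if any(a <= 0 for a in self.body_half_axes_mm):
            raise PhantomError("body half-axes must be positive")
        if any(a <= 0 for a in self.lung_half_axes_mm):
            raise PhantomError("lung half-axes must be positive")

    @classmethod
    def default(cls, grid: GridSpec | None = None, **overrides) -> "PhantomConfig":
        """Default thorax scaled to the grid extent.

        At the default 128 x 128 x 64 grid (2.6 mm isotropic) the lungs
        target 2.6 L, the scale typical of expiratory breath-hold
        attenuation maps.
        """
        if grid is None:
            grid = GridSpec((128, 128, 64))
        ex, ey, ez = grid.extent_mm
        sxy = min(ex, ey) / _REF_XY
        sz = ez / _REF_Z
        cfg = dict(
            grid=grid,
            body_half_axes_mm=(130.0 * sxy, 95.0 * sxy),
            fat_shell_mm=9.0 * sxy,
            lung_centers_mm=(
                (-72.0 * sxy, 4.0 * sxy, 16.0 * sz),
                (72.0 * sxy, 4.0 * sxy, 16.0 * sz),
            ),
            lung_half_axes_mm=(54.0 * sxy, 70.0 * sxy, 66.0 * sz),
            lung_target_L=2.6 * sxy * sxy * sz,
            lv_center_mm=(-25.0 * sxy, 8.0 * sxy, 2.0 * sz),
            lv_inner_mm=18.0 * sxy,
            lv_outer_mm=28.0 * sxy,
            lv_extent_mm=65.0 * sz,
            sternum_center_mm=(0.0, 80.0 * sxy, 2.0 * sz),
            diaphragm_z_mm=-41.6 * sz,
            body_top_z_mm=63.2 * sz,
            arm_radius_mm=13.0 * sxy,
        )
        cfg.update(overrides)
        return cls(**cfg)

    def lv_geometry(self) -> LVGeometry:
        return LVGeometry(
            center_mm=self.lv_center_mm,
            inner_mm=self.lv_inner_mm,
            outer_mm=self.lv_outer_mm,
            extent_mm=self.lv_extent_mm,
        )


def _ellipse2d(X, Y, cx, cy, ax, ay):
    return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 <= 1.0


def _lung_masks(config: PhantomConfig, scale: float, centers, interior, X, Y, Z):
    """Lung ellipsoids at the given size scale, clipped to the body interior,
    above the diaphragm and outside the cardiac exclusion cylinder."""
    a, b, c = (s * scale for s in config.lung_half_axes_mm)
    cx0, cy0, _ = config.lv_center_mm
    heart_r = config.lv_outer_mm + 6.0
    heart = ((X - cx0) ** 2 + (Y - cy0) ** 2 <= heart_r**2) & (
        Z >= config.lv_center_mm[2] - config.lv_extent_mm / 2 - 6.0
    )
    lungs = np.zeros(interior.shape, dtype=bool)
    for (lx, ly, lz) in centers:
        lungs |= ((X - lx) / a) ** 2 + ((Y - ly) / b) ** 2 + ((Z - lz) / c) ** 2 <= 1.0
    return lungs & interior & (Z > config.diaphragm_z_mm) & ~heart


def generate_phantom(
    config: PhantomConfig, seed: int
) -> tuple[TissueLabelMap, ActivityMap]:
    """Generate a deterministic thorax phantom.

    The anatomy is a pure function of (config, seed): the seed drives only
    small jitter fields (lung-volume scale and lung-centre offsets) that
    emulate inter-acquisition variability.  Lung ellipsoid axes are
    iteratively rescaled until the rasterized lung volume matches the
    (jittered) target; generation fails if the final volume deviates more
    than 15% from the configured target.
    """
    grid = config.grid
    rng = np.random.default_rng(seed)
    X, Y, Z = grid.meshgrid()
    bx, by = config.body_half_axes_mm

    # Seed-driven jitter: breath-hold depth and small lung displacements.
    vol_jitter = float(np.clip(rng.normal(1.0, 0.05), 0.9, 1.1))
    centers = tuple(
        tuple(np.asarray(c) + rng.uniform(-2.0, 2.0, size=3))
        for c in config.lung_centers_mm
    )
    target_L = config.lung_target_L * vol_jitter

    below_top = np.broadcast_to(Z <= config.body_top_z_mm, grid.shape)
    body = _ellipse2d(X, Y, 0.0, 0.0, bx, by)
    body = np.broadcast_to(body, grid.shape) & below_top
    t = config.fat_shell_mm
    if t > 0:
        interior = _ellipse2d(X, Y, 0.0, 0.0, bx - t, by - t)
        interior = np.broadcast_to(interior, grid.shape) & body
    else:
        interior = body

    labels = np.full(grid.shape, BACKGROUND, dtype=np.uint8)
    labels[body] = FAT
    labels[interior] = SOFT

    if config.arms:
        ex = grid.extent_mm[0] / 2.0
        for sgn in (-1.0, 1.0):
            arm = _ellipse2d(X, Y, sgn * (ex - config.arm_radius_mm - 1.0), 0.0,
                             config.arm_radius_mm, config.arm_radius_mm)
            labels[np.broadcast_to(arm, grid.shape) & below_top] = SOFT

    # Lungs: fixed-point rescale of the half-axes onto the target volume.
    voxel_L = grid.voxel_volume_mm3 * 1e-6
    scale = 1.0
    lungs = _lung_masks(config, scale, centers, interior, X, Y, Z)
    for _ in range(12):
        vol = lungs.sum() * voxel_L
        if vol > 0 and abs(vol / target_L - 1.0) <= 0.02:
            break
        if vol <= 0:
            scale *= 1.3
        else:
            scale *= float(np.clip((target_L / vol) ** (1.0 / 3.0), 0.7, 1.4))
        scale = float(np.clip(scale, 0.3, 2.5))
        lungs = _lung_masks(config, scale, centers, interior, X, Y, Z)
    vol = lungs.sum() * voxel_L
    if abs(vol / config.lung_target_L - 1.0) > 0.15:
        raise PhantomError(
            f"rasterized lung volume {vol:.3f} L misses target "
            f"{config.lung_target_L:.3f} L by more than 15%"
        )
    labels[lungs] = LUNG

    # Left ventricle: soft-tissue annulus + blood pool, overwrites lungs.
    lv = config.lv_geometry()
    cx, cy, cz = config.lv_center_mm
    r2 = (X - cx) ** 2 + (Y - cy) ** 2
    inz = (Z >= lv.apex_z_mm) & (Z <= lv.base_z_mm)
    heart_cyl = inz & (r2 <= config.lv_outer_mm**2)
    labels[heart_cyl] = SOFT
    ring = inz & (r2 >= config.lv_inner_mm**2) & (r2 <= config.lv_outer_mm**2)
    blood = inz & (r2 < config.lv_inner_mm**2)
    if np.any(ring & ~body):
        raise PhantomError("LV ring exits the body outline")
    if not ring.any():
        raise PhantomError("LV ring does not intersect the grid")

    # Sternum marker: anterior midline soft-tissue peg (site of sternal wires).
    sx, sy, sz_ = config.sternum_center_mm
    sternum = Box((sx - 12, sy - 10, sz_ - 30), (sx + 12, sy + 10, sz_ + 30)).contains(grid)
    labels[sternum & body] = SOFT

    # Activity: piecewise constant per compartment.
    ratios = config.activity_ratios
    values = np.zeros(grid.shape, dtype=np.float64)
    values[labels != BACKGROUND] = ratios.background
    values[labels == LUNG] = ratios.lung
    liver = interior & (Z < config.diaphragm_z_mm) & (X > 10.0 * bx / 130.0)
    values[liver & (labels == SOFT)] = ratios.liver
    values[blood] = ratios.blood
    values[ring] = ratios.myocardium

    return TissueLabelMap(grid, labels), ActivityMap(grid, values)


@dataclass(frozen=True)
class ArtifactSpec:
    """Declarative description of one injected attenuation-map artifact."""

    kind: str
    region: Region | None = None
    shift_mm: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ARTIFACT_KINDS:
            raise ArtifactError(f"unknown artifact kind {self.kind!r}")
        if self.kind == "MISALIGNMENT":
            if self.shift_mm is None:
                raise ArtifactError("MISALIGNMENT requires shift_mm")
            s = np.asarray(self.shift_mm, dtype=float)
            if not np.all(np.isfinite(s)):
                raise ArtifactError("shift must be finite")
            if np.linalg.norm(s) > 30.0:
                raise ArtifactError("misalignment shift magnitude must be <= 30 mm")
        elif self.region is None:
            raise ArtifactError(f"{self.kind} requires a region")


def inject_artifact(
    labels: TissueLabelMap, spec: ArtifactSpec
) -> tuple[TissueLabelMap, np.ndarray]:
    """Apply one artifact to a label map.

    Returns the new map and the boolean mask of changed voxels.  Voxels
    outside the region are untouched.  MISALIGNMENT is not handled here
    (shift the derived mu-map with :func:`shift_map` instead).

    Semantics per kind: STN/SMA set fat/soft voxels in the region to
    background (susceptibility void); LSTI swaps lung and soft tissue in the
    region; FSTI swaps fat and soft tissue; PMA turns lung voxels in a
    transaxial band into soft tissue (breathing during the map acquisition);
    TRUNCATION clears all tissue beyond a lateral half-plane.
    """
    if spec.kind == "MISALIGNMENT":
        raise ArtifactError("MISALIGNMENT is applied with shift_map, not inject_artifact")
    region = spec.region.contains(labels.grid)
    if not region.any():
        raise ArtifactError(f"{spec.kind} region does not intersect the grid")
    lab = labels.labels
    new = lab.copy()
    if spec.kind in ("STN", "SMA"):
        applicable = region & ((lab == FAT) | (lab == SOFT))
        new[applicable] = BACKGROUND
    elif spec.kind == "LSTI":
        applicable = region & ((lab == LUNG) | (lab == SOFT))
        new[region & (lab == LUNG)] = SOFT
        new[region & (lab == SOFT)] = LUNG
    elif spec.kind == "FSTI":
        applicable = region & ((lab == FAT) | (lab == SOFT))
        new[region & (lab == FAT)] = SOFT
        new[region & (lab == SOFT)] = FAT
    elif spec.kind == "PMA":
        if not isinstance(spec.region, Band):
            raise ArtifactError("PMA region must be a transaxial Band")
        applicable = region & (lab == LUNG)
        new[applicable] = SOFT
    elif spec.kind == "TRUNCATION":
        if not isinstance(spec.region, HalfPlane):
            raise ArtifactError("TRUNCATION region must be a HalfPlane")
        applicable = region & (lab != BACKGROUND)
        new[applicable] = BACKGROUND
    if not applicable.any():
        raise ArtifactError(
            f"{spec.kind} region contains no applicable tissue ({spec!r})"
        )
    changed = new != lab
    return labels.with_labels(new), changed


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.trunc(x + np.copysign(0.5, x))


def quantize_shift(shift_mm, voxel_size_mm) -> tuple[int, int, int]:
    """Quantize a mm shift to whole voxels, rounding half away from zero."""
    s = np.asarray(shift_mm, dtype=float)
    if s.shape != (3,) or not np.all(np.isfinite(s)):
        raise ValueError("shift must be a finite 3-vector")
    v = _round_half_away(s / np.asarray(voxel_size_mm, dtype=float))
    return tuple(int(i) for i in v)


def _translate(arr: np.ndarray, shift_vox, fill) -> np.ndarray:
    out = np.full_like(arr, fill)
    src, dst = [], []
    for n, s in zip(arr.shape, shift_vox):
        s = int(s)
        if abs(s) >= n:
            return out
        if s >= 0:
            dst.append(slice(s, n))
            src.append(slice(0, n - s))
        else:
            dst.append(slice(0, n + s))
            src.append(slice(-s, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def shift_map(volume, shift_mm):
    """Rigidly translate a map by a mm shift quantized to whole voxels.

    Positive components move content toward +x/+y/+z (z = cranial).  Voxels
    shifted in from outside the grid are background/zero.  Accepts MuMap,
    ActivityMap, TissueLabelMap or a plain ndarray.
    """
    s = np.asarray(shift_mm, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("shift must be finite")
    if np.linalg.norm(s) > 30.0:
        raise ValueError("shift magnitude must be <= 30 mm")
    if isinstance(volume, np.ndarray):
        raise TypeError("shift_map needs a grid-aware map, not a bare array")
    vox = quantize_shift(s, volume.grid.voxel_size_mm)
    if isinstance(volume, MuMap):
        return volume.with_mu(_translate(volume.mu, vox, 0.0))
    if isinstance(volume, ActivityMap):
        return volume.with_values(_translate(volume.values, vox, 0.0))
    if isinstance(volume, TissueLabelMap):
        return volume.with_labels(_translate(volume.labels, vox, BACKGROUND))
    raise TypeError(f"cannot shift object of type {type(volume)!r}")


def shift_mask(mask: np.ndarray, shift_mm, voxel_size_mm) -> np.ndarray:
    """Translate a boolean mask the same way shift_map translates a map."""
    vox = quantize_shift(shift_mm, voxel_size_mm)
    return _translate(mask, vox, False)
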