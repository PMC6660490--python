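"""Quantitative measurement chain for attenuation-map artifact studies.

Relative-difference maps (corrected / original x 100%), 42%-threshold
myocardium segmentation with SUV statistics, lung volumes by voxel counting
with test-retest comparison, and a simplified 17-segment polar map with
defect-extent / scar / hibernating scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import LVGeometry
from .grid import GridSpec
from .simulate import DEFAULT_MU_TABLE, MuTable
from .volumes import LUNG, ActivityMap, MuMap, TissueLabelMap


class QuantError(ValueError):
    pass


@dataclass(frozen=True)
class RDMap:
    """Relative-difference map in percent, defined on a validity mask where
    the original image is above a denominator floor."""

    grid: GridSpec
    rd: np.ndarray
    mask: np.ndarray

    def masked_values(self) -> np.ndarray:
        return self.rd[self.mask]


@dataclass(frozen=True)
class MyoStats:
    suv_mean: float
    suv_max: float
    n_voxels: int

    def __post_init__(self):
        if self.n_voxels < 1:
            raise QuantError("myocardial mask must contain at least one voxel")
        if not (self.suv_max >= self.suv_mean >= 0):
            raise QuantError("need suv_max >= suv_mean >= 0")


@dataclass(frozen=True)
class LungVolumeReport:
    """Test-retest lung volumes with the >10% incoherence flag."""

    vol1_L: float
    vol2_L: float
    ratio: float
    incoherent: bool


@dataclass(frozen=True)
class PolarMap17:
    """17-segment polar map: mean uptake per AHA segment normalized to a
    polar-map maximum of 100, plus the segment-level defect extent."""

    segments: np.ndarray
    defect_extent_pct: float
    defect_threshold: float = 50.0

    def __post_init__(self):
        seg = np.asarray(self.segments, dtype=np.float64)
        if seg.shape != (17,):
            raise QuantError("polar map needs exactly 17 segments")
        if seg.min() < -1e-9 or seg.max() > 100 + 1e-9:
            raise QuantError("segment values must lie in [0, 100]")
        object.__setattr__(self, "segments", seg)

    def reduced(self) -> np.ndarray:
        return self.segments < self.defect_threshold


def relative_difference(
    corrected: ActivityMap, original: ActivityMap, floor: float = 0.01
) -> RDMap:
    """RD = corrected / original x 100%, defined where the original is at
    least ``floor`` times its maximum."""
    if corrected.grid != original.grid:
        raise QuantError("corrected and original must share one grid")
    if not (floor > 0):
        raise QuantError("floor must be positive")
    omax = original.values.max()
    if omax <= 0:
        raise QuantError("original image is identically zero")
    mask = original.values >= floor * omax
    rd = np.full(original.values.shape, np.nan)
    # ratio first: corrected == original then gives exactly 100.0
    rd[mask] = 100.0 * (corrected.values[mask] / original.values[mask])
    return RDMap(original.grid, rd, mask)


def segment_myocardium(
    pet: ActivityMap, search_region: np.ndarray, threshold: float = 0.42
) -> np.ndarray:
    """Threshold segmentation of the myocardium: voxels in the search region
    at or above ``threshold`` (default 42%) of the regional maximum."""
    region = np.asarray(search_region, dtype=bool)
    if region.shape != pet.values.shape:
        raise QuantError("search region shape does not match image")
    if not region.any():
        raise QuantError("search region is empty")
    vals = pet.values[region]
    vmax = vals.max()
    if vmax <= 0 or vals.min() == vmax:
        raise QuantError("image is flat in the search region")
    mask = np.zeros_like(region)
    mask[region] = pet.values[region] >= threshold * vmax
    return mask


def myo_stats(pet: ActivityMap, mask: np.ndarray) -> MyoStats:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pet.values.shape:
        raise QuantError("mask shape does not match image")
    if not mask.any():
        raise QuantError("myocardial mask is empty")
    vals = pet.values[mask]
    return MyoStats(
        suv_mean=float(vals.mean()),
        suv_max=float(vals.max()),
        n_voxels=int(mask.sum()),
    )


def lung_volume(volume, table: MuTable = DEFAULT_MU_TABLE) -> float:
    """Lung volume in liters: count of lung voxels (label 1, or voxels at
    the lung attenuation coefficient) times the voxel volume."""
    if isinstance(volume, TissueLabelMap):
        count = int(np.count_nonzero(volume.labels == LUNG))
        vox = volume.grid.voxel_volume_mm3
    elif isinstance(volume, MuMap):
        count = int(np.count_nonzero(np.isclose(volume.mu, table.lung, atol=1e-9)))
        vox = volume.grid.voxel_volume_mm3
    else:
        raise QuantError("lung_volume needs a TissueLabelMap or MuMap")
    return count * vox * 1e-6


def test_retest(vol1_L: float, vol2_L: float) -> LungVolumeReport:
    """Test-retest lung-volume ratio; the incoherence flag fires for
    intra-scan variation strictly above 10%."""
    if vol1_L < 0 or not np.isfinite(vol1_L) or not np.isfinite(vol2_L):
        raise QuantError("volumes must be finite and nonnegative")
    if vol2_L <= 0:
        raise QuantError("retest volume must be positive")
    ratio = vol1_L / vol2_L
    return LungVolumeReport(
        vol1_L=float(vol1_L),
        vol2_L=float(vol2_L),
        ratio=float(ratio),
        incoherent=bool(abs(ratio - 1.0) > 0.10),
    )


# Long-axis zone fractions (from base): basal, mid, apical thirds of the
# wall plus an apical cap pooled over all angles.
_ZONES = ((0.0, 0.30), (0.30, 0.60), (0.60, 0.90), (0.90, 1.0 + 1e-9))
_SECTORS = (6, 6, 4, 1)


def polar_map_17(
    pet: ActivityMap, geometry: LVGeometry, defect_threshold: float = 50.0
) -> PolarMap17:
    """Project LV uptake onto the standard 17-segment polar map.

    The wall is sampled along the long axis into basal/mid/apical thirds
    plus an apical cap, with 6/6/4/1 angular sectors.  Segment values are
    sector means normalized so the polar-map maximum is 100; the defect
    extent is the percentage of segments below ``defect_threshold``.
    """
    grid = pet.grid
    X, Y, Z = grid.meshgrid()
    cx, cy, _ = geometry.center_mm
    r = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2)
    r = np.broadcast_to(r, grid.shape)
    phi = np.arctan2(Y - cy, X - cx)
    phi = np.broadcast_to(phi, grid.shape)
    frac = (geometry.base_z_mm - Z) / geometry.extent_mm
    frac = np.broadcast_to(frac, grid.shape)
    inz = (frac >= 0) & (frac <= 1)
    if not inz.any():
        raise QuantError("LV geometry lies outside the volume")

    seg_values = []
    for (zlo, zhi), nsec in zip(_ZONES, _SECTORS):
        zone = inz & (frac >= zlo) & (frac < zhi)
        ring = zone & (r >= geometry.inner_mm) & (r <= geometry.outer_mm)
        if nsec == 1:
            # apical cap pooled over all angles (the LV model is an open
            # cylinder, so the cap is sampled on the annulus as well)
            if not ring.any():
                raise QuantError("apex zone contains no voxels")
            seg_values.append(pet.values[ring].mean())
            continue
        width = 2.0 * np.pi / nsec
        sector_idx = np.floor((phi + np.pi) / width).astype(int)
        sector_idx = np.clip(sector_idx, 0, nsec - 1)
        for s in range(nsec):
            sel = ring & (sector_idx == s)
            if not sel.any():
                raise QuantError(f"empty polar-map sector (zone {zlo}-{zhi}, sector {s})")
            seg_values.append(pet.values[sel].mean())
    seg = np.asarray(seg_values, dtype=np.float64)
    vmax = seg.max()
    if vmax <= 0:
        raise QuantError("polar map has no uptake")
    seg = 100.0 * seg / vmax
    extent = 100.0 * np.count_nonzero(seg < defect_threshold) / 17.0
    return PolarMap17(seg, float(extent), defect_threshold)


def viability_scores(
    perfusion: PolarMap17, metabolism: PolarMap17
) -> dict[str, float]:
    """Scar and hibernating fractions of the left ventricle.

    A segment is scar when reduced in both perfusion and metabolism, and
    hibernating when reduced in perfusion but preserved in metabolism; both
    are reported as percentages of the 17 segments.
    """
    p = perfusion.reduced()
    m = metabolism.reduced()
    scar = 100.0 * np.count_nonzero(p & m) / 17.0
    hib = 100.0 * np.count_nonzero(p & ~m) / 17.0
    return {"scar_pct": float(scar), "hibernating_pct": float(hib)}
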