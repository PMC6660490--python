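"""Attenuation-map correction operators.

Three retrospective corrections for segmented MR attenuation maps:

* susceptibility-gap filling — each artifact voxel receives the most
  frequent tissue class among its six face-neighbours, propagated inward
  wavefront by wavefront;
* rigid re-alignment — exhaustive integer-voxel translation search
  maximizing the Dice overlap of the nonAC-PET body support with the
  mu-map body mask (translation only; clinical reports quote axial offsets);
* truncation completion — voxels seen in the nonAC-PET body support but
  missing from the mu-map are assigned soft tissue (a simple stand-in for
  joint activity/attenuation estimation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .simulate import DEFAULT_MU_TABLE, MuTable
from .volumes import BACKGROUND, FAT, LUNG, SOFT, ActivityMap, MuMap, TissueLabelMap

# Tie-break priority for the majority fill: artifacts sit inside the body
# where soft tissue dominates, so soft > fat > lung > background.
FILL_PRIORITY = (SOFT, FAT, LUNG, BACKGROUND)


class CorrectionError(ValueError):
    pass


@dataclass(frozen=True)
class FillReport:
    """Bookkeeping of one susceptibility fill."""

    n_artifact: int
    assigned_counts: dict[int, int]
    n_passes: int
    n_unresolved: int

    def __post_init__(self):
        if sum(self.assigned_counts.values()) != self.n_artifact - self.n_unresolved:
            raise ValueError("assigned counts must sum to artifact - unresolved")


@dataclass(frozen=True)
class ShiftEstimate:
    """Result of the rigid re-alignment search."""

    shift_mm: tuple[float, float, float]
    score: float
    search_mm: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("overlap score must be in [0, 1]")


_NEIGHBOR_SHIFTS = [
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
]


def _shift_bool(arr: np.ndarray, s) -> np.ndarray:
    out = np.zeros_like(arr)
    src, dst = [], []
    for n, k in zip(arr.shape, s):
        if k >= 0:
            dst.append(slice(k, n))
            src.append(slice(0, n - k))
        else:
            dst.append(slice(0, n + k))
            src.append(slice(-k, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def fill_susceptibility(labels, artifact_mask: np.ndarray):
    """Fill artifact voxels with the majority class of their six
    face-neighbours, propagating inward until every voxel is assigned.

    Passes are synchronous: a voxel assigned in one pass only counts as a
    neighbour from the next pass on.  Ties break by the fixed priority
    soft > fat > lung > background.  Accepts a TissueLabelMap or a plain
    label ndarray; returns (filled map of the same type, FillReport).
    """
    is_map = isinstance(labels, TissueLabelMap)
    lab = labels.labels if is_map else np.asarray(labels)
    mask = np.asarray(artifact_mask, dtype=bool)
    if mask.shape != lab.shape:
        raise CorrectionError("artifact mask shape does not match labels")
    if not mask.any():
        raise CorrectionError("artifact mask is empty")
    if mask.all():
        raise CorrectionError("artifact mask covers the entire volume: no seeds")

    work = lab.astype(np.uint8).copy()
    assigned = ~mask
    n_artifact = int(mask.sum())
    n_passes = 0
    while not assigned.all():
        counts = np.zeros((4,) + work.shape, dtype=np.int32)
        for s in _NEIGHBOR_SHIFTS:
            nb_assigned = _shift_bool(assigned, s)
            nb_labels = _shift_bool(work, s)  # zero-fill ok: masked by nb_assigned
            for c in range(4):
                counts[c] += (nb_assigned & (nb_labels == c)).astype(np.int32)
        frontier = ~assigned & (counts.sum(axis=0) > 0)
        if not frontier.any():
            raise CorrectionError("fill cannot progress: isolated artifact region")
        stacked = counts[list(FILL_PRIORITY)]
        choice = np.asarray(FILL_PRIORITY, dtype=np.uint8)[np.argmax(stacked, axis=0)]
        work[frontier] = choice[frontier]
        assigned |= frontier
        n_passes += 1

    assigned_counts = {
        c: int(np.count_nonzero(work[mask] == c)) for c in range(4)
    }
    report = FillReport(
        n_artifact=n_artifact,
        assigned_counts=assigned_counts,
        n_passes=n_passes,
        n_unresolved=0,
    )
    out = labels.with_labels(work) if is_map else work
    return out, report


def support_mask(pet: ActivityMap, frac: float = 0.05,
                 largest_component: bool = False,
                 closing_voxels: int = 4) -> np.ndarray:
    """Body support of a PET image: voxels above ``frac`` of the maximum,
    optionally reduced to the largest connected component.

    Connectivity is judged on a morphologically closed copy of the mask
    (``closing_voxels`` face-connected iterations) so that body parts
    separated by a narrow air gap inside the field of view — arms beside
    the trunk — count as one body; the returned mask is still the
    unclosed thresholded support.
    """
    vmax = pet.values.max()
    if vmax <= 0:
        raise CorrectionError("PET image has empty support")
    mask = pet.values >= frac * vmax
    if largest_component:
        closed = mask
        if closing_voxels > 0:
            closed = ndimage.binary_closing(
                mask, iterations=closing_voxels,
                structure=ndimage.generate_binary_structure(3, 1),
            )
            closed |= mask
        lab, n = ndimage.label(closed)
        if n == 0:
            raise CorrectionError("PET image has empty support")
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        mask = mask & (lab == (1 + int(np.argmax(sizes))))
    return mask


def estimate_shift(
    nonac_pet: ActivityMap,
    mu: MuMap,
    search_mm: tuple = ((-10.0, 10.0), (-10.0, 10.0), (-20.0, 20.0)),
    support_frac: float = 0.05,
) -> ShiftEstimate:
    """Estimate the rigid translation to apply to the mu-map so that its
    body mask best overlaps the nonAC-PET body support.

    Exhaustive integer-voxel search over ``search_mm`` (default +/-10 mm
    transaxial, +/-20 mm axial) maximizing the Dice coefficient; ties break
    toward the smallest shift, so an already-aligned map returns (0, 0, 0).
    """
    if nonac_pet.grid != mu.grid:
        raise CorrectionError("nonAC PET and mu-map must share one grid")
    pet_mask = support_mask(nonac_pet, support_frac)
    mu_mask = mu.mu > 0
    if not mu_mask.any():
        raise CorrectionError("mu-map body mask is empty")
    vox = nonac_pet.grid.voxel_size_mm
    ranges = []
    for (lo, hi), v in zip(search_mm, vox):
        if lo > hi:
            raise CorrectionError("invalid search range")
        # truncate toward zero so candidate shifts stay inside the range
        ranges.append(np.arange(int(lo / v), int(hi / v) + 1))
    na = int(pet_mask.sum())

    candidates = sorted(
        itertools.product(*ranges),
        key=lambda s: (s[0] * s[0] + s[1] * s[1] + s[2] * s[2], s),
    )
    best_shift, best_score = (0, 0, 0), -1.0
    shape = pet_mask.shape
    for shift in candidates:
        src, dst = [], []
        ok = True
        for n, k in zip(shape, shift):
            if abs(k) >= n:
                ok = False
                break
            if k >= 0:
                dst.append(slice(k, n))
                src.append(slice(0, n - k))
            else:
                dst.append(slice(0, n + k))
                src.append(slice(-k, n))
        if not ok:
            continue
        mu_part = mu_mask[tuple(src)]
        inter = int(np.count_nonzero(pet_mask[tuple(dst)] & mu_part))
        nb = int(np.count_nonzero(mu_part))
        dice = 2.0 * inter / (na + nb) if (na + nb) else 0.0
        if dice > best_score:
            best_score, best_shift = dice, shift
    return ShiftEstimate(
        shift_mm=tuple(float(k * v) for k, v in zip(best_shift, vox)),
        score=best_score,
        search_mm=tuple(tuple(map(float, r)) for r in search_mm),
    )


def complete_truncation(
    mu: MuMap,
    nonac_pet: ActivityMap,
    table: MuTable = DEFAULT_MU_TABLE,
    support_frac: float = 0.05,
    erode_voxels: int = 3,
) -> MuMap:
    """Restore truncated tissue: background voxels of the mu-map that lie
    inside the nonAC-PET body support (largest connected component) are
    assigned the soft-tissue coefficient; nothing else changes.

    The support is eroded by ``erode_voxels`` face-connected voxels so that
    reconstruction blur spilling past the body outline does not grow a
    spurious tissue rind on untruncated maps.
    """
    if nonac_pet.grid != mu.grid:
        raise CorrectionError("nonAC PET and mu-map must share one grid")
    support = support_mask(nonac_pet, support_frac, largest_component=True)
    if erode_voxels > 0:
        support = ndimage.binary_erosion(support, iterations=erode_voxels)
    out = mu.mu.copy()
    out[support & (mu.mu == 0)] = table.soft
    return mu.with_mu(out)
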