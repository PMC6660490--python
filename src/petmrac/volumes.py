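"""Volumetric containers: tissue labels, attenuation, activity."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridSpec

# Four-class segmentation codes of MR-derived attenuation maps.
BACKGROUND = 0
LUNG = 1
FAT = 2
SOFT = 3
TISSUE_CLASSES = (BACKGROUND, LUNG, FAT, SOFT)
CLASS_NAMES = {BACKGROUND: "background", LUNG: "lung", FAT: "fat", SOFT: "soft"}


def _check_shape(grid: GridSpec, arr: np.ndarray, what: str) -> None:
    if tuple(arr.shape) != tuple(grid.shape):
        raise ValueError(f"{what} shape {arr.shape} does not match grid {grid.shape}")


@dataclass(frozen=True)
class TissueLabelMap:
    """Four-class tissue segmentation: 0 background/air, 1 lung, 2 fat,
    3 soft tissue — the stand-in for a DIXON-style attenuation segmentation."""

    grid: GridSpec
    labels: np.ndarray

    def __post_init__(self):
        labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        _check_shape(self.grid, labels, "label map")
        if labels.max(initial=0) > SOFT:
            raise ValueError("labels must be in {0, 1, 2, 3}")
        object.__setattr__(self, "labels", labels)

    def with_labels(self, labels: np.ndarray) -> "TissueLabelMap":
        return TissueLabelMap(self.grid, labels)

    def class_counts(self) -> dict[int, int]:
        counts = np.bincount(self.labels.ravel(), minlength=4)
        return {c: int(counts[c]) for c in TISSUE_CLASSES}


@dataclass(frozen=True)
class ActivityMap:
    """Nonnegative tracer activity (arbitrary units) on a grid; holds both
    ground-truth phantoms and reconstructed PET images."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self):
        values = np.ascontiguousarray(self.values, dtype=np.float64)
        _check_shape(self.grid, values, "activity map")
        if not np.all(np.isfinite(values)):
            raise ValueError("activity values must be finite")
        if values.min(initial=0.0) < 0:
            raise ValueError("activity values must be nonnegative")
        object.__setattr__(self, "values", values)

    def with_values(self, values: np.ndarray) -> "ActivityMap":
        return ActivityMap(self.grid, values)


@dataclass(frozen=True)
class MuMap:
    """Linear attenuation coefficients at 511 keV in cm^-1."""

    grid: GridSpec
    mu: np.ndarray

    def __post_init__(self):
        mu = np.ascontiguousarray(self.mu, dtype=np.float64)
        _check_shape(self.grid, mu, "mu map")
        if not np.all(np.isfinite(mu)):
            raise ValueError("mu values must be finite")
        if mu.min(initial=0.0) < 0:
            raise ValueError("mu values must be nonnegative")
        object.__setattr__(self, "mu", mu)

    def with_mu(self, mu: np.ndarray) -> "MuMap":
        return MuMap(self.grid, mu)
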