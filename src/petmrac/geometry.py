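"""Geometric primitives used to place artifacts and sample the left ventricle.

Regions are defined in world millimetres and rasterized centre-inclusive: a
voxel belongs to a region iff its centre does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridSpec

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class Sphere:
    center_mm: tuple[float, float, float]
    radius_mm: float

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("sphere radius must be positive")

    def contains(self, grid: GridSpec) -> np.ndarray:
        X, Y, Z = grid.meshgrid()
        cx, cy, cz = self.center_mm
        return (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= self.radius_mm**2


@dataclass(frozen=True)
class Box:
    lo_mm: tuple[float, float, float]
    hi_mm: tuple[float, float, float]

    def __post_init__(self):
        if any(l > h for l, h in zip(self.lo_mm, self.hi_mm)):
            raise ValueError("box lo must not exceed hi")

    def contains(self, grid: GridSpec) -> np.ndarray:
        X, Y, Z = grid.meshgrid()
        lo, hi = self.lo_mm, self.hi_mm
        return (
            (X >= lo[0]) & (X <= hi[0])
            & (Y >= lo[1]) & (Y <= hi[1])
            & (Z >= lo[2]) & (Z <= hi[2])
        )


@dataclass(frozen=True)
class Band:
    """Slab orthogonal to one axis, e.g. a transaxial band for breathing
    artifacts above the diaphragm."""

    lo_mm: float
    hi_mm: float
    axis: str = "z"

    def __post_init__(self):
        if self.axis not in _AXES:
            raise ValueError(f"unknown axis {self.axis!r}")
        if self.lo_mm > self.hi_mm:
            raise ValueError("band lo must not exceed hi")

    def contains(self, grid: GridSpec) -> np.ndarray:
        C = grid.meshgrid()[_AXES[self.axis]]
        out = (C >= self.lo_mm) & (C <= self.hi_mm)
        return np.broadcast_to(out, grid.shape)


@dataclass(frozen=True)
class HalfPlane:
    """Everything strictly beyond ``offset_mm`` in ``direction`` along
    ``axis`` — the shape of a lateral field-of-view cut-off."""

    offset_mm: float
    axis: str = "x"
    direction: int = 1

    def __post_init__(self):
        if self.axis not in _AXES:
            raise ValueError(f"unknown axis {self.axis!r}")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")

    def contains(self, grid: GridSpec) -> np.ndarray:
        C = grid.meshgrid()[_AXES[self.axis]]
        out = self.direction * (C - self.offset_mm) > 0
        return np.broadcast_to(out, grid.shape)


Region = Sphere | Box | Band | HalfPlane


@dataclass(frozen=True)
class LVGeometry:
    """Left-ventricular annulus with its long axis along z.

    ``center_mm`` is the ring centre, ``inner_mm``/``outer_mm`` the
    endo-/epicardial radii, ``extent_mm`` the base-to-apex length.  The base
    is the cranial end.
    """

    center_mm: tuple[float, float, float]
    inner_mm: float
    outer_mm: float
    extent_mm: float

    def __post_init__(self):
        if not (self.outer_mm > self.inner_mm > 0):
            raise ValueError("need outer radius > inner radius > 0")
        if self.extent_mm <= 0:
            raise ValueError("long-axis extent must be positive")

    @property
    def base_z_mm(self) -> float:
        return self.center_mm[2] + self.extent_mm / 2.0

    @property
    def apex_z_mm(self) -> float:
        return self.center_mm[2] - self.extent_mm / 2.0

    def ring_mask(self, grid: GridSpec) -> np.ndarray:
        """Boolean mask of the myocardial ring (ground truth)."""
        X, Y, Z = grid.meshgrid()
        cx, cy, _ = self.center_mm
        r2 = (X - cx) ** 2 + (Y - cy) ** 2
        inz = (Z >= self.apex_z_mm) & (Z <= self.base_z_mm)
        return inz & (r2 >= self.inner_mm**2) & (r2 <= self.outer_mm**2)

    def search_box(self, grid: GridSpec, margin_mm: float = 12.0) -> np.ndarray:
        """Boolean box around the LV used as myocardium search region."""
        cx, cy, _ = self.center_mm
        r = self.outer_mm + margin_mm
        box = Box(
            (cx - r, cy - r, self.apex_z_mm - margin_mm),
            (cx + r, cy + r, self.base_z_mm + margin_mm),
        )
        return box.contains(grid)
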