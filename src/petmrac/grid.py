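"""Volumetric grid description shared by all maps.

World coordinates are in millimetres with the origin at the volume centre:
axis x runs left->right, y posterior->anterior, z caudal->cranial, and the
centre of voxel (i, j, k) sits at ((i - (nx-1)/2) dx, ...).  All maps in the
package (tissue labels, attenuation, activity) live on one of these grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Regular 3-D voxel grid.

    Parameters
    ----------
    shape
        Voxel counts (nx, ny, nz); every dimension must be >= 16.
    voxel_size_mm
        Edge lengths of a voxel in mm.  The default 2.6 mm isotropic grid
        matches segmented MR attenuation maps of integrated PET/MR systems.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (2.6, 2.6, 2.6)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.voxel_size_mm) != 3:
            raise ValueError("GridSpec is three-dimensional")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(
            self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm)
        )
        if any(n < 16 for n in self.shape):
            raise ValueError(f"all grid dimensions must be >= 16, got {self.shape}")
        if any(not np.isfinite(v) or v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive and finite")

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_size_mm
        return dx * dy * dz

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * v for n, v in zip(self.shape, self.voxel_size_mm))

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1-D voxel-centre coordinates (x, y, z) in mm, origin at centre."""
        return tuple(
            (np.arange(n) - (n - 1) / 2.0) * v
            for n, v in zip(self.shape, self.voxel_size_mm)
        )

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable voxel-centre coordinate arrays of shapes
        (nx,1,1), (1,ny,1), (1,1,nz)."""
        x, y, z = self.coords()
        return x[:, None, None], y[None, :, None], z[None, None, :]
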