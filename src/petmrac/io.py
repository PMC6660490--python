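"""NIfTI and config-file I/O.

Volumes are exchanged as NIfTI-1 (.nii / .nii.gz) via nibabel with the voxel
size in the header and the world origin at the volume centre.  Phantom and
cohort configuration round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .geometry import Band, Box, HalfPlane, Sphere
from .grid import GridSpec
from .phantom import ActivityRatios, ArtifactSpec, PhantomConfig
from .volumes import ActivityMap, MuMap, TissueLabelMap


def _affine(grid: GridSpec) -> np.ndarray:
    aff = np.diag(list(grid.voxel_size_mm) + [1.0])
    for a in range(3):
        aff[a, 3] = -(grid.shape[a] - 1) / 2.0 * grid.voxel_size_mm[a]
    return aff


def save_volume(volume, path: str | Path) -> None:
    """Write a TissueLabelMap / ActivityMap / MuMap as NIfTI-1."""
    if isinstance(volume, TissueLabelMap):
        data = volume.labels.astype(np.uint8)
    elif isinstance(volume, ActivityMap):
        data = volume.values.astype(np.float32)
    elif isinstance(volume, MuMap):
        data = volume.mu.astype(np.float32)
    else:
        raise TypeError(f"cannot save object of type {type(volume)!r}")
    img = nib.Nifti1Image(data, _affine(volume.grid))
    img.header.set_zooms(volume.grid.voxel_size_mm)
    nib.save(img, str(path))


def _load(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    # zooms are stored float32; round so 2.6 mm survives the round-trip
    zooms = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])
    grid = GridSpec(tuple(data.shape), zooms)
    return grid, data


def load_labels(path: str | Path) -> TissueLabelMap:
    grid, data = _load(path)
    return TissueLabelMap(grid, np.rint(data).astype(np.uint8))


def load_activity(path: str | Path) -> ActivityMap:
    grid, data = _load(path)
    return ActivityMap(grid, np.asarray(data, dtype=np.float64))


def load_mu(path: str | Path) -> MuMap:
    grid, data = _load(path)
    return MuMap(grid, np.asarray(data, dtype=np.float64))


def save_phantom_config(config: PhantomConfig, path: str | Path) -> None:
    doc = asdict(config)
    doc["grid"] = {
        "shape": list(config.grid.shape),
        "voxel_size_mm": list(config.grid.voxel_size_mm),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _as_tuple(x):
    return tuple(x) if isinstance(x, (list, tuple)) else x


def load_phantom_config(path: str | Path) -> PhantomConfig:
    doc = yaml.safe_load(Path(path).read_text())
    grid = GridSpec(
        tuple(doc["grid"]["shape"]), tuple(doc["grid"]["voxel_size_mm"])
    )
    ratios = ActivityRatios(**doc.get("activity_ratios", {}))
    kwargs = {
        k: v
        for k, v in doc.items()
        if k not in ("grid", "activity_ratios")
    }
    for k in (
        "body_half_axes_mm",
        "lung_half_axes_mm",
        "lv_center_mm",
        "sternum_center_mm",
    ):
        if k in kwargs:
            kwargs[k] = _as_tuple(kwargs[k])
    if "lung_centers_mm" in kwargs:
        kwargs["lung_centers_mm"] = tuple(tuple(c) for c in kwargs["lung_centers_mm"])
    return PhantomConfig(grid=grid, activity_ratios=ratios, **kwargs)


_REGION_TYPES = {"sphere": Sphere, "box": Box, "band": Band, "halfplane": HalfPlane}


def artifact_spec_from_dict(doc: dict) -> ArtifactSpec:
    """Build an ArtifactSpec from a plain mapping, e.g. parsed YAML like
    ``{kind: STN, region: {type: sphere, center_mm: [0, 80, 0],
    radius_mm: 14}}``."""
    region = None
    if doc.get("region") is not None:
        rdoc = dict(doc["region"])
        rtype = _REGION_TYPES[rdoc.pop("type").lower()]
        for k, v in rdoc.items():
            rdoc[k] = _as_tuple(v)
        region = rtype(**rdoc)
    shift = doc.get("shift_mm")
    return ArtifactSpec(
        kind=doc["kind"],
        region=region,
        shift_mm=tuple(shift) if shift is not None else None,
        seed=int(doc.get("seed", 0)),
    )
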