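"""Volume / label-map data model and NIfTI-1 I/O.

All stages of the segmentation framework operate on a :class:`Volume`
(a 3D grid of Hounsfield units on an isotropic lattice) and produce or
consume :class:`LabelMap` objects on the same lattice.

Axis convention (fixed, applied consistently across the package):

* axis 0 (x): transverse, left/right
* axis 1 (y): vertical
* axis 2 (z): sagittal depth; index 0 is the anterior (nipple) end and
  the maximum index is the posterior (chest-wall) end.  A "posterior to
  anterior" scan therefore iterates z from the last index down to 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "COMPONENT_CODES",
    "CODE_COMPONENTS",
    "Volume",
    "LabelMap",
    "ComponentFlags",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
]

#: canonical component -> integer code mapping.  Air is 0 so that an
#: all-zero label grid is a legal, fully "background" map.
COMPONENT_CODES: dict[str, int] = {
    "air": 0,
    "fat": 1,
    "gland": 2,
    "skin": 3,
    "muscle": 4,
    "skinfold": 5,
    "rib": 6,
    "implant": 7,
}

CODE_COMPONENTS: dict[int, str] = {v: k for k, v in COMPONENT_CODES.items()}

MIN_Z_EXTENT = 16


@dataclass
class Volume:
    """3D scalar grid of HU values with isotropic voxel spacing."""

    data: np.ndarray
    spacing_mm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("not a 3D volume")
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite voxels")
        if not (self.spacing_mm > 0):
            raise ValueError("spacing_mm must be positive")
        if self.data.shape[2] < MIN_Z_EXTENT:
            raise ValueError(
                f"z extent must be >= {MIN_Z_EXTENT} voxels, got {self.data.shape[2]}"
            )
        self.spacing_mm = float(self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing_mm**3


@dataclass
class LabelMap:
    """Integer component-code grid congruent with a :class:`Volume`."""

    labels: np.ndarray
    spacing_mm: float
    code_table: dict[str, int] = field(default_factory=lambda: dict(COMPONENT_CODES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("not a 3D label map")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer grid")
        self.labels = self.labels.astype(np.uint8, copy=False)
        allowed = set(self.code_table.values())
        present = set(np.unique(self.labels).tolist())
        if not present <= allowed:
            raise ValueError(f"label codes {sorted(present - allowed)} not in code table")
        self.spacing_mm = float(self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, *components: str) -> np.ndarray:
        """Boolean mask of the union of the named components."""
        out = np.zeros(self.labels.shape, dtype=bool)
        for name in components:
            out |= self.labels == self.code_table[name]
        return out

    def volume_ml(self, component: str) -> float:
        n = int(np.count_nonzero(self.labels == self.code_table[component]))
        return n * self.spacing_mm**3 / 1000.0


@dataclass
class ComponentFlags:
    """Presence flags for the optional components.

    Skin, adipose and glandular tissue are present in every breast image
    and carry no flag.
    """

    muscle: bool = False
    skinfold: bool = False
    rib: bool = False
    implant: bool = False

    def as_dict(self) -> dict[str, bool]:
        return {
            "muscle": self.muscle,
            "skinfold": self.skinfold,
            "rib": self.rib,
            "implant": self.implant,
        }


def _affine(spacing_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = spacing_mm
    return aff


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_volume(path: str | Path, resample: bool = False) -> Volume:
    """Read a NIfTI-1 HU volume.

    Anisotropic spacing raises unless ``resample=True``, in which case the
    grid is linearly resampled onto an isotropic lattice at the smallest
    of the three voxel pitches.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 3:
        raise ValueError("not a 3D volume")
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if not np.allclose(zooms, zooms[0], rtol=1e-3):
        if not resample:
            raise ValueError(f"anisotropic spacing {tuple(zooms)}; pass resample=True")
        from scipy.ndimage import zoom as _zoom

        target = float(zooms.min())
        data = _zoom(data, zooms / target, order=1).astype(np.float32)
        zooms = np.array([target] * 3)
    return Volume(data=data, spacing_mm=float(zooms[0]))


def write_volume(v: Volume, path: str | Path) -> None:
    path = Path(path)
    img = nib.Nifti1Image(v.data.astype(np.float32), _affine(v.spacing_mm))
    img.header.set_zooms((v.spacing_mm,) * 3)
    nib.save(img, str(path))


def write_labels(l: LabelMap, path: str | Path) -> None:
    """Write a LabelMap as unsigned-integer NIfTI plus a JSON sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(l.labels.astype(np.uint8), _affine(l.spacing_mm))
    img.header.set_zooms((l.spacing_mm,) * 3)
    nib.save(img, str(path))
    sidecar = {"code_table": l.code_table, "spacing_mm": l.spacing_mm}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_labels(path: str | Path) -> LabelMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError("not a 3D label map")
    spacing = float(img.header.get_zooms()[0])
    sidecar = _sidecar_path(path)
    code_table = dict(COMPONENT_CODES)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "code_table" in meta:
            code_table = {k: int(v) for k, v in meta["code_table"].items()}
        spacing = float(meta.get("spacing_mm", spacing))
    return LabelMap(labels=data.astype(np.uint8), spacing_mm=spacing, code_table=code_table)
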