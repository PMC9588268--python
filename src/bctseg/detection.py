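"""Stage 1: presence investigation and seed localization.

Each optional component (skinfold, rib, silicone implant, pectoralis
muscle) is searched for by thresholding the volume at the mean of the
reference HU of the target and its surrounding component, followed by
connected-component analysis with a component-specific pre-filter:

* skinfold - per-slice 2D CCA scanning from the posterior end; the
  first slice holding two or more soft-tissue objects yields the breast
  (largest object) and fold seeds, which are extruded toward the
  posterior end;
* rib / implant - 5x5x5 erosion of the high-HU binary image, then 3D
  CCA; surviving objects are classified implant vs rib by HU proximity
  and size;
* muscle - 5x5x5 Gaussian denoising before thresholding, then 3D CCA
  restricted to components reaching the posterior fifth of the grid.

Absence of a component is a valid outcome, reported through
:class:`~bctseg.core_io.ComponentFlags`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .calibration import CalibrationTable
from .core_io import ComponentFlags, Volume

__all__ = [
    "SeedSet",
    "component_threshold",
    "soft_tissue_mask",
    "detect_skinfold",
    "detect_hard_components",
    "detect_muscle",
    "detect_all",
]

#: minimum 2D object area (voxels) for the skinfold slice scan
MIN_FOLD_AREA = 25
#: minimum component volume for a muscle seed
MIN_MUSCLE_VOLUME_MM3 = 1000.0
#: implant classification: component must exceed this volume
MIN_IMPLANT_VOLUME_MM3 = 5000.0
#: minimum surviving eroded-component size for hard seeds (voxels)
MIN_HARD_SEED_VOXELS = 20
#: posterior fraction of z-slices a muscle seed must reach into
MUSCLE_POSTERIOR_FRACTION = 0.2

_STRUCT_2D = np.ones((3, 3), dtype=bool)
_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)
_CUBE5 = np.ones((5, 5, 5), dtype=bool)


@dataclass
class SeedSet:
    """Binary seed regions per component plus presence flags."""

    flags: ComponentFlags = field(default_factory=ComponentFlags)
    skinfold_seed: np.ndarray | None = None
    breast_seed: np.ndarray | None = None
    rib_seed: np.ndarray | None = None
    implant_seed: np.ndarray | None = None
    muscle_seed: np.ndarray | None = None

    def seed_union(self) -> np.ndarray | None:
        parts = [
            s
            for s in (self.skinfold_seed, self.rib_seed, self.implant_seed, self.muscle_seed)
            if s is not None
        ]
        if not parts:
            return None
        out = parts[0].copy()
        for p in parts[1:]:
            out |= p
        return out


def component_threshold(cal: CalibrationTable, target: str, neighbor: str) -> float:
    """Mean of the reference HU of the target and its surrounding component."""
    return 0.5 * (cal.mean(target) + cal.mean(neighbor))


def soft_tissue_mask(v: Volume, cal: CalibrationTable) -> np.ndarray:
    """Binary image of all soft tissue (threshold between fat and air)."""
    return v.data >= component_threshold(cal, "fat", "air")


def detect_skinfold(
    v: Volume, cal: CalibrationTable, min_area: int = MIN_FOLD_AREA
) -> tuple[bool, np.ndarray, np.ndarray]:
    """Scan slices posterior -> anterior for a second soft-tissue object.

    Returns ``(flag, skinfold_seed, breast_seed)``.  When a qualifying
    slice is found, its largest 2D object seeds the breast and the
    remaining objects seed the fold; both 2D seeds are extruded from
    that slice to the posterior end of the grid.  With no qualifying
    slice the flag is False and both seeds are empty.
    """
    soft = soft_tissue_mask(v, cal)
    nz = v.shape[2]
    fold_seed = np.zeros(v.shape, dtype=bool)
    breast_seed = np.zeros(v.shape, dtype=bool)
    for z in range(nz - 1, -1, -1):
        sl = soft[:, :, z]
        lab, n = ndi.label(sl, structure=_STRUCT_2D)
        if n < 2:
            continue
        counts = np.bincount(lab.ravel())[1:]
        big = np.flatnonzero(counts >= min_area) + 1
        if big.size < 2:
            continue
        largest = big[np.argmax(counts[big - 1])]
        breast_2d = lab == largest
        fold_2d = np.isin(lab, big[big != largest])
        breast_seed[:, :, z:] = breast_2d[:, :, None]
        fold_seed[:, :, z:] = fold_2d[:, :, None]
        return True, fold_seed, breast_seed
    return False, fold_seed, breast_seed


def detect_hard_components(
    v: Volume,
    cal: CalibrationTable,
    min_seed_voxels: int = MIN_HARD_SEED_VOXELS,
) -> tuple[bool, bool, np.ndarray, np.ndarray]:
    """Detect ribs and silicone implant among the strongly absorbing voxels.

    The high-HU binary image (threshold between implant and gland) is
    eroded with a 5x5x5 element so sub-kernel bright slivers vanish,
    then 3D CCA labels the survivors.  A component whose mean HU is
    nearer the silicone reference than the rib reference *and* whose
    (pre-erosion equivalent) volume exceeds 5 cm^3 is the implant;
    everything else is a rib.

    Returns ``(rib_flag, implant_flag, rib_seed, implant_seed)``.
    """
    thr = component_threshold(cal, "implant", "gland")
    # 3x3x3 median suppresses noise speckle that would otherwise riddle the
    # binary image with holes and let the 5x5x5 erosion shatter the implant
    binary = ndi.median_filter(v.data, size=3, mode="reflect") >= thr
    eroded = ndi.binary_erosion(binary, structure=_CUBE5)
    lab, n = ndi.label(eroded, structure=_STRUCT_3D)
    rib_seed = np.zeros(v.shape, dtype=bool)
    implant_seed = np.zeros(v.shape, dtype=bool)
    if n == 0:
        return False, False, rib_seed, implant_seed
    mm3 = v.voxel_volume_mm3
    mu_si, mu_rib = cal.mean("implant"), cal.mean("rib")
    # the size rule concerns the object's full (pre-erosion) extent
    parent_lab, _ = ndi.label(binary, structure=_STRUCT_3D)
    parent_counts = np.bincount(parent_lab.ravel())
    for comp in range(1, n + 1):
        region = lab == comp
        n_vox = int(region.sum())
        if n_vox < min_seed_voxels:
            continue
        mean_hu = float(v.data[region].mean())
        parents = np.unique(parent_lab[region])
        parents = parents[parents > 0]
        vol = float(parent_counts[parents].sum()) * mm3
        if abs(mean_hu - mu_si) < abs(mean_hu - mu_rib) and vol > MIN_IMPLANT_VOLUME_MM3:
            implant_seed |= region
        else:
            rib_seed |= region
    return bool(rib_seed.any()), bool(implant_seed.any()), rib_seed, implant_seed


def detect_muscle(
    v: Volume,
    cal: CalibrationTable,
    exclude: np.ndarray | None = None,
    min_volume_mm3: float = MIN_MUSCLE_VOLUME_MM3,
) -> tuple[bool, np.ndarray]:
    """Detect the pectoralis muscle.

    A Gaussian denoise filter with a 5x5x5 support (sigma 1 voxel,
    truncated at two sigma) precedes thresholding between the muscle
    and gland means; compact gland masses fall below the threshold once
    smoothed.  3D CCA then keeps components that reach into the
    posterior fifth of the z-slices (the muscle enters from the chest
    wall) and exceed a minimum volume; the largest survivor is the
    muscle seed.
    """
    smoothed = ndi.gaussian_filter(v.data, sigma=1.0, truncate=2.0)
    thr = component_threshold(cal, "muscle", "gland")
    binary = smoothed >= thr
    if exclude is not None:
        binary &= ~exclude
    lab, n = ndi.label(binary, structure=_STRUCT_3D)
    seed = np.zeros(v.shape, dtype=bool)
    if n == 0:
        return False, seed
    nz = v.shape[2]
    z_floor = int(np.ceil(nz * (1.0 - MUSCLE_POSTERIOR_FRACTION)))
    counts = np.bincount(lab.ravel())
    min_vox = min_volume_mm3 / v.voxel_volume_mm3
    best, best_n = 0, 0
    for comp in range(1, n + 1):
        if counts[comp] < min_vox or counts[comp] <= best_n:
            continue
        if not (lab[:, :, z_floor:] == comp).any():
            continue
        best, best_n = comp, counts[comp]
    if best == 0:
        return False, seed
    seed = lab == best
    return True, seed


def detect_all(v: Volume, cal: CalibrationTable) -> SeedSet:
    """Run the full presence investigation in the framework's order."""
    rib_flag, implant_flag, rib_seed, implant_seed = detect_hard_components(v, cal)
    fold_flag, fold_seed, breast_seed = detect_skinfold(v, cal)
    hard = rib_seed | implant_seed
    hard_grown = ndi.binary_dilation(hard, structure=_CUBE5) if hard.any() else hard
    muscle_flag, muscle_seed = detect_muscle(v, cal, exclude=hard_grown)
    # seeds must stay pairwise disjoint
    muscle_seed &= ~(rib_seed | implant_seed | fold_seed)
    return SeedSet(
        flags=ComponentFlags(
            muscle=muscle_flag, skinfold=fold_flag, rib=rib_flag, implant=implant_flag
        ),
        skinfold_seed=fold_seed if fold_flag else None,
        breast_seed=breast_seed if fold_flag else None,
        rib_seed=rib_seed if rib_flag else None,
        implant_seed=implant_seed if implant_flag else None,
        muscle_seed=muscle_seed if muscle_flag else None,
    )
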