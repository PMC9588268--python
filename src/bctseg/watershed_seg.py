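"""Stage 2: adaptive seeded watershed segmentation of skin, muscle and
skinfold, plus morphological recovery of the strongly absorbing
components.

All watersheds flood the negated Euclidean distance transform of a
thresholded binary image, so floods meet at minimal cross-sections
(necks) between touching bodies.  Markers follow the component-specific
constructions:

* skinfold - the two extruded seeds (fold and breast) from the slice
  scan compete on the soft-tissue binary image;
* muscle - the object marker is the upper-40% distance core clipped to
  the detected seed, competing against the breast soft tissue beyond a
  tight neighborhood of the seed;
* skin - the skin/gland binary image is augmented with the background
  air (which deepens the distance basin under the skin shell), the
  milk ducts are cut with a 1.8-cm sphere at the nipple tip, markers
  are the air body versus interior voxels beyond the median positive
  distance and deeper than any plausible skin, and after flooding the
  air is removed and the duct voxels are restored.

Each soft-tissue result is closed with a 3x3x3 element so its volume
tracks the pre-watershed thresholded component.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from ._flood import watershed
from .calibration import CalibrationTable
from .core_io import Volume
from .detection import SeedSet, component_threshold, soft_tissue_mask

__all__ = [
    "segment_hard",
    "segment_skinfold",
    "segment_muscle",
    "segment_skin",
    "locate_nipple",
    "upper_distance_marker",
]

_CUBE3 = np.ones((3, 3, 3), dtype=bool)
_CUBE5 = np.ones((5, 5, 5), dtype=bool)
_FACE = ndi.generate_binary_structure(3, 1)

#: diameter of the duct-cutting sphere at the nipple (mm)
DUCT_SPHERE_DIAMETER_MM = 18.0
#: muscle marker keeps the upper 40% of the distance distribution
MUSCLE_MARKER_PERCENTILE = 60.0
#: interior watershed markers must lie deeper than any plausible skin (mm)
MAX_SKIN_DEPTH_MM = 4.0


def _close(region: np.ndarray, forbidden: np.ndarray | None = None) -> np.ndarray:
    # edge-padded closing: a zero border would erode regions that touch the
    # field-of-view cut (e.g. the chest wall at the last slice)
    padded = np.pad(region, 1, mode="edge")
    closed = ndi.binary_closing(padded, structure=_CUBE3)[1:-1, 1:-1, 1:-1]
    if forbidden is not None:
        closed &= ~forbidden
    return closed


def segment_hard(seed: np.ndarray, binary_image: np.ndarray) -> np.ndarray:
    """Recover the full extent of an eroded hard-component seed.

    The seed is dilated with the same 5x5x5 element used by the
    detection erosion, clipped to the thresholded binary image, and
    geodesically propagated (face connectivity) inside it, recovering
    boundary voxels the opening removed.
    """
    if not seed.any():
        raise ValueError("empty hard-component seed")
    dilated = ndi.binary_dilation(seed, structure=_CUBE5) & binary_image
    return ndi.binary_propagation(dilated, mask=binary_image, structure=_FACE)


def segment_skinfold(
    v: Volume,
    seeds: SeedSet,
    cal: CalibrationTable,
    removed: np.ndarray | None = None,
) -> np.ndarray:
    """Separate an attached skinfold from the breast.

    Seeded watershed on the inverted distance map of the soft-tissue
    binary image, with the two extruded seed volumes as markers; the
    fold is the catchment of the skinfold marker.
    """
    if not seeds.flags.skinfold or seeds.skinfold_seed is None:
        raise ValueError("skinfold flag is not set")
    soft = soft_tissue_mask(v, cal)
    if removed is not None:
        soft &= ~removed
    dist = ndi.distance_transform_edt(soft)
    markers = np.zeros(v.shape, dtype=np.int32)
    markers[seeds.breast_seed & soft] = 1
    markers[seeds.skinfold_seed & soft] = 2
    labels = watershed(-dist, markers, soft)
    # the fold surface ends at the skin/air HU midpoint (the fold section
    # is wrapped in its own skin)
    rim = v.data < component_threshold(cal, "skin", "air")
    return _close(labels == 2, forbidden=~soft | rim)


def upper_distance_marker(
    dist: np.ndarray,
    region: np.ndarray,
    percentile: float = MUSCLE_MARKER_PERCENTILE,
) -> np.ndarray:
    """Voxels of ``region`` whose distance lies in the upper 40%.

    The marker keeps voxels with distance at or above the given
    percentile (inclusive) of the positive distances within the region;
    on a solid ball this is a concentric ball.
    """
    if not region.any():
        return np.zeros(dist.shape, dtype=bool)
    cutoff = np.percentile(dist[region], percentile)
    return region & (dist >= cutoff)


def segment_muscle(
    v: Volume,
    seeds: SeedSet,
    cal: CalibrationTable,
    removed: np.ndarray | None = None,
) -> np.ndarray:
    """Segment the pectoralis muscle against connected glandular tissue."""
    if not seeds.flags.muscle or seeds.muscle_seed is None:
        raise ValueError("muscle flag is not set")
    thr = component_threshold(cal, "gland", "fat")
    binary = v.data >= thr
    if removed is not None:
        binary &= ~removed
    # keep the thin near-surface shell (the skin) out of the contested
    # binary: it also exceeds this threshold and adjoins the slab, and would
    # otherwise be flooded from the muscle side; the skin stage claims it.
    # Depth is measured against real air (removed components are interior)
    depth = ndi.distance_transform_edt(soft_tissue_mask(v, cal)) * v.spacing_mm
    binary &= depth > 2.0 * v.spacing_mm
    lab, _ = ndi.label(binary, structure=_CUBE3)
    seed_labels = np.unique(lab[seeds.muscle_seed & binary])
    seed_labels = seed_labels[seed_labels > 0]
    if seed_labels.size == 0:
        return np.zeros(v.shape, dtype=bool)
    comp = np.isin(lab, seed_labels)
    dist = ndi.distance_transform_edt(comp)
    # object marker: the upper-40% distance core, anchored to the interior
    # of the detected seed.  The distance rule alone under-constrains the
    # marker once a dense glandular mass dominates the component's distance
    # distribution, so the marker is clipped to the seed (whose smoothed-
    # threshold edge is an unbiased estimate of the muscle/gland interface)
    cand = upper_distance_marker(dist, comp)
    seed_core = ndi.binary_erosion(seeds.muscle_seed, structure=_FACE)
    if not seed_core.any():
        seed_core = seeds.muscle_seed
    obj = (cand & seeds.muscle_seed) | (seed_core & comp)
    if not obj.any():
        obj = seeds.muscle_seed & comp
    # background marker: the breast soft tissue outside the muscle, i.e.
    # everything in the contested component beyond a tight neighborhood of
    # the seed; without it the flood runs away along thin glandular
    # branches that hold no high-distance background cores
    background = comp & ~ndi.binary_dilation(
        seeds.muscle_seed, structure=_CUBE3, iterations=2
    )
    markers = np.zeros(v.shape, dtype=np.int32)
    markers[background] = 2
    markers[obj] = 1
    labels = watershed(-dist, markers, comp)
    return _close(labels == 1, forbidden=~comp)


def locate_nipple(v: Volume, cal: CalibrationTable, min_area: int = 10) -> tuple[int, int, int]:
    """Nipple tip: centroid of the breast surface in the most anterior
    slice containing breast tissue."""
    soft = soft_tissue_mask(v, cal)
    for z in range(v.shape[2]):
        sl = soft[:, :, z]
        if int(sl.sum()) >= min_area:
            cx, cy = ndi.center_of_mass(sl)
            return int(round(cx)), int(round(cy)), z
    raise ValueError("no breast tissue found")


def _nipple_sphere(shape: tuple[int, int, int], tip: tuple[int, int, int], radius_vox: float) -> np.ndarray:
    xs = np.arange(shape[0])[:, None, None]
    ys = np.arange(shape[1])[None, :, None]
    zs = np.arange(shape[2])[None, None, :]
    return (xs - tip[0]) ** 2 + (ys - tip[1]) ** 2 + (zs - tip[2]) ** 2 <= radius_vox**2


def segment_skin(
    v: Volume,
    cal: CalibrationTable,
    nipple_tip: tuple[int, int, int],
    removed: np.ndarray | None = None,
    duct_diameter_mm: float = DUCT_SPHERE_DIAMETER_MM,
) -> np.ndarray:
    """Segment the skin shell, including where gland connects to it.

    Sequence: (1) skin/gland binary image B1 (threshold between the skin
    and fat means, plus the outermost soft-tissue surface layer - the
    anatomical prior that the surface is always skin); (2) join the
    background air to B1, deepening the distance basin under the shell;
    (3) cut the 1.8-cm nipple sphere, disconnecting the milk ducts;
    (4) Euclidean distance map; (5) markers: the air-connected surface
    side versus interior voxels deeper than the median positive
    distance; (6) watershed; (7) subtract air, restore the cut duct
    voxels (surface-shell part to skin, duct core back to the breast).
    """
    if not all(0 <= nipple_tip[i] < v.shape[i] for i in range(3)):
        raise ValueError("nipple_tip outside volume")
    soft = soft_tissue_mask(v, cal)
    if removed is not None:
        soft &= ~removed
    # the outer skin boundary sits at the skin/air HU midpoint, not at the
    # generic soft-tissue floor (which would bias the surface outward)
    air = v.data < component_threshold(cal, "skin", "air")
    if removed is not None:
        air &= ~removed
    soft &= ~air
    # the outermost soft-tissue layers are skin regardless of their blurred
    # HU (partial volume pulls thin skin below the skin/fat midpoint)
    surface = soft & ndi.binary_dilation(air, structure=_FACE, iterations=2)
    b1 = (v.data >= component_threshold(cal, "skin", "fat")) & soft
    b1 |= surface
    b_air = b1 | air
    radius_vox = 0.5 * duct_diameter_mm / v.spacing_mm
    sphere = _nipple_sphere(v.shape, nipple_tip, radius_vox)
    b_cut = b_air & ~sphere
    dist = ndi.distance_transform_edt(b_cut)
    tissue_dist = dist[b_cut & ~air]
    if tissue_dist.size == 0:
        return np.zeros(v.shape, dtype=bool)
    # median positive distance over the tissue voxels (air distances are
    # unboundedly large and would push the marker level into the air)
    positive = tissue_dist[tissue_dist > 0]
    median = float(np.median(positive)) if positive.size else 0.0
    marker_cand = b_cut & (dist > median)
    # glandular tissue may touch the shell away from the nipple, connecting
    # the two marker basins; markers are therefore split voxelwise: the
    # surface side is the air body itself, the interior side the candidate
    # voxels deeper below the outer surface than any plausible skin
    depth = ndi.distance_transform_edt(~air) * v.spacing_mm
    surface_marker = air & b_cut
    interior_marker = marker_cand & ~air & (depth > MAX_SKIN_DEPTH_MM)
    markers = np.zeros(v.shape, dtype=np.int32)
    markers[interior_marker] = 2
    markers[surface_marker] = 1
    labels = watershed(-dist, markers, b_cut)
    skin = (labels == 1) & ~air
    # restore the duct-cut voxels: surface-connected shell -> skin
    cut_tissue = sphere & b1
    if cut_tissue.any():
        if skin.any():
            ring = ndi.binary_dilation(sphere, structure=_CUBE3) & skin
            t_est = float(np.percentile(depth[ring], 90)) if ring.any() else float(np.percentile(depth[skin], 90))
        else:
            t_est = float(np.percentile(depth[cut_tissue], 50))
        skin |= cut_tissue & (depth <= t_est)
    return _close(skin, forbidden=air | (removed if removed is not None else np.zeros(v.shape, bool)))
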