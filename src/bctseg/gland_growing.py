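"""Stage 4: adaptive seeded region growing of the glandular tissue.

The grower starts from the pure-gland seed (voxels at or above the
glandular reference HU), then repeatedly lowers the inclusion threshold
by 2.5% of the fat-to-gland HU interval, each time annexing the voxels
in the new threshold range that are 26-connected to the current region.
The loop stops at the iteration whose two-class volumetric density is
closest to the HU-derived reference density (first increase of the
absolute error after the minimum), so the segmentation-based density
closes on the reference to within half a step.

A probabilistic per-voxel classification follows: each breast voxel's
gland probability is its HU interpolation weight times an exponential
decay in the distance to the nearest pure-gland seed voxel, globally
rescaled so the expected gland volume matches the reference density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .calibration import CalibrationTable
from .core_io import Volume
from .density import density_error_rate

__all__ = ["GrowthState", "gland_seed", "grow_to_density", "probabilistic_labels"]

_CUBE3 = np.ones((3, 3, 3), dtype=bool)

#: threshold decrement per iteration, as a fraction of the gland-fat interval
GROWTH_STEP_FRACTION = 0.025
MAX_GROWTH_ITERATIONS = 60
#: distance scale of the probabilistic weighting (mm)
PROBABILITY_TAU_MM = 5.0


@dataclass
class GrowthState:
    """One iteration of the growth loop (kept in the trace)."""

    iteration: int
    threshold: float
    n_voxels: int
    seg_density: float
    error_rate: float


def gland_seed(
    v: Volume, breast_mask: np.ndarray, cal: CalibrationTable
) -> tuple[np.ndarray, bool]:
    """Pure-gland seed: breast voxels at or above the glandular reference HU.

    Returns ``(seed, fallback)``; on an almost-entirely-fatty breast with
    no voxel at the pure-gland level the growth falls back to the single
    maximal-HU voxel and the fallback flag is set.
    """
    if not breast_mask.any():
        raise ValueError("empty breast mask")
    # partial-volume halos along the mask boundary (skin/muscle mixing into
    # fat) reach gland-level HU; seeds must come from the mask interior
    interior = ndi.binary_erosion(breast_mask, ndi.generate_binary_structure(3, 1))
    if not interior.any():
        interior = breast_mask
    seed = interior & (v.data >= cal.mean("gland"))
    if seed.any():
        return seed, False
    seed = np.zeros(v.shape, dtype=bool)
    flat = np.where(breast_mask.ravel(), v.data.ravel(), -np.inf)
    seed.ravel()[int(np.argmax(flat))] = True
    return seed, True


def grow_to_density(
    v: Volume,
    breast_mask: np.ndarray,
    seed: np.ndarray,
    ref_density: float,
    cal: CalibrationTable,
    step_fraction: float = GROWTH_STEP_FRACTION,
    literal_step: bool = False,
    max_iter: int = MAX_GROWTH_ITERATIONS,
) -> tuple[np.ndarray, list[GrowthState]]:
    """Grow the gland region until the two-class density closes on the reference.

    ``literal_step=True`` switches the decrement to 2.5% of the gland HU
    value itself instead of the fat-to-gland interval (the alternative
    reading of the step rule; far finer steps on HU scales near zero).

    Returns the region of the error-minimizing iteration and the full
    iteration trace.
    """
    if not 0.0 <= ref_density <= 1.0:
        raise ValueError("ref_density must lie in [0, 1]")
    hu_gland, hu_fat = cal.mean("gland"), cal.mean("fat")
    step = abs(step_fraction * hu_gland) if literal_step else step_fraction * (hu_gland - hu_fat)
    if step <= 0:
        raise ValueError("non-positive growth step")
    n_breast = int(breast_mask.sum())

    region = seed & breast_mask
    trace: list[GrowthState] = []

    def record(it: int, thr: float, reg: np.ndarray) -> GrowthState:
        nvox = int(reg.sum())
        d = nvox / n_breast
        state = GrowthState(
            iteration=it,
            threshold=thr,
            n_voxels=nvox,
            seg_density=d,
            error_rate=density_error_rate(d, ref_density),
        )
        trace.append(state)
        return state

    best_state = record(0, float(hu_gland), region)
    best_region = region
    prev_err = abs(best_state.error_rate)
    floor = hu_fat - 4.0 * cal.sd("fat")  # growing below this annexes noise only
    for it in range(1, max_iter + 1):
        thr = hu_gland - it * step
        allowed = breast_mask & (v.data >= thr)
        lab, n = ndi.label(allowed, structure=_CUBE3)
        keep = np.unique(lab[region])
        keep = keep[keep > 0]
        region = np.isin(lab, keep) if keep.size else region
        state = record(it, float(thr), region)
        err = abs(state.error_rate)
        if err < abs(best_state.error_rate):
            best_state, best_region = state, region
        if err > prev_err:  # past the minimum: error started increasing
            break
        prev_err = err
        if thr < floor:
            break
    return best_region, trace


def probabilistic_labels(
    v: Volume,
    gland_region: np.ndarray,
    breast_mask: np.ndarray,
    cal: CalibrationTable,
    ref_density: float,
    seed: np.ndarray | None = None,
    tau_mm: float = PROBABILITY_TAU_MM,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel gland probability field and its 0.5-level binary map.

    p(voxel) = clip((HU - HU_fat) / (HU_gland - HU_fat), 0, 1)
               * exp(-distance_to_seed / tau), rescaled by a global
    factor (bisection) so that sum(p) over the breast mask matches
    ref_density * |mask| within 0.5% - unless even saturated
    probabilities cannot reach the target, in which case the saturated
    field is returned.
    """
    hu_fat, hu_gland = cal.mean("fat"), cal.mean("gland")
    p0 = np.clip((v.data - hu_fat) / (hu_gland - hu_fat), 0.0, 1.0)
    if seed is None:
        seed = breast_mask & (v.data >= hu_gland)
        if not seed.any():
            seed = gland_region
    if seed.any():
        dist = ndi.distance_transform_edt(~seed) * v.spacing_mm
        w = np.exp(-dist / tau_mm)
    else:
        w = np.ones(v.shape)
    base = np.where(breast_mask, p0 * w, 0.0)
    target = ref_density * float(breast_mask.sum())
    if target <= 0:
        p = np.zeros(v.shape, dtype=np.float32)
        return p, p >= 0.5
    def total(scale: float) -> float:
        return float(np.minimum(base * scale, np.where(breast_mask, 1.0, 0.0)).sum())

    lo, hi = 0.0, 1.0
    while total(hi) < target and hi < 1e9:
        hi *= 2.0
    if total(hi) < target:
        scale = hi  # saturated: target unreachable
    else:
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if total(mid) < target:
                lo = mid
            else:
                hi = mid
            if target > 0 and abs(total(hi) - target) / target < 1e-4:
                break
        scale = hi
    p = np.minimum(base * scale, 1.0)
    p[~breast_mask] = 0.0
    return p.astype(np.float32), p >= 0.5
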