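"""End-to-end orchestration of the four-stage segmentation framework.

Order of operations (following the components' HU values, hard to
soft): presence investigation; morphological recovery of ribs and
implant; skinfold separation; pectoralis muscle; skin; HU-derived
reference density on the cleaned breast soft tissue; adaptive gland
region growing with probabilistic classification; density bias audit.
Each identified region is removed from subsequent analysis, and the
skinfold is excluded from the glandularity steps.

The pipeline itself is deterministic: all randomness lives in the
phantom generator.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .calibration import CalibrationTable, DEFAULT_CALIBRATION
from .core_io import COMPONENT_CODES, LabelMap, Volume
from .density import DensityReport, density_error_rate, hu_derived_density
from .detection import SeedSet, detect_all, soft_tissue_mask
from .gland_growing import (
    GROWTH_STEP_FRACTION,
    MAX_GROWTH_ITERATIONS,
    gland_seed,
    grow_to_density,
    probabilistic_labels,
)
from .metrics import bias_audit
from .watershed_seg import (
    DUCT_SPHERE_DIAMETER_MM,
    locate_nipple,
    segment_hard,
    segment_muscle,
    segment_skin,
    segment_skinfold,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    calibration: CalibrationTable = field(default_factory=lambda: DEFAULT_CALIBRATION)
    duct_diameter_mm: float = DUCT_SPHERE_DIAMETER_MM
    growth_step_fraction: float = GROWTH_STEP_FRACTION
    literal_growth_step: bool = False
    max_growth_iterations: int = MAX_GROWTH_ITERATIONS
    compute_bias_audit: bool = True
    compute_probability_field: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.duct_diameter_mm <= 0 or self.growth_step_fraction <= 0:
            raise ValueError("pipeline parameters must be positive")
        if self.max_growth_iterations < 1:
            raise ValueError("iteration cap must be >= 1")


@dataclass
class PipelineResult:
    labels: LabelMap
    report: DensityReport
    seeds: SeedSet
    probability_field: np.ndarray | None
    log: list[str]


def run_pipeline(v: Volume, cfg: PipelineConfig | None = None) -> PipelineResult:
    """Run detection, segmentation, density estimation and gland growing."""
    cfg = cfg if cfg is not None else PipelineConfig()
    cal = cfg.calibration
    log: list[str] = []
    flags: list[str] = []
    t_start = time.perf_counter()

    def stage(name: str, t0: float) -> None:
        log.append(f"{name}: {time.perf_counter() - t0:.2f} s")

    labels = np.zeros(v.shape, dtype=np.uint8)
    removed = np.zeros(v.shape, dtype=bool)

    t0 = time.perf_counter()
    try:
        seeds = detect_all(v, cal)
    except Exception as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(f"stage 'detect': {exc}") from exc
    stage("detect", t0)

    # hard components: morphological recovery from the eroded seeds
    t0 = time.perf_counter()
    if seeds.flags.rib or seeds.flags.implant:
        from .detection import component_threshold

        med = ndi.median_filter(v.data, size=3, mode="reflect")
        if seeds.flags.implant:
            implant = segment_hard(
                seeds.implant_seed, med >= component_threshold(cal, "implant", "gland")
            )
            labels[implant] = COMPONENT_CODES["implant"]
            removed |= implant
        if seeds.flags.rib:
            # ribs sit in muscle; their extent ends at the rib/muscle midpoint
            rib = segment_hard(
                seeds.rib_seed,
                (med >= component_threshold(cal, "rib", "muscle")) & ~removed,
            )
            labels[rib] = COMPONENT_CODES["rib"]
            removed |= rib
        # exclude the partial-volume halo around hard components from all
        # later analysis: its mixed HU mimics glandular tissue
        hard = (labels == COMPONENT_CODES["rib"]) | (labels == COMPONENT_CODES["implant"])
        removed |= ndi.binary_dilation(hard, structure=np.ones((3, 3, 3), bool), iterations=2)
    stage("hard", t0)

    t0 = time.perf_counter()
    if seeds.flags.skinfold:
        fold = segment_skinfold(v, seeds, cal, removed=removed)
        fold &= ~removed
        labels[fold] = COMPONENT_CODES["skinfold"]
        removed |= fold
    stage("skinfold", t0)

    t0 = time.perf_counter()
    if seeds.flags.muscle:
        muscle = segment_muscle(v, seeds, cal, removed=removed)
        muscle &= ~removed
        labels[muscle] = COMPONENT_CODES["muscle"]
        removed |= muscle
    stage("muscle", t0)

    t0 = time.perf_counter()
    nipple = locate_nipple(v, cal)
    skin = segment_skin(
        v, cal, nipple, removed=removed, duct_diameter_mm=cfg.duct_diameter_mm
    )
    skin &= ~removed
    labels[skin] = COMPONENT_CODES["skin"]
    removed |= skin
    stage("skin", t0)

    # cleaned breast soft tissue: largest remaining soft component
    t0 = time.perf_counter()
    breast_mask = soft_tissue_mask(v, cal) & ~removed
    lab, n = ndi.label(breast_mask, structure=np.ones((3, 3, 3), bool))
    if n > 1:
        counts = np.bincount(lab.ravel())
        counts[0] = 0
        breast_mask = lab == int(np.argmax(counts))
    if not breast_mask.any():
        raise RuntimeError("stage 'density': no breast soft tissue remains")
    # estimate density on the mask core: the boundary ring mixes skin and
    # air signal into fat and would inflate the HU-derived reference
    core_mask = ndi.binary_erosion(
        breast_mask, ndi.generate_binary_structure(3, 1), iterations=2
    )
    if not core_mask.any():
        core_mask = breast_mask
    ref_density = hu_derived_density(v, core_mask, cal)
    stage("density", t0)

    t0 = time.perf_counter()
    seed, fallback = gland_seed(v, core_mask, cal)
    if fallback:
        flags.append("gland seed fallback: no voxel at the pure-gland level")
    gland, trace = grow_to_density(
        v,
        core_mask,
        seed,
        ref_density,
        cal,
        step_fraction=cfg.growth_step_fraction,
        literal_step=cfg.literal_growth_step,
        max_iter=cfg.max_growth_iterations,
    )
    if trace and trace[-1].iteration >= cfg.max_growth_iterations:
        flags.append("growth iteration cap reached; best-so-far returned")
    prob = None
    if cfg.compute_probability_field:
        prob, _ = probabilistic_labels(
            v, gland, core_mask, cal, ref_density, seed=seed if not fallback else None
        )
    # densities are bookkept on the core, but the final map must classify
    # the excluded boundary ring as well: extend the stopping threshold to
    # the full breast mask, keeping only voxels connected to the grown gland
    best = min(trace, key=lambda s: abs(s.error_rate))
    allowed = breast_mask & (v.data >= best.threshold)
    ext_lab, _ = ndi.label(allowed, structure=np.ones((3, 3, 3), bool))
    keep = np.unique(ext_lab[gland])
    keep = keep[keep > 0]
    gland_full = (np.isin(ext_lab, keep) | gland) if keep.size else gland
    labels[breast_mask & ~gland_full] = COMPONENT_CODES["fat"]
    labels[gland_full] = COMPONENT_CODES["gland"]
    stage("gland", t0)

    # mop-up: tissue voxels above the skin/air HU midpoint left unassigned
    # (blurred component rims, stray fragments) inherit the nearest label;
    # voxels below the midpoint are air-dominated mixtures and stay air
    from .detection import component_threshold as _ct

    orphan = (
        soft_tissue_mask(v, cal)
        & (labels == 0)
        & (v.data >= _ct(cal, "skin", "air"))
    )
    if orphan.any():
        # hard components do not donate: their excluded partial-volume halo
        # is soft tissue, not bone or silicone
        donors = labels.copy()
        donors[(donors == COMPONENT_CODES["rib"]) | (donors == COMPONENT_CODES["implant"])] = 0
        _, idx = ndi.distance_transform_edt(donors == 0, return_indices=True)
        labels[orphan] = donors[idx[0][orphan], idx[1][orphan], idx[2][orphan]]

    label_map = LabelMap(labels=labels, spacing_mm=v.spacing_mm)
    seg_density = float(gland.sum()) / float(core_mask.sum())
    volumes = {
        name: label_map.volume_ml(name)
        for name in COMPONENT_CODES
        if name != "air" and label_map.mask(name).any()
    }
    audit = bias_audit(v, label_map, cal) if cfg.compute_bias_audit else None
    report = DensityReport(
        hu_derived_density=ref_density,
        seg_based_density=seg_density,
        error_rate=density_error_rate(seg_density, ref_density),
        component_volumes_ml=volumes,
        bias_audit=audit,
        flags=flags,
    )
    log.append(f"total: {time.perf_counter() - t_start:.2f} s")
    return PipelineResult(
        labels=label_map, report=report, seeds=seeds, probability_field=prob, log=log
    )
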