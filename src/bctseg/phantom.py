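"""Synthetic pendant-breast CT phantoms with known ground truth.

No patient breast-CT data is publicly available, so every stage of the
segmentation framework is exercised on phantoms that emulate the
geometry and signal structure the method assumes:

* a pendant half-ellipsoid breast hanging in air along the z (depth)
  axis, nipple at low z, chest wall at high z;
* a skin shell whose thickness varies smoothly over the surface;
* a branching fibroglandular tree rooted retro-areolarly, touching the
  skin at the nipple (the duct connectivity that motivates the 1.8-cm
  nipple-sphere cut in the skin stage) and reaching the chest wall
  (the gland/muscle contact the muscle markers address);
* optionally a pectoralis-muscle slab at the chest wall, rib rods
  embedded in it, a silicone implant, and a fat-like skinfold body
  attached to the posterior breast surface;
* per-tissue Gaussian HU texture, Gaussian PSF blur (partial-volume
  mixing) and additive detector noise.

Ground truth is the crisp pre-blur label map plus the exact glandular
fraction of the breast soft tissue (gland / (gland + fat)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .calibration import CalibrationTable, DEFAULT_CALIBRATION
from .core_io import COMPONENT_CODES, ComponentFlags, LabelMap, Volume

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "phantom_cohort"]


@dataclass
class PhantomSpec:
    """Parameters of one synthetic breast phantom.

    Defaults reproduce the study conditions of the evaluation cohort:
    128 x 128 x 160 grid at 0.6 mm isotropic spacing, skin thickness
    varying within 1-3 mm, PSF sigma 0.6 mm, additive noise 15 HU.
    """

    shape: tuple[int, int, int] = (128, 128, 160)
    spacing_mm: float = 0.6
    breast_radius_mm: float = 27.0
    breast_length_mm: float = 72.0
    skin_thickness_mm: tuple[float, float] = (1.0, 3.0)
    glandular_fraction: float = 0.3
    include_muscle: bool = False
    include_skinfold: bool = False
    include_ribs: bool = False
    include_implant: bool = False
    n_gland_branches: int = 12
    muscle_thickness_mm: float = 9.0
    fold_radius_mm: float = 5.0
    fold_length_mm: float = 26.0
    implant_radius_mm: float = 15.0
    rib_radius_mm: float = 2.4
    psf_sigma_mm: float = 0.6
    noise_sd_hu: float = 15.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.glandular_fraction <= 1.0:
            raise ValueError("glandular_fraction must lie in [0, 1]")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        tmin, tmax = self.skin_thickness_mm
        if tmin <= 0 or tmax < tmin:
            raise ValueError("skin thickness range must be positive and ordered")
        if self.include_ribs and not self.include_muscle:
            raise ValueError("ribs are embedded in the chest wall; enable include_muscle")


@dataclass
class PhantomTruth:
    """Crisp pre-blur labels, exact glandularity, and the nipple-tip voxel."""

    labels: LabelMap
    true_density: float
    nipple_tip: tuple[int, int, int]
    flags: ComponentFlags = field(default_factory=ComponentFlags)


def _draw_segment(skel: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> None:
    """Mark skeleton voxels along the segment p0 -> p1 (dense sampling)."""
    length = float(np.linalg.norm(p1 - p0))
    n = max(int(np.ceil(length * 2)), 2)
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = np.round(p0[None, :] * (1 - t) + p1[None, :] * t).astype(int)
    pts = np.clip(pts, 0, np.array(skel.shape) - 1)
    skel[pts[:, 0], pts[:, 1], pts[:, 2]] = True


def _gland_skeleton(
    spec: PhantomSpec,
    rng: np.random.Generator,
    center: tuple[float, float],
    z_tip: int,
    z_end: int,
) -> np.ndarray:
    """Random branching ductal tree: trunk nipple -> chest wall plus side branches."""
    cx, cy = center
    skel = np.zeros(spec.shape, dtype=bool)
    # trunk: from the nipple tip (touching the skin) to the chest wall, with
    # mild lateral jitter so the tree is not a straight rod
    n_knots = 6
    zs = np.linspace(z_tip, z_end, n_knots)
    jitter = rng.normal(0.0, 2.0, size=(n_knots, 2))
    jitter[0] = 0.0
    knots = np.column_stack([cx + jitter[:, 0], cy + jitter[:, 1], zs])
    for a, b in zip(knots[:-1], knots[1:]):
        _draw_segment(skel, a, b)
    trunk_len = z_end - z_tip
    r_vox = spec.breast_radius_mm / spec.spacing_mm
    for _ in range(spec.n_gland_branches):
        t0 = rng.uniform(0.2, 0.9)
        start = np.array([cx, cy, z_tip + t0 * trunk_len])
        theta = rng.uniform(0, 2 * np.pi)
        # outward+posterior bias; branch length scales with local breast radius
        local_r = r_vox * np.sqrt(max(1.0 - (1.0 - t0) ** 2, 0.05))
        blen = rng.uniform(0.3, 0.75) * local_r
        direction = np.array(
            [np.cos(theta), np.sin(theta), rng.uniform(0.2, 1.2)]
        )
        direction /= np.linalg.norm(direction)
        end = start + direction * blen
        end[2] = min(end[2], z_end)
        _draw_segment(skel, start, end)
        # secondary branchlet
        if rng.uniform() < 0.6:
            theta2 = theta + rng.uniform(-1.2, 1.2)
            d2 = np.array([np.cos(theta2), np.sin(theta2), rng.uniform(0.0, 1.0)])
            d2 /= np.linalg.norm(d2)
            end2 = end + d2 * blen * 0.6
            end2[2] = min(end2[2], z_end)
            _draw_segment(skel, end, end2)
    return skel


def generate_phantom(
    spec: PhantomSpec, cal: CalibrationTable | None = None
) -> tuple[Volume, PhantomTruth]:
    """Generate one (Volume, PhantomTruth) pair.

    Deterministic for a fixed ``spec.rng_seed``.  The glandular tree is
    thickened around its skeleton exactly until the gland voxel count
    matches the requested glandular fraction of the breast soft tissue,
    so ``true_density`` tracks ``spec.glandular_fraction`` to within the
    discretization of the grid.
    """
    cal = cal if cal is not None else DEFAULT_CALIBRATION
    rng = np.random.default_rng(spec.rng_seed)
    nx, ny, nz = spec.shape
    sp = spec.spacing_mm
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    r_vox = spec.breast_radius_mm / sp
    l_vox = spec.breast_length_mm / sp

    z_chest = nz - 1
    muscle_vox = int(round(spec.muscle_thickness_mm / sp)) if spec.include_muscle else 0
    z_tip = int(round(z_chest - l_vox))
    if z_tip < 2 or r_vox >= min(cx, cy):
        raise ValueError("breast geometry does not fit the grid")

    xs = np.arange(nx)[:, None, None]
    ys = np.arange(ny)[None, :, None]
    zs = np.arange(nz)[None, None, :]
    rho2 = (xs - cx) ** 2 + (ys - cy) ** 2

    # pendant half-ellipsoid: radius shrinks from the chest-wall end of the
    # field of view (the most posterior slice) to the nipple tip
    axial = (z_chest - zs) / l_vox
    inside_z = (zs <= z_chest) & (axial <= 1.0)
    breast = inside_z & (rho2 / r_vox**2 + axial**2 <= 1.0)

    labels = np.zeros(spec.shape, dtype=np.uint8)

    # ---- skin shell of smoothly varying thickness -----------------------
    # (the posterior field-of-view cut carries no shell: the EDT sees no
    # background beyond the last slice, as in a real truncated scan)
    tmin, tmax = spec.skin_thickness_mm
    d_in = ndi.distance_transform_edt(breast) * sp
    phi1, phi2 = rng.uniform(0, 2 * np.pi, size=2)
    theta_xy = np.arctan2(ys - cy, xs - cx)
    modulation = 0.5 * (
        1.0
        + np.sin(2.0 * np.pi * (z_chest - zs) / l_vox + phi1) * np.sin(theta_xy + phi2)
    )
    thickness = tmin + (tmax - tmin) * modulation
    skin = breast & (d_in <= thickness)
    interior = breast & ~skin

    # ---- pectoralis dome at the chest wall, ribs embedded ---------------
    muscle = np.zeros(spec.shape, dtype=bool)
    ribs = np.zeros(spec.shape, dtype=bool)
    if spec.include_muscle:
        am = bm = 0.8 * r_vox
        cm = float(muscle_vox)
        muscle = (
            ((xs - cx) / am) ** 2
            + ((ys - cy) / bm) ** 2
            + ((zs - z_chest) / cm) ** 2
            <= 1.0
        ) & (zs <= z_chest)
        muscle &= interior
        if spec.include_ribs:
            rib_r = spec.rib_radius_mm / sp
            zr = z_chest - 0.45 * cm
            for frac in (-0.4, 0.0, 0.4):
                yr = cy + frac * bm
                rod = ((ys - yr) ** 2 + (zs - zr) ** 2 <= rib_r**2) & (
                    np.abs(xs - cx) <= 0.5 * am
                )
                ribs |= rod & muscle
        muscle &= ~ribs

    # ---- skinfold: fat-like body attached to the posterior surface,
    # tilting away from the breast toward the anterior end so the slice
    # scan finds a slice where the two bodies separate ---------------------
    fold = np.zeros(spec.shape, dtype=bool)
    if spec.include_skinfold:
        fr = spec.fold_radius_mm / sp
        fx0 = cx + r_vox + fr - 3.0  # overlaps the breast edge by ~3 voxels
        z0 = nz - 1 - int(round(spec.fold_length_mm / sp))
        fx = fx0 + 0.12 * (nz - 1 - zs)
        if fx0 + fr >= nx - 1:
            raise ValueError("skinfold does not fit the grid")
        fold = ((xs - fx) ** 2 + (ys - cy) ** 2 <= fr**2) & (zs >= z0)
        fold &= ~breast

    # ---- implant --------------------------------------------------------
    implant = np.zeros(spec.shape, dtype=bool)
    if spec.include_implant:
        ir = spec.implant_radius_mm / sp
        zi = z_chest - muscle_vox - 0.25 * l_vox
        implant = (rho2 / ir**2 + ((zs - zi) / (0.6 * ir)) ** 2) <= 1.0
        implant &= interior & ~muscle & ~ribs

    # ---- glandular tree thickened to the target fraction ----------------
    soft = interior & ~implant & ~muscle & ~ribs
    n_soft = int(np.count_nonzero(soft))
    gf = spec.glandular_fraction
    gland = np.zeros(spec.shape, dtype=bool)
    if n_soft and gf > 0:
        if gf >= 1.0:
            gland = soft.copy()
        else:
            # the ductal tree ends at the anterior face of the pectoralis
            # dome (gland abuts, but does not wrap, the muscle)
            z_gland_end = z_chest - muscle_vox - 2 if spec.include_muscle else z_chest
            skel = _gland_skeleton(spec, rng, (cx, cy), z_tip, z_gland_end)
            d_skel = ndi.distance_transform_edt(~skel)
            d_soft = d_skel[soft]
            k = int(round(gf * n_soft))
            if k > 0:
                cutoff = np.partition(d_soft, k - 1)[k - 1]
                gland = soft & (d_skel <= cutoff)
    fat = soft & ~gland

    labels[fat] = COMPONENT_CODES["fat"]
    labels[gland] = COMPONENT_CODES["gland"]
    labels[skin] = COMPONENT_CODES["skin"]
    labels[muscle] = COMPONENT_CODES["muscle"]
    labels[fold] = COMPONENT_CODES["skinfold"]
    labels[ribs] = COMPONENT_CODES["rib"]
    labels[implant] = COMPONENT_CODES["implant"]

    # the fold section is thoracic/abdominal wall tissue: a fatty core
    # wrapped in its own skin.  The whole section carries the skinfold
    # label (it is excluded wholesale from the density analysis), but the
    # HU material of its outer shell is skin.
    material = labels.copy()
    if fold.any():
        fold_depth = ndi.distance_transform_edt(fold) * sp
        cover = fold & (fold_depth <= 0.5 * (tmin + tmax))
        material[cover] = COMPONENT_CODES["skin"]

    n_gland = int(np.count_nonzero(gland))
    n_fat = int(np.count_nonzero(fat))
    true_density = n_gland / max(n_gland + n_fat, 1)

    # ---- HU synthesis: tissue texture -> PSF blur -> detector noise -----
    mean_by_code = np.zeros(8, dtype=np.float64)
    sd_by_code = np.zeros(8, dtype=np.float64)
    for name, code in COMPONENT_CODES.items():
        comp = name if cal.has(name) else "fat"
        mean_by_code[code] = cal.mean("air") if name == "air" else cal.mean(comp)
        sd_by_code[code] = cal.sd("air") if name == "air" else cal.sd(comp)
    hu = mean_by_code[material] + sd_by_code[material] * rng.standard_normal(spec.shape)
    if spec.psf_sigma_mm > 0:
        hu = ndi.gaussian_filter(hu, sigma=spec.psf_sigma_mm / sp)
    if spec.noise_sd_hu > 0:
        hu = hu + rng.normal(0.0, spec.noise_sd_hu, size=spec.shape)

    # nipple tip: centroid of the most anterior occupied slice
    z_front = int(np.nonzero(breast.any(axis=(0, 1)))[0].min())
    tip_coords = np.argwhere(breast[:, :, z_front])
    tip_x, tip_y = np.round(tip_coords.mean(axis=0)).astype(int)

    volume = Volume(data=hu.astype(np.float32), spacing_mm=sp)
    truth = PhantomTruth(
        labels=LabelMap(labels=labels, spacing_mm=sp),
        true_density=float(true_density),
        nipple_tip=(int(tip_x), int(tip_y), z_front),
        flags=ComponentFlags(
            muscle=spec.include_muscle,
            skinfold=spec.include_skinfold,
            rib=spec.include_ribs,
            implant=spec.include_implant,
        ),
    )
    return volume, truth


#: glandular fractions of the four mammographic density classes
#: (almost entirely fatty / scattered / heterogeneously dense / extremely dense)
DENSITY_CLASSES = (0.05, 0.2, 0.5, 0.8)


def phantom_cohort(
    n: int,
    class_mix: dict[int, int] | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> list[tuple[Volume, PhantomTruth]]:
    """Reproducible cohort spanning the four density classes and component mixes.

    ``class_mix`` optionally maps density-class index (0-3) to a count.
    Optional components cycle deterministically: the pectoralis dome on
    even cohort indices (with ribs on every fourth), the skinfold on odd
    indices, and an implant on every fourth index starting at 2.  By
    default the even (muscle) phantoms cycle down through the density
    classes while the fold-bearing phantoms stay in the two fatty
    classes - skinfolds of thoracic/abdominal wall tissue are typical of
    larger, predominantly fatty breasts - so any four consecutive
    phantoms still span all four classes.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    base = base_spec if base_spec is not None else PhantomSpec()
    classes: list[int] = []
    if class_mix is not None:
        for cls, count in sorted(class_mix.items()):
            classes.extend([cls] * count)
        if len(classes) != n:
            raise ValueError("class_mix counts must sum to n")
    else:
        classes = [
            [3, 2, 1, 0][(i // 2) % 4] if i % 2 == 0 else [0, 1][(i // 2) % 2]
            for i in range(n)
        ]

    cohort = []
    for i in range(n):
        spec = replace(
            base,
            glandular_fraction=DENSITY_CLASSES[classes[i]],
            include_muscle=(i % 2 == 0),
            include_ribs=(i % 4 == 0),
            include_skinfold=(i % 2 == 1),
            include_implant=(i % 4 == 2),
            rng_seed=int(seed) * 100 + i + 1,
        )
        cohort.append(generate_phantom(spec))
    return cohort
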