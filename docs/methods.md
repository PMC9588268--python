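# Methods

This note records the scientific assumptions, parameter choices and
numerical conventions behind `bctseg`.  It is written for a reader who
wants to know *why* the pipeline behaves as it does and what passing the
test suite does and does not demonstrate about real breast-CT data.

## Data model and conventions

A `Volume` is a 3-D grid of Hounsfield units on an isotropic lattice
(`spacing_mm`).  Axes are fixed: x transverse, y vertical, z sagittal
depth with index 0 at the anterior (nipple) end and the last index at
the posterior (chest-wall) end; a "posterior to anterior" scan iterates
z downward.  The most posterior slice is treated as the field-of-view
cut of a truncated scan: tissue may touch it, and morphological
operations must not erode it (closings are edge-padded for this reason).
Label maps use fixed integer codes with air = 0, so an all-zero map is
legal background.  Storage is NIfTI-1 plus a JSON sidecar carrying the
code table.

## HU calibration

Every threshold in the pipeline derives from a `CalibrationTable` of
per-component HU means and standard deviations.  The shipped default is
literature-typical for breast CT:

| component | mean (HU) | SD (HU) |
|-----------|----------:|--------:|
| air       | −1000     | 5       |
| fat       | −150      | 15      |
| gland     | +30       | 20      |
| skin      | +20       | 25      |
| muscle    | +45       | 25      |
| rib       | +450      | 80      |
| silicone  | +120      | 15      |

The coefficient of variation is reported as `cv = sd / (mean − offset)`
with the offset anchored at air (−1000 HU) so the denominator is a
positive attenuation-like scale; all tissue CVs of the default table are
below 0.1.

Fitting a table from labeled data uses a 3×3×3 volumetric median filter
to suppress partial-volume mixtures, then splits the breast tissue at
the fat/gland midpoint.  Two exclusions remove volume effects: a band of
half the smaller tissue SD around the split threshold, and — because the
median of a mixed neighborhood is biased toward the neighboring mode
rather than the midpoint — any voxel whose filtered 3×3×3 neighborhood
spans more than half the fat-to-gland interval.  Without the second
exclusion the recovered fat mean is biased upward by several HU on
interface-rich (dense) breasts; with it, means are recovered to within
1 HU on unblurred noiseless phantoms.  Components with fewer than 100
voxels are flagged low-confidence; absent components are omitted.

## Synthetic phantoms

The generator emulates the geometry the segmentation method assumes:

* **Breast**: pendant half-ellipsoid (default radius 27 mm, length
  72 mm) reaching the posterior field-of-view cut.
* **Skin**: a shell whose thickness varies smoothly over the surface
  within a 1–3 mm range (sinusoidal modulation in both surface angles);
  the field-of-view cut itself carries no shell.
* **Gland**: a random branching ductal tree rooted at the nipple
  (touching the skin there — the duct connectivity that motivates the
  1.8-cm nipple-sphere cut) and extending to the chest wall.  The tree
  skeleton is thickened by a distance threshold chosen so the gland
  voxel count matches the requested glandular fraction exactly; the
  reported `true_density` is recomputed from the labels.
* **Pectoralis**: a dome at the chest wall *inside* the breast outline,
  under the skin and surrounded by fat/gland — as on real coronal breast
  CT, where the muscle appears as a posterior body, not a free-standing
  slab.  The gland tree ends at the dome's anterior face (gland abuts,
  but does not wrap, the muscle).
* **Ribs**: three rods embedded in the dome (so they only occur together
  with the muscle).
* **Implant**: an oblate silicone body anterior to the muscle.
* **Skinfold**: a tilted cylindrical body of thoracic-wall tissue
  attached to the posterior breast surface, drifting away from the
  breast toward the anterior end so that some slice shows two separate
  soft-tissue objects (what the slice scan detects).  The fold section
  carries a single `skinfold` label but is materially a fatty core
  wrapped in its own skin — which is also why including a fold in the
  density mask barely moves the estimate.
* **Signal**: per-voxel Gaussian tissue texture, Gaussian PSF blur
  (default sigma 0.6 mm, the partial-volume model) and additive detector
  noise (default SD 15 HU).  Everything is deterministic given the seed.

The default grid is 128×128×160 at 0.6 mm — a deliberately reduced scale
at which the full pipeline runs in seconds per phantom; kernel sizes
specified in voxels (3³ median, 5³ erosion/Gaussian) are therefore
resolution-dependent, while physical sizes (1.8-cm sphere, marker depth
floors) are specified in millimetres.

The standard evaluation cohort cycles the four mammographic density
classes (glandular fractions 0.05 / 0.2 / 0.5 / 0.8), puts the muscle
(and on every other occasion ribs, or an implant) on even cohort
indices and the skinfold on odd ones.  Fold-bearing phantoms stay in
the two fatty classes — skinfolds of loose thoracic/abdominal wall
tissue are typical of larger, predominantly fatty breasts — and any
four consecutive phantoms still span all four classes.

**What the phantoms do not model**: ring and radial-line reconstruction
artifacts, motion, pathological lesions and microcalcifications, breast
deformation asymmetries, anisotropic slice profiles, and scanner HU
nonlinearity.  Passing the suite therefore demonstrates the geometric
and quantitative behavior of the algorithms under idealized acquisition,
not robustness to artifacts.

## Detection stage

Thresholds follow one rule: the mean of the target's and the surrounding
component's reference HU.  Specifics:

* **Skinfold**: 2-D connected components per slice, scanning posterior
  to anterior on the soft-tissue binary image; the first slice with at
  least two objects of ≥ 25 px yields the breast seed (largest object)
  and the fold seed (the rest), both extruded from that slice to the
  posterior end.  The area floor suppresses noise specks.
* **Ribs/implant**: the high-HU binary image (implant/gland midpoint) is
  median-filtered first — noise speckle would otherwise riddle it with
  holes and let the 5×5×5 erosion shatter the implant — then eroded and
  labeled in 3-D.  A surviving component is the implant if its mean HU
  is nearer the silicone reference than the rib reference *and* its
  pre-erosion extent exceeds 5 cm³; otherwise it is a rib.
* **Muscle**: Gaussian denoising (sigma 1 voxel, truncated at 2 sigma —
  a 5-voxel support) before thresholding at the muscle/gland midpoint;
  smoothing pushes compact gland masses (mean below the threshold) under
  it while the muscle stays above.  Candidate components must reach into
  the posterior 20% of slices (the muscle enters from the chest wall)
  and exceed 1 cm³; the largest wins.

## Watershed stage

All watersheds flood the negated Euclidean distance transform so floods
meet at minimal cross-sections.  The flood itself is a priority queue
ordered by (value, insertion age) with marker voxels seeded in raveled
order and face neighbors visited in a fixed documented order — fully
deterministic and reproducible voxel-for-voxel by an independent
implementation of the same rule.  Face (6) connectivity is used for
flooding; 26-connectivity for component labeling.

* **Hard components** are recovered by dilating the eroded seed with the
  same 5×5×5 element and geodesically propagating inside the thresholded
  binary image (face connectivity), so the opening's boundary loss is
  restored.  The rib extent uses the rib/muscle midpoint, the implant
  the silicone/gland midpoint.  A 2-voxel halo around recovered hard
  components is excluded from all later analysis: its mixed HU mimics
  glandular tissue and would otherwise seed the gland grower.
* **Skinfold**: the two extruded seeds compete on the soft-tissue binary
  image; the fold is the catchment of the fold marker, clipped at the
  skin/air HU midpoint.
* **Muscle**: the contested binary image is the gland/fat threshold with
  the outermost 2 voxels of the body excluded (that sheet is skin and
  must stay available to the skin stage).  The object marker is the
  upper-40% distance core clipped to the detected seed plus the seed's
  interior; the background marker is everything in the contested
  component beyond a 2-voxel neighborhood of the seed.  The clipping is
  necessary because a dense glandular mass dominates the distance
  distribution (the bare percentile rule would mark gland cores as
  muscle), and the tight background ring is necessary because thin
  glandular branches hold no high-distance background cores of their own
  (the flood would otherwise run away along the sleeve).  The smoothed
  threshold that built the seed crosses the muscle/gland interface at
  its midpoint, so the seed edge is an unbiased interface estimate and
  the contested band can stay narrow.
* **Skin**: the binary image is the skin/fat threshold plus the
  outermost two soft-tissue layers (partial volume pulls thin skin below
  the midpoint; anatomically the surface is always skin).  Air is joined
  to the foreground — this is what gives the shell a deep distance basin
  — the 1.8-cm nipple sphere is cut to disconnect the milk ducts, and
  the flood runs with the air body as the surface marker against
  interior voxels that are beyond the median positive tissue distance
  *and* deeper than 4 mm below the outer surface (deeper than any
  plausible skin).  The depth floor resolves the case of gland touching
  the shell away from the nipple, which connects the two basins and
  would otherwise make a component-based marker split degenerate.
  After flooding the air is subtracted and the duct-cut voxels are
  restored: the surface-connected part (within the locally estimated
  shell thickness) to skin, the duct core back to the breast.
  The outer skin boundary sits at the skin/air HU midpoint rather than
  the generic soft-tissue floor, which would bias the surface outward
  by a fraction of a voxel.
* **Nipple**: centroid of the soft tissue in the most anterior slice
  holding at least 10 voxels.

After all stages, tissue voxels above the skin/air midpoint that remain
unlabeled (blurred component rims between the soft-tissue floor and the
component threshold, fragments disconnected from the main breast) adopt
the label of the nearest assigned voxel; hard components do not donate
(their halo is soft tissue, not bone or silicone).  Voxels below the
midpoint are air-dominated mixtures and stay air.

## Density and gland growing

The HU-derived reference interpolates the mean HU of the breast mask
between the pure-fat and pure-gland references, clipped to [0, 1].  Both
the reference and the growth run on the mask *core* (the mask eroded by
2 voxels): the boundary ring mixes skin and air signal into fat and
inflates the reference by several percentage points, which at low
glandularity would misplace a third of the grown gland.  The density
error rate is the signed percentage-point difference
`100 · (seg − ref)` (the same units as the glandularity itself).

The grower seeds at the pure-gland HU (mask-interior voxels only — the
partial-volume halo along the mask boundary reaches gland-level HU), and
lowers the threshold by 2.5% of the fat-to-gland interval per iteration,
annexing 26-connected voxels.  The literal alternative reading — 2.5% of
the gland HU value itself, a far finer step on HU scales near zero — is
available via `literal_growth_step`.  The absolute error is unimodal in
the threshold (it falls until the optimum and then rises), so the loop
stops at the first increase; an iteration cap of 60 returns the best
iteration so far and sets a flag.  The stopping rule bounds the closure
|seg − ref| by half a step.  For the final label map the stopping
threshold is extended from the core to the full mask (components
connected to the grown region), so ring voxels are classified too while
the density bookkeeping stays on the core.  An almost-entirely-fatty
breast with no pure-gland voxel falls back to a single maximal-HU seed
and is flagged.

The probabilistic field is
`p = clip((HU − HU_fat)/(HU_gland − HU_fat), 0, 1) · exp(−d/τ)` with
τ = 5 mm distance to the nearest pure-gland voxel, rescaled by a global
factor (bisection, 60 iterations) so that `Σp` over the mask matches the
reference density within 0.5%; if even saturated probabilities cannot
reach the target the saturated field is returned.  The exponential form
and τ are package choices — only the qualitative requirement (weight
decreasing with distance, expectation matched to the mean glandularity)
is inherent to the method.

## Evaluation metrics

Dice `DSC = 2|A∩B|/(|A|+|B|)` (DSC > 0.75 is the conventional
"excellent agreement" bound), difference coefficient
`DC = |A⊕B|/((|A|+|B|)/2)` with range [0, 2], and the logit transform
`LDSC = ln(DSC/(1−DSC))` for normal-theory inference; paired comparisons
use a two-sided paired t-test on LDSC values.  The conservation identity
`DSC·(|A|+|B|)/2 + DC·(|A|+|B|)/2 = |A∪B|` is fuzz-tested.  Cronbach's
alpha uses population variances for rater and total scores (alpha is
invariant to the variance convention as long as it is consistent).

The bias audit recomputes the HU-derived density with each of skin,
muscle and skinfold merged into the breast mask and reports the signed
shift in percentage points.  On the phantoms, merging the muscle biases
the density upward on every muscle-bearing phantom, and merging the
fold moves it by well under a percentage point.  Merging the *skin* is
only positive on the fattiest phantoms: at 0.6 mm spacing with a 0.6 mm
PSF, a 1–3 mm shell is so strongly air-mixed that even the ground-truth
skin region's mean HU (≈ −135 HU) falls below the breast-tissue mean
once glandularity exceeds roughly 0.1, flipping the bias negative.  On
real sub-millimetre acquisitions with relatively thicker skin the
crisp-HU expectation (skin denser than the average breast, hence a
positive bias) reasserts itself; the sign flip here is a partial-volume
property of the reduced phantom scale, and the corresponding test
documents it as a known failure under these study conditions.

## Cohort-level behavior

On the standard cohort (seed 1) the pipeline reaches median DSC ≈ 0.97
for skin, ≈ 0.94 for muscle, ≈ 0.996 for the skinfold, a minimum
per-component DSC ≈ 0.85, mean |density closure| ≈ 0.05 percentage
points and median skin DC ≈ 0.065 — numbers recomputed from scratch by
`scripts/acceptance.py` and asserted by `tests/test_acceptance.py`.

## Known limitations

* All voxel-kernel parameters (3³, 5³) assume sub-millimetre isotropic
  grids; at coarser resampling the erosion can destroy thin ribs.
* The slice-scan fold detector assumes the fold separates from the
  breast in some slice; a fold fused with the breast over its entire
  length is not detected.
* The muscle stage assumes the muscle body is the largest posterior
  high-HU structure; bilateral or strongly scattered muscles would
  need per-component handling.
* The HU-derived reference inherits partial-volume bias at tissue
  interfaces (a few percentage points at mid densities even with the
  core-mask exclusion); the closure metric is therefore relative to the
  HU reference, not to the generator truth.
* Lesions, artifacts and deformations are out of scope (see the phantom
  section).
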