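# Methods

`strokemark` implements the quantitative-imaging half of an automated
stroke-MRI biomarker pipeline: everything downstream of deep-learning
lesion segmentation and tractography. Its inputs are files those external
tools produce — one ADC volume per subject, one or more binary lesion
masks, and binary left/right corticospinal-tract (CST) masks — plus a
table of discharge modified Rankin Scale (mRS) scores. Its outputs are a
19-feature record per subject and an exploratory binary outcome model with
bootstrap uncertainty.

## Image model and geometry

All volumes are reoriented at load time to the canonical closest-to-RAS
axis order, so axis indices have a fixed meaning across heterogeneous
inputs. Geometry lives in a 4×4 voxel-to-world affine; spacings are its
column norms (mm). Masks are strict {0,1} fields. Masks on a foreign grid
are moved by nearest-neighbour resampling of world-mapped voxel centres,
which preserves binarity; resampling always moves tract masks into lesion
space, never the reverse, and grid agreement is enforced at 1e-4 mm rather
than silently broadcast. 4D diffusion series collapse to their first
volume when the caller allows it.

## Mask fusion

Candidate lesion masks from multiple segmentation models are fused by
voxel-wise strict majority: a voxel is lesion iff at least
`floor(n/2) + 1` of the n models mark it. For the canonical three-model
ensemble this is the at-least-two-of-three rule; ties at even n resolve to
non-lesion (the conservative default), and a single mask passes through
unchanged — the configuration used when only one segmentation model is
compatible with the available modalities.

## Lesion morphology

With V the lesion volume (voxel count × voxel volume) and A the mesh
surface area:

* **volume** — reported in mL; all internal arithmetic stays in mm³/mm² so
  the dimensionless indices are unit-consistent.
* **surface area** — marching cubes at iso-level 0.5 on the zero-padded
  binary field, after one voxel of Gaussian smoothing in index space.
  Meshing the raw binary field inflates the area of smooth shapes by ~9%
  (staircase bevel); with smoothing, digital spheres of radius ≥ 10 voxels
  mesh to within ~2% of 4πr², converging as the radius grows. Lesions so
  small that smoothing removes the 0.5 crossing fall back to the raw mesh,
  keeping single-voxel input well-defined.
* **sphericity** π^{1/3}(6V)^{2/3}/A and **compactness** A³/(36πV²) — 1
  for a perfect sphere, and exactly reciprocal: compactness ×
  sphericity³ = 1.
* **solidity** V / V_hull with the convex hull taken over world-mm voxel
  centres. The centre-based hull slightly underestimates the hull of the
  voxel solid, so the raw ratio can exceed 1 for small lesions; the
  reported value is capped at 1. A single voxel is defined as solidity 1;
  coplanar/collinear lesions raise a degenerate-geometry error.
* **elongation** sqrt(λ_min/λ_max) of the covariance of world-mm voxel
  centres — the minor/major axis-length ratio of the fitted ellipsoid, in
  (0,1]; a single voxel is an isotropic point (1.0). A perfectly thin rod
  has zero minor variance and hence elongation 0.

## Spatial and intensity descriptors

The intensity-weighted centroid uses in-mask ADC values as weights and is
reported in voxel and world coordinates (zero total weight falls back to
the geometric centroid, logged). Max and mean in-lesion ADC intensities
are taken verbatim. Quadrant occupancy splits the volume at the real-valued
midpoints of two configurable axes (defaults: array axes 0 and 2, labelled
left/right and anterior/posterior), counting each lesion voxel into
LA/LP/RA/RP by strict `index < midpoint` tests. The axis defaults follow
the printed convention of the source protocol; after canonical
reorientation axis 2 is typically inferior–superior, so the axes are
configurable rather than silently corrected.

## GLCM texture

Texture is computed on ADC intensities strictly inside the lesion.
In-mask intensities are min-max normalised to 8-bit levels over the whole
3D lesion (per-subject; a per-slice switch exists, and a constant lesion
maps to level 0). Each axial slice containing lesion voxels contributes
grey-level co-occurrence matrices for distances {1,2,3} and directions
{0°,45°,90°,135°}; a pixel pair counts only when **both** ends are inside
the mask. Matrices are symmetrised and normalised to probabilities. Six
statistics follow the classical definitions — contrast Σ(i−j)²p,
dissimilarity Σ|i−j|p, homogeneity Σp/(1+|i−j|) (absolute-difference
kernel, not the squared-difference inverse-difference-moment some
libraries use), ASM Σp², energy √ASM, and marginal-normalised correlation
with the zero-variance limit set to 1. Shannon entropy (bits) comes from
the slice's 256-bin level histogram, not from the matrix. Per slice, the
six matrix statistics are averaged with uniform weights over every
(distance, direction) offset that produced at least one pair — uniform
weights make the direction/distance averaging order immaterial — and the
subject descriptor is the arithmetic mean over contributing slices: seven
numbers per subject. Offsets or slices with no valid pair are excluded
from averages rather than contributing zeros.

For cohort-scale runs the statistics are evaluated directly from the pair
list (each of N ordered pairs carries probability 1/2N in the symmetrised
matrix, so every sum collapses to a mean over pairs) without materialising
the 256×256 matrix; the test suite asserts this fast path equals the dense
route and an independent double-loop oracle to 1e-10.

## Tract overlap

Per hemisphere: tract volume, lesion∩tract volume (both mL, using the
lesion grid's voxel volume after resampling), and

    overlap% = 100 · V(lesion ∩ tract) / V(tract).

The denominator is the tract — the fraction of the motor pathway invaded —
not the lesion; both conventions exist in the literature, so this is
stated explicitly. An empty tract after resampling null-flags that side.
Bilateral lesions are reported symmetrically; lateralisation is left to
downstream consumers.

## Feature record and cohort table

The registry names 19 biomarkers: six morphological, four
intensity/spatial (max, mean, centroid, quadrant distribution), seven
texture, and two tract-based (CST volume, CST overlap). Multi-component
features expand to a fixed 26-column design matrix (centroid → 3,
quadrants → 4, each CST feature → 2). Records carry a configuration hash
and package version; tables refuse to mix configuration hashes. Extraction
never aborts a cohort run: an empty fused lesion yields volume 0, 0%
overlaps and documented nulls elsewhere, and a lesion with no valid pixel
pair (isolated scattered voxels) nulls only the texture block. The cohort
serialises as CSV with nulls as empty fields, losslessly round-tripping.

Outcome labels are raw mRS values (0–6) joined by subject id; the binary
target is unfavourable = mRS > 2. Unlabeled subjects stay in the table but
are excluded from modelling. The label file is treated as "outcome at the
stated horizon" without interpreting whether that horizon is 24 h or
discharge.

## Outcome modelling

The protocol, in leakage-safe order: stratified 80/20 split first; then,
on training rows only — median imputation of nulls, per-column one-way
ANOVA F scores, top-k selection (default k = 17, ties to the lower column
index), and grid-searched hyperparameters under stratified 5-fold CV
scored by mean F1. The refit model sees held-out rows exactly once, at
evaluation. Metrics: accuracy, precision, recall, F1, ROC-AUC, MCC with
confusion counts; 95% confidence intervals by the percentile bootstrap
over test-set resamples (default 1000; resamples on which a metric is
undefined are skipped). Test-set resampling, not model refitting, is used
because the held-out set must be touched only once. Importances are
reported both impurity-based (from the trees) and permutation-based on
held-out data. Classifier families: random forest (default), gradient
boosting, and an optional xgboost backend; grids are package defaults
documented in the config, not a claim about any external protocol.

## Phantom generator

The generator exists so every stage — and the end-to-end pipeline — is
testable without patient data. A subject is a 40×48×24 voxel volume at
2 mm spacing (a scaled-down head; small enough that cohort-scale
simulations run on one CPU in minutes): two curved vertical tubes of
radius 5 mm placed symmetrically about the left/right midplane stand in
for TractSeg CST masks; the lesion is a randomly sized (semi-axes
4–12 mm), randomly oriented ellipsoid whose centre is biased toward a
tract with probability 0.7, producing a realistic spread of lesion–tract
overlap; the ADC volume is spatially correlated background texture
(Gaussian-smoothed white noise, 4 mm length-scale, SD 60) around a mean of
800, reduced by 350 inside the lesion — acute infarcts are ADC-dark —
which keeps texture features non-degenerate. Candidate segmentations
derive from the truth mask by a random one-voxel erosion/dilation plus
independent boundary-voxel flips (rate 0.10 per model).

Outcomes follow a stated logistic model:
logit P(unfavourable) = β₀ + β_vol·volume_mL + β_ov·mean(left,right
overlap%). The defaults (β₀ = −2.0, β_vol = 0.5, β_ov = 0.35) were fixed
once so the default cohort resembles a published acute-stroke profile:
~53% unfavourable outcomes and an oracle (true-probability) ROC-AUC of
~0.83. Two named conditions support calibration testing: an
*overlap-dominated* condition (β_vol = 0, β_ov = 1.2, oracle AUC ~0.96)
under which the pipeline must recover the signal, and a *null* condition
(all slopes 0) under which held-out AUC must average 0.5. mRS labels are
drawn uniformly from 3–6 for unfavourable and 0–2 for favourable
subjects. Everything is deterministic given (spec, seed), with per-subject
seeds spawned from the cohort seed.

What the phantom does **not** emulate: real brain anatomy and atlases, MR
physics and acquisition artefacts, multi-lesion or non-ellipsoidal infarct
shapes, registration error between modalities, and any correlation
structure between texture and outcome beyond what the ADC drop induces.
Passing tests therefore demonstrate correctness of the measurement and
modelling machinery and internal statistical calibration — not clinical
validity on patient data.

## Numerical choices and degenerate inputs

* Grid agreement tolerance 1e-4 mm; mask binarisation threshold 0.5.
* Marching cubes: iso-level 0.5, one-voxel zero padding, Gaussian σ = 1
  voxel pre-smoothing with raw-mesh fallback (above).
* GLCM zero-variance correlation := 1 when σᵢσⱼ < 1e-12.
* Level discretisation floors, with the in-mask maximum mapping to 255.
* Non-finite voxels in loaded volumes are replaced with 0 and logged.
* Top-k ties break to the lower column index for determinism; NaN F
  scores (constant columns) rank last.
* Bootstrap resamples with an undefined metric are skipped and counted;
  an all-undefined metric is null-flagged, as is ROC-AUC on a
  single-class test set.

## Problem sizes used in the shipped checks

The self-checks run cohorts of 300 phantom subjects; the signal/null
calibration averages held-out AUC over 50 generator seeds per condition in
the test suite (10 per condition in the acceptance script), with a
one-point hyperparameter grid (random forest, 100 trees) and 100–200
bootstrap repetitions. These sizes were chosen so a full run completes in
minutes on a single CPU while keeping the Monte-Carlo error of the mean
AUC near 0.01.

## Known limitations

* The mask is treated as one lesion; no connected-component splitting.
* Probabilistic or weighted fusion (e.g. STAPLE) is out of scope, as are
  probabilistic tract maps and along-tract profiling.
* Quadrant axis semantics depend on the acquisition's axis meaning; the
  defaults follow the printed array-axis convention and are configurable.
* The catboost family of the original three-classifier comparison is not
  bundled; random forest and gradient boosting are, xgboost optionally.
* Solidity's centre-based hull makes the index optimistic for lesions of
  a few dozen voxels (capped at 1).
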