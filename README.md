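# strokemark

Quantitative imaging biomarkers for acute ischemic stroke, downstream of
deep-learning segmentation.

After a stroke, short-term disability — conventionally summarised by the
modified Rankin Scale (mRS), dichotomised into favourable (mRS ≤ 2) vs
unfavourable (mRS > 2) — depends not only on how much tissue is infarcted
but on *where* the infarct sits relative to motor pathways and how
heterogeneous the damaged tissue is. `strokemark` turns the raw outputs of
external tools (lesion masks from segmentation networks, corticospinal-
tract masks from tractography, ADC maps from routine diffusion MRI) into
an interpretable per-subject feature record and an exploratory outcome
model. It is aimed at imaging researchers who already have segmentations
and want reproducible biomarkers and honest uncertainty, not another
segmentation network.

## What it computes

For each subject, 19 named biomarkers:

* **Mask fusion** — voxel-wise strict majority vote over candidate lesion
  masks (lesion iff ≥ ⌊n/2⌋+1 models agree; one mask passes through).
* **Morphology (6)** — volume V (mL); marching-cubes surface area A
  (mm²); sphericity π^{1/3}(6V)^{2/3}/A; solidity V/V_hull; elongation
  √(λ_min/λ_max) of the voxel-centre covariance; compactness A³/(36πV²)
  (= sphericity⁻³).
* **Spatial / intensity (4)** — intensity-weighted centroid; max and mean
  in-lesion ADC; quadrant occupancy after splitting the volume at the
  axis midpoints (LA/LP/RA/RP).
* **Texture (7)** — slice-wise grey-level co-occurrence statistics of the
  8-bit-normalised in-lesion ADC signal, for distances {1,2,3} and
  directions {0°,45°,90°,135°}, both pixels in-mask, symmetrised and
  normalised: contrast, dissimilarity, homogeneity, ASM, energy,
  correlation, plus histogram Shannon entropy — averaged over offsets and
  axial slices.
* **Tract overlap (2)** — per hemisphere, CST volume and
  overlap% = 100·V(lesion ∩ CST)/V(CST), after nearest-neighbour
  resampling of the tract masks onto the lesion grid.

The cohort layer assembles records into a CSV (26-column design matrix),
joins mRS labels, and runs the modelling protocol: stratified 80/20
split, training-only median imputation and ANOVA-F selection of the top
17 columns, grid-searched tree ensembles under 5-fold CV, and held-out
evaluation with percentile-bootstrap 95% CIs plus impurity and
permutation feature importances.

A seeded phantom generator (`strokemark.phantom`) produces tract-shaped
tubes, ellipsoidal lesions, textured ADC volumes, noisy candidate
segmentations and logistic-model outcomes with known ground truth, so the
whole pipeline is testable without patient data. See `docs/methods.md`
for the full model description and its limitations.

## Worked example

Simulate a 150-subject phantom cohort, extract features, and model the
outcome:

```sh
strokemark simulate -n 150 --seed 7 -o cohort
strokemark cohort cohort/manifest.csv -o features.csv --labels cohort/labels.csv
strokemark train-eval features.csv --seed 0
```

The last command prints a JSON report; with these seeds:

```
n_train 120   n_test 30
accuracy 0.667   precision 0.727   recall 0.533   f1 0.615
roc_auc 0.689    mcc 0.346
ci95 accuracy [0.500, 0.833]   ci95 roc_auc [0.484, 0.866]
top importances: cst_right_overlap_pct, dissimilarity, avg_intensity, ...
```

Reading it: 150 subjects split into 120 training / 30 held-out test
cases; the random forest discriminates favourable from unfavourable
outcomes with held-out AUC ≈ 0.69, but the wide bootstrap intervals show
how uncertain a 30-subject test set is — the point of reporting them.
The top-ranked feature is a lesion–CST overlap percentage, consistent
with the generator, whose outcome model is driven by lesion volume and
tract overlap. Single-subject use:

```sh
strokemark extract --adc adc.nii.gz \
    --lesion-mask m1.nii.gz --lesion-mask m2.nii.gz --lesion-mask m3.nii.gz \
    --cst-left cst_l.nii.gz --cst-right cst_r.nii.gz
```

prints the fused-mask 19-feature record as JSON. `strokemark fuse` and
`strokemark overlap` expose the individual stages.

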