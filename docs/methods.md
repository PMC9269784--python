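# Methods

This note documents the models, numerical choices and limitations behind
`formfactors`, in the spirit of a statistical-software methods appendix.

## Geometry of the features

All features are computed from a binary voxel mask with physical spacing
`(sx, sy, sz)` in mm. Masks are analysed in the file's own voxel lattice:
no resampling or anatomical reorientation is applied, because the bounding
box is axis-aligned *in image space* and resampling would change it. The z
step of the lattice is the inter-slice spacing, not the slice thickness
(an acquisition property); when the two differ, the spacing defines voxel
geometry.

**Bounding box.** Per axis the box side is `(max_index − min_index + 1) ×
spacing`: full voxel extents, not centre-to-centre distances. This makes a
single-voxel lesion a box of one voxel's physical size, so thickness is
never zero and every ratio stays defined — including the degenerate
single-slice ROI, whose thickness is one slice spacing. The sorted sides
give `l ≥ b ≥ t`.

The form-factor formulas are fixed as

- AEL `(l−b)/(l+b+t)`, AFL `2(b−t)/(l+b+t)`, ACO `3t/(l+b+t)`
  (sum to one identically — the identity `(l−b) + 2(b−t) + 3t = l+b+t`),
- KEL `1 − b/l`, KFL `1 − t/b`,
- MPS `(t²/(lb))^(1/3)`.

All are invariant to scaling the spacing and to permuting the grid axes
(the sides are sorted), and deliberately **not** rotation invariant: a 45°
rotated elongated ellipsoid changes its AEL, and the test suite asserts
this. Principal-axis (inertia-based) boxes are out of scope.

**Volume** is foreground voxel count × voxel volume.

**Surface area** comes from a closed triangulated isosurface at level 0.5
(scikit-image marching cubes) of the zero-padded volume. Marching cubes on
a raw binary grid systematically overestimates the area of smooth bodies by
roughly 9% (staircase artefact), so the default path anti-aliases the
binary volume with a Gaussian of 1 voxel before iso-surfacing; a voxelised
sphere of radius 10 mm at 0.5 mm spacing is then recovered to ±0.2%, and
the error decreases with resolution. The per-axis smoothing sigma is capped
at a quarter of the ROI's voxel extent along that axis so thin ROIs
(1–3 voxels across) are not eroded below the iso level; if smoothing would
remove the surface entirely the raw binary surface is used. Both
alternatives remain accessible (`smooth_sigma=0` for the raw isosurface,
`method="voxel"` for exposed-face counting, which gives exactly 6 for a
unit voxel).

**Maximum 3D diameter** is the largest pairwise distance between vertices
of the *raw* (unsmoothed) isosurface, restricted to the convex hull. The
raw mesh is used here because smoothing rounds corners and shortens
diagonals; on a solid 20×10×5 mm cuboid the measured diameter is within 3%
of the box diagonal, and on a voxelised sphere within 3% of the true
diameter. The mesh-vertex convention (the radiomics standard) implies a
single voxel reports its largest face-to-face span rather than its corner
diagonal; this sub-voxel discrepancy is accepted.

**Sphericity** `π^(1/3)(6V)^(2/3)/A` may marginally exceed 1 on
near-spherical or very coarse ROIs because volume (voxel counting) and area
(smoothed mesh) discretise differently; values above 1 are clipped to 1
with a warning. **Volume density** `V/(lbt)` cannot exceed 1 because the
box contains every counted voxel.

## Statistics

Univariate screening uses the two-sided Mann–Whitney U test per feature:
the exact null distribution when both groups have ≤ 25 observations and the
pooled sample is tie-free, otherwise the tie-corrected normal approximation
with continuity correction (scipy). Group summaries are mean ± sample SD
(n−1). Multiplicity is controlled by Benjamini–Hochberg step-up across the
11-feature panel (m = 11, one correction per dataset) at FDR 0.05
(statsmodels `fdr_bh`; the test suite checks it against a brute-force
implementation of the step-up definition). Re-analysis of published
p-value columns replaces censored entries ("<0.001") by 0.0005; the flags
are insensitive to the stand-in anywhere below the censoring point. On the
SSR-1 column this reproduces the published 7-of-11 significance pattern
exactly. On the LUNGx column standard step-up on the rounded printed
p-values flags 8 features where the original analysis reported 6; the
original correction was presumably run on unrounded p-values, which cannot
be recovered from the printed table, so the discrepancy is documented
rather than matched.

## Classification

Linear soft-margin SVMs (scikit-learn `SVC(kernel="linear")`, tolerance
1e-6, deterministic) compare a *base* feature set (maximum 3D diameter,
surface area, volume) with an *extended* set adding AFL, ACO, KFL and MPS.
Features are Z-scored feature-by-feature per dataset, each dataset blind to
the other; the scale uses the population (n) SD — the choice is
documented for determinism and cannot change predictions beyond a rescaling
of C. The penalty is grid-searched over C ∈ {0.01, 0.1, 1, 10} under the
row's own evaluation protocol, ties broken toward the smallest C (strongest
regularisation) for determinism.

Within-dataset evaluation is leave-one-out. By default the Z-score
parameters are fitted once on the whole dataset and reused in every fold —
replicating the per-dataset normalisation protocol — which leaks the
held-out sample's contribution to the feature moments; a
`strict_normalization` mode refits them inside each fold for a
leakage-free estimate. A fold whose training split loses a class entirely
(possible only in tiny cohorts) predicts the remaining class. Cross-dataset
evaluation normalises the test cohort with the test cohort's own
parameters, never the training set's.

## Cutoffs

For each discriminative form factor the accuracy-maximising univariate
threshold is found by exhaustive search over the midpoints of consecutive
distinct values plus ±∞ sentinels (the classify-everything-one-way rules),
so the achieved accuracy is never below the majority-class prevalence and
the search is total even for useless features. Accuracy ties are broken
toward the lowest threshold for the "greater ⇒ malignant" direction and the
highest for "less ⇒ malignant", making the rule symmetric under value
negation. Directions are fixed per feature (ACO, MPS: greater ⇒ malignant;
AFL, KFL: less ⇒ malignant); an inference mode derives them from pooled
group means for new features. Thresholds are reported per dataset, on the
pooled data, and as the two-dataset average.

## Synthetic data

**Phantoms.** Ellipsoids, cuboids and superellipsoids are voxelised by the
centre-inside rule on a grid with two voxels of margin; optional rotation
and a seeded, smoothed radial perturbation (5% default amplitude) provide
non-quadric test shapes. A solid thinner than one voxel along any axis is
rejected as degenerate. Phantoms are the oracles for the feature extractor:
cuboids give exact box dimensions, ellipsoids give closed-form factors.

**Calibrated cohorts.** The built-in `SSR1` and `LUNGx` calibrations (CSV
data files under `formfactors/data/`) carry the published per-group mean,
SD and group sizes of both reference cohorts (109 lesions, 38/71, PET/CT
series with 1.37/1.37/3.27 mm spacing; 83 lesions, 42/41, TCIA challenge
series). Each dimensionless feature is sampled from a beta distribution
whose analytic mean and SD equal the targets exactly (feasible whenever
`sd² < mean(1−mean)`; verified at load time); each positive size feature
from a moment-matched lognormal (positive, right-skewed — consistent with
the published volume SD exceeding its mean in the benign group). Features
are sampled **independently within class**: the published tables contain no
covariance information. Consequently the calibrated cohorts reproduce the
univariate structure but not inter-feature identities (AEL+AFL+ACO = 1
holds only in expectation) nor realistic multivariate geometry — so
absolute SVM accuracies on them say nothing about patient data, and the
published cross-dataset accuracy table is only mimicked directionally,
never numerically.

**Geometric cohorts.** For end-to-end tests with internally consistent
features, lesions are generated as ellipsoid phantoms with sampled box
dimensions: length lognormal (benign 20 ± 6 mm, malignant 24 ± 6 mm,
echoing larger malignant lesions), `b/l` beta (≈0.8 ± 0.1 both arms), and
`t/b` beta with a flatter benign arm (0.62 ± 0.14 vs 0.86 ± 0.08) —
encoding the finding that benign lesions tend to be flatter and malignant
ones more equant. Spacing defaults to `t/8` per lesion (capped by `l/40`),
keeping grids around 30–50 voxels per side so a 30-lesion cohort extracts
in well under a second.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use: 1,000 random box
dimensions for the sum-to-one identity; phantoms up to ~34k foreground
voxels (ellipsoid at 0.125 mm) for the 3% closed-form checks; 400–1,000
replicate calibrated cohorts for moment recovery (CLT error well below the
published 3-decimal precision); 100 random instances (n ≤ 200) for the
cutoff oracle, full enumeration up to n = 7 per group for the exact
Mann–Whitney path, and m ≤ 12 for the BH definition check; and 20 seeded
geometric cohorts of 30 lesions for the median feature-set gain.

## Known limitations

- Bounding-box form factors are rotation sensitive by design; re-oriented
  scans of the same lesion can yield different values.
- Surface area and diameter inherit marching-cubes discretisation error;
  at clinical CT resolution (2-slice lesions) all mesh-based quantities are
  crude and sphericity clipping is common.
- The calibrated cohorts are a univariate emulation only (see above).
- No intensity, texture, margin or spiculation features; masks are inputs,
  segmentation is out of scope.
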