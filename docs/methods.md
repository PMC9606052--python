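# Methods

`petrad` implements a complete multi-lesion FDG-PET radiomics pipeline for a
disease like diffuse large B-cell lymphoma (DLBCL): disease is multifocal,
outcome (progression within two years of the baseline scan) is a minority
class, and the scientific question is *which lesions, and which features of
them, carry the predictive signal* — a single "index" lesion, the whole-body
tumor burden treated as one volume of interest (VOI), per-lesion features
aggregated across lesions, or simple patient-level dissemination metrics.
Because no clinical scans ship with the package, a synthetic phantom cohort
with fully known ground truth stands in for the patient population; every
downstream stage is validated against that ground truth or against
independent brute-force oracles.

## Synthetic cohort model

A patient is a 3D SUV image (default 128 x 128 x 200 voxels at 2 mm
isotropic; tests and the acceptance script use 48 x 48 x 64 grids for
single-CPU runtimes) with:

* **Background**: Gaussian noise, mean 1.0 SUV, SD 0.1, truncated at 0.
  With these values background voxels essentially never cross the SUV-4.0
  segmentation threshold.
* **Lesions**: 1-20 per patient (uniform count), radii log-uniform over
  6.2-49 mm so volumes span ~1-500 mL across decades, peak SUVs uniform on
  4.5-40 and drawn independently of size (so the largest lesion is not
  automatically the hottest, as in real cohorts).  Shapes: spheres by
  default; volume-preserving random ellipsoids and multi-sphere "blobs" are
  available.  Lesions are placed by rejection sampling with a
  non-overlap margin; an impossible placement raises after bounded retries.
* **Lesion profile**: uniform core at the peak SUV with a smooth one-voxel
  edge ramp defined on the signed distance to the nominal boundary.  The
  ramp is anchored so the SUV-4.0 iso-contour coincides exactly with the
  nominal lesion boundary: thresholded volume then matches the analytic
  volume up to lattice discretization *for any peak SUV*.  A plain Gaussian
  blur of the support indicator does not have this property (its 4.0-contour
  moves outward by >1 voxel for hot lesions and inward with curvature),
  which would make analytic volumes unusable as ground truth.  Lesions are
  combined additively above background, so a "lesion" at background SUV
  leaves the image bit-identical.
* **Outcome**: Bernoulli from a logistic link on pilot-standardized
  (log MTV, SUVpeak, Dmax_bulk) with default weights (0.8, 0.4, 0.5).  The
  intercept is calibrated by bisection on a 10,000-draw pilot of the
  ground-truth feature distribution so that the expected prevalence matches
  the target (default 52/296 ~ 17.6%).  A progression-free-survival variant
  adds an independent 5% feature-independent event rate.  The package also
  reports the generating model's Bayes AUC by probability-weighted
  concordance over a large pilot sample — the large-n limit of scoring
  Bernoulli draws with the true risk.

What the phantom does **not** emulate: anatomy, attenuation, scanner point
spread and reconstruction, intra-lesion texture beyond the edge ramp, or
inter-scanner variability.  Passing tests therefore demonstrate that the
*pipeline* is correct and calibrated, not that any particular clinical AUC
is reproduced.

Randomness: one master seed; per-patient seeds come from
`SeedSequence(master, spawn_key=(patient_index,))`, fold and SMOTE seeds
from analogous spawn keys, so cohorts and CV runs are bit-reproducible.

## Segmentation

Lesions are 26-connected components of `{SUV >= 4.0}` with volume >= 3 mL,
labels ordered by decreasing volume (centroid-lexicographic tie-break).
Manual curation is scripted rather than interactive: `add_lesion` admits the
component containing a seed voxel regardless of volume (the "single mouse
click" for small lesions) and `remove_region` deletes a label.  A scan-level
QC rule is provided as advisory metadata: pass when hepatic SUVmean lies in
[1.3, 3.0] and glucose < 11 mmol/L; out-of-range hepatic uptake is still
accepted when 50-80% of the injected activity is in the image.

## Feature panels

Per lesion and for the patient-level VOI (the union of all lesion voxels,
processed as one possibly disconnected region):

* **5 conventional PET features** on the original grid: MTV (mL), SUVmax,
  SUVpeak (highest mean over a ~1 mL sphere centered on any in-VOI voxel;
  the sphere may extend outside the VOI and is truncated at image borders),
  SUVmean, and TLG = MTV x SUVmean.
* **Resampling** to 2 x 2 x 2 mm with centered-grid tri-linear
  interpolation (output grid center coincides with the input grid center);
  masks are interpolated tri-linearly and thresholded at 0.5.
* **Discretization** at a fixed 0.25-SUV bin width anchored at 0
  (`level = floor(SUV/0.25) + 1`), making gray levels comparable across
  lesions and patients.
* **22 morphology features**: mesh volume and surface area, voxel volume,
  surface/volume ratio, compactness (2 forms), spherical disproportion,
  sphericity, asphericity, center-of-mass shift, maximum diameter, PCA axis
  lengths, elongation, flatness, and volume/area densities relative to the
  axis-aligned bounding box, approximate enclosing ellipsoid and convex
  hull.  The mesh is marching cubes on a lightly Gaussian-smoothed (sigma
  0.8 voxel) indicator at level 0.5: a direct binary mesh has a staircase
  surface that overestimates sphere area by ~9% (digital-sphere sphericity
  ~0.91); smoothing restores it to ~0.99 at the cost of a curvature
  shrinkage of order sigma^2/r (< 1% volume for lesions above a few
  voxels).  Tiny masks without a 0.5-crossing fall back to the binary mesh.
  Ellipsoid surface area uses the Thomsen approximation (error < ~1.1%).
* **50 intensity features**: 2 local-intensity (1 mL-sphere peaks), 18
  statistics of the in-mask SUVs, 23 histogram statistics over gray levels
  1..Ng (including histogram gradients, with the two-sided difference in the
  interior and one-sided at the ends), and 7 intensity-volume-histogram
  features (V10, V90, I10, I90, their differences, and the IVH area under
  the curve on a 1000-point intensity grid).
* **408 texture features** over six families: GLCM (25 features) and GLRLM
  (16) with six aggregation methods (2D averaged, 2D slice-merged, 2.5D
  direction-merged, 2.5D merged, 3D averaged, 3D merged); GLSZM, GLDZM (16
  each), NGTDM (5) and NGLDM (17) with 2D / 2.5D / 3D aggregations.
  Conventions: GLCM at Chebyshev distance 1 with 4 in-plane and 13 unique
  3D directions, symmetric matrices; runs break at mask boundaries; zones
  are 8-connected (2D) or 26-connected (3D); GLDZM distances are city-block
  distances to the mask border with border voxels at distance 1 and the
  volume outside the image treated as outside the mask; NGTDM excludes
  voxels with no in-mask neighbor; NGLDM uses dependence coarseness
  alpha = 0.  Run/zone "percentage" denominators scale with the number of
  merged matrices so the features stay in [0, 1].

Degenerate regions never produce NaN: constant regions give zero
entropies/contrasts/variances, uniformity 1, GLCM correlation 1, coinciding
IVH intensities; a point-like mask has elongation/flatness 1 and zero-size
enclosing shapes give density 0.  Matrices with no entries (e.g. no voxel
pairs for a direction in a one-voxel slice) are excluded from aggregation
averages, and an all-empty aggregation reports 0.

Counts (5 / 22 / 50 / 408, total 485) are asserted on every extraction.

## Dissemination features

Eighteen patient-level features: lesion count; Dmax/Dmean from the bulk
(largest) lesion and over all lesion pairs, as Euclidean distances between
volume-weighted lesion centroids in mm; range, SD (population), coefficient
of variation, max/min ratio and IQR of per-lesion SUVpeak and SUVmean; and
volume range, volume SD and the bulk volume fraction (largest lesion volume
/ patient MTV).  Single-lesion patients take pinned values (distances and
spreads 0, ratios and bulk fraction 1), keeping the feature matrix complete
without imputation.  Centroid-based distances were chosen over
surface-to-surface distances for determinism and cost; this is an open
convention in the Dmax literature.

## Lesion-selection approaches and modeling

Twelve approaches map extracted features to a patient row: `reference`
(MTV, SUVpeak, Dmax_bulk — 3 columns), `largest`, `hottest`, `patient_mtv`,
`maximum`, `median` (480 radiomics + 5 conventional = 485), `dissemination`
(18 + 5 = 23) and the four/two `diss_*` combinations (498 radiomics + 5 =
503).  Conventional features are always the patient-level values so every
approach carries the same five; maximum/median aggregate only the 480
non-conventional features.

The classifier is ridge-penalized logistic regression (C = 1.0) on
within-fold z-scored features; with p up to 503 and n ~ 300 an unpenalized
fit is not identifiable.  Preprocessing per training fold only: natural-log
transform of columns with skewness > 0.5 and strictly positive training
values; optional SMOTE (hand-implemented: synthetic minority rows are convex
combinations of a minority row and one of its k = 5 minority nearest
neighbors, balancing to 1:1); optional reduction — PCA or factor analysis
keeping the components that explain 95% of training variance (FA uses the
PCA-determined count), RFE (random-forest, linear-SVM or logistic ranker,
10% eliminated per step down to 10 features), or ANOVA top-10-percentile.
Constant training columns are dropped before reduction.

Performance is the mean AUC over 5 outcome-stratified folds x 50 repeats
(CV-AUC); the reported SD pools all fold AUCs.  Paired models share fold
layouts exactly; the DeLong test (midrank implementation with the paired
variance of the AUC difference) is applied per test fold and the **median**
of all fold p values is the final p — the median is taken over all
repeats x folds.  Feature importances are normalized random-forest impurity
importances over the features surviving the approach's reduction method;
PCA is refused because its components are not features (factor-analysis
importances attach to the latent factors).

### Calibration facts worth knowing

* The CV-AUC of a *single* permuted-label dataset is not tightly centered
  on 0.5: fold AUCs on one permutation are strongly correlated, giving a
  permutation-to-permutation SD of ~0.07-0.1 at n = 150.  Null calibration
  is therefore assessed as the mean over many fresh permutations, which is
  the quantity that converges to 0.5 in a leak-free pipeline.
* Similarly, the realized true-risk AUC of one n = 300 cohort fluctuates
  around the population Bayes AUC with SD ~0.035 at ~18% prevalence; signal
  recovery is judged on the mean CV-AUC over independent cohorts.
* Leakage is tested with a canary feature that is constant in stored data
  (hence provably discarded by any training-side step) and rewritten to the
  outcome in held-out rows; only a pipeline that consults test rows during
  fitting can react to it.

## Problem sizes

Unit and acceptance tests run on 48 x 48 x 64-voxel phantoms with 1-4
lesions of 9-16 mm radius and peak SUV 4.5-25, cohorts of 150-300 patients,
5 folds x 10 repeats, texture oracles on <= 6^3 grids, and 10,000 DeLong
null simulations; these sizes were chosen so the full pipeline exercises
every code path on a single CPU in minutes.  The experiment driver scales
to the full default grid (12 approaches x 2 oversampling x 7 reductions x
250 folds) unchanged.

## Known limitations

* The exact membership of the 22-morphology / 50-intensity panels and the
  "up to 8 matrix calculation methods" of the original feature-extraction
  tool are not published in full; the panels here reproduce the printed
  cardinalities and all named features, but individual members may differ
  from that tool.
* Dissemination definitions (centroid vs border distances, normalization)
  follow the stated counts and semantics; supplemental-table-level details
  are pinned choices documented above.
* The phantom's texture content comes from edge ramps and background noise
  only; absolute values of texture features are not clinically meaningful,
  only their contracts (counts, invariances, oracle equivalence) are.
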