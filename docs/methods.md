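# Methods

`btiradiomics` implements a peritumoral-radiomics analysis for predicting
brain invasion (BI) in meningioma from contrast-enhanced T1-weighted MR
images. The scientific question it operationalizes: how wide a
brain–tumor-interface (BTI) shell around the tumor surface carries the
most diagnostic texture information, compared with the whole tumor (WT)
and with combined tumor+shell (COM) regions?

## Regions of interest

Nine ROIs are built per subject from the tumor segmentation:

* **BTI-N** (N ∈ {2, 3, 4, 5} mm): voxels whose signed Euclidean distance
  to the tumor surface lies in [−N, +N]; band full width 2N mm.
* **COM-N**: tumor ∪ BTI-N.
* **WT**: the tumor mask itself.

All ROIs are intersected with the brain mask, and voxels inside the skull
mask are removed (automating the manual skull-exclusion step of clinical
workflows; skull exclusion can only remove voxels).

Signed distances are in physical millimetres and honor anisotropic
spacing. Two backends are provided and the choice is a documented
accuracy/speed trade-off:

* `edt` — distance from each voxel center to the nearest voxel center of
  the opposite class (`scipy.ndimage.distance_transform_edt`). Exactly
  reproducible by a brute-force pairwise oracle; fast (two EDTs per
  subject). Used for cohort-scale experiments.
* `mesh` — distance to the 0.5-level marching-cubes surface of the
  lightly smoothed mask (Gaussian σ = 0.8 voxel), evaluated on a ±8 mm
  narrow band. The sub-voxel surface removes the half-voxel bias of the
  `edt` convention: on digital spheres of radius 8–12 mm the voxelized
  band volumes agree with the analytic shell volumes to within ~2.5%
  (raw `edt` thresholds are off by up to ~13% for thin bands). Default
  for `make_roi` and geometry metrics.

Volumes are voxel-count based by default (ml); a triangle-mesh volume
(divergence theorem over the marching-cubes surface) is available and
reported alongside. The peritumoral edema volume is
PEV = vol(FLAIR-outlined region) − vol(tumor) and the edema index
PEI = PEV / TV.

## Feature extraction

Preprocessing: per-image z-score normalization over the brain mask,
rescaled by 100 (so one gray-level bin of the default width 25 equals
0.25 SD), tri-linear resampling to 3×3×3 mm (nearest-neighbor for masks;
interface bands are constructed at native resolution *before* resampling
to preserve mm-scale geometry). Discretization uses a fixed bin width:
`level = floor((x − min)/width) + 1`.

Feature classes (names follow common radiomics usage; all logarithms are
base 2):

* first-order histogram statistics (18),
* 3-D shape descriptors from the original-resolution mask (14; mesh
  volume/area with the σ = 0.8 voxel pre-smoothing — the raw binary
  isosurface overestimates the area of smooth objects by ~8%, which would
  bias sphericity),
* GLCM (21; symmetric, counts summed over the 13 unique 3-D offsets at
  Chebyshev distance 1, then normalized; the documented 21-feature list
  excludes the duplicative SumAverage/SumSquares and MCC),
* GLRLM (16; runs pooled over the 13 directions, run percentage uses
  13 × voxel count),
* GLSZM (16; 26-connected zones),
* NGTDM (5; 26-neighborhoods),
* GLDM (14; dependence = 1 + number of 26-neighbors whose level differs
  by ≤ α, default α = 0).

Degenerate single-level ROIs yield finite, documented values (e.g. GLCM
Correlation = 1). The derived-image bank holds the original image, the 8
sub-bands of a one-level stationary 3-D coiflet-1 wavelet, and
Laplacian-of-Gaussian filters at σ ∈ {3, 5} mm — 10 derived images, so
the default configuration yields 14 + 11 × 90 = 1004 features. (The
corresponding clinical analyses usually quote feature totals near one
thousand; the exact figure is a pure function of the configured class
counts, which this package asserts rather than forces.) Every texture
family is verified against naive nested-loop oracles to 1e-6 relative
tolerance.

Min-max scaling `x' = (x − min)/(max − min)` is fitted on training data
only; stored parameters are re-applied (never re-fitted) to validation
and external sets, where out-of-range values are allowed.

## Feature selection

1. **Reproducibility filter**: ICC(2,1) — two-way random effects,
   absolute agreement, single measurement — between features extracted
   from two segmentations ("raters"); features with ICC < 0.8 (or
   undefined ICC) are removed. The form is the standard choice for
   continuous test–retest radiomics.
2. **Redundancy filter**: greedy Spearman filter at |ρ| > 0.9. Features
   are prioritized by |Spearman ρ| with the class label (ties broken
   lexicographically), and lower-priority members of correlated pairs are
   removed. The label-aware survivor rule is a deterministic, documented
   design choice.
3. **LASSO screen**: L1-penalized logistic path, penalty chosen at the
   minimum of 10-fold cross-validated deviance (not 1-SE), seeded fold
   assignment. Active features are ranked by |coefficient|; the retained
   count is capped by the events-per-variable rule
   k = floor(events / EPV) with EPV = 10, with explicit presets k = 9 and
   k = 3 replicating the two modeled cohorts (their published EPV
   arithmetic matches no single divisor, so k is configuration). A
   squared-error variant (`objective="linear"`) exists; on orthonormal
   designs it equals soft-thresholding exactly and serves as a
   closed-form oracle.
4. **Varimax PCA**: PCA of the feature correlation matrix; components
   retained by the Kaiser rule (eigenvalue ≥ 1) unless overridden (an
   override of 8 replicates the 4-mm-band analysis). Loadings
   (eigenvector × √eigenvalue) are varimax-rotated with Kaiser
   normalization (statsmodels' gradient-projection rotation; tolerance
   1e-6, ≤ 1000 iterations); the rotation is orthogonal, so communalities
   are preserved to 1e-8. Signs are fixed so each component's
   largest-|loading| entry is positive. Held-out subjects are projected
   with the stored standardization and rotation.

## Modeling and resampling

* **Temporal split**: earliest 80% of subjects by acquisition date train,
  the rest validate; ties break by subject id so the split is a pure
  function of its inputs.
* **Repeated CV**: per iteration, a stratified subsample without
  replacement (fraction 0.8 — the source protocol does not state the
  fraction) followed by stratified 5-fold CV; the AUC of pooled
  out-of-fold predictions is recorded. Min-max scaling is re-fitted
  inside every training fold (no leakage). 100 iterations by default;
  the phantom experiments use 10 per cohort.
* **Classifiers**: backward-stepwise logistic regression by AIC from the
  full model (complete separation falls back to an L2-penalized fit,
  flagged), and a random forest (500 trees, √p candidate predictors,
  out-of-bag AUC reported). Note that AIC retains a 1-df predictor
  whenever its likelihood-ratio statistic exceeds 2, so a pure-noise
  predictor survives with probability ≈ 0.16 — an inherent property of
  the criterion, reflected in the tests.
* **Clinical and combined models**: PEV-only logistic model, and PEV +
  interface component scores.

## Evaluation

Confusion-matrix rates at the decision-curve-derived cutoff 0.20
(sensitivity, specificity, accuracy with Clopper–Pearson exact CI, PPV,
NPV; half-up rounding to 3 decimals with trailing-zero trimming to match
clinical-table style); ROC AUC as the tie-corrected Mann–Whitney
statistic with the DeLong variance; precision-recall AUC by
interpolation-free step integration (baseline = prevalence); decision
curves NB(pt) = TP/n − (FP/n)·pt/(1−pt) with treat-all/treat-none
references; categorical NRI (cutoff 0.20), continuous NRI (sum of event
and non-event components, so the range is [−2, 2]), and IDI as the
discrimination-slope difference, all with seeded 2000-replicate
percentile-bootstrap CIs; pairwise AUC-distribution comparisons by
two-sided Wilcoxon signed-rank tests with BH-FDR adjustment (the
comparison test is swappable for DeLong on fixed splits).

## The phantom generator

No patient data are distributable, so every cohort is synthesized. A
subject is an ellipsoidal "brain" (with a 3 mm "skull" shell) containing
a skull-adjacent, mildly anisotropic spherical "tumor" (radius 8–13 mm at
the default 48³ × 1.5 mm geometry — roughly a 1/5 volume scale-down of
clinical meningiomas so nine ROIs fit a tractable grid). The image is a
CE-T1-like class map (tissue 100, tumor 140, skull 45) plus a smooth bias
field and white noise; two synthetic sites differ in intensity scale
(×1.1) and noise SD (5 vs 6.5) to emulate scanner differences.
Acquisition dates are sequential, so a temporal split is meaningful.
Labels are Bernoulli draws at prevalence 0.21 (the two-center cohorts
this emulates run 21–23%).

Invasive subjects carry two class signals:

* **Edema**: peritumoral-edema volumes drawn from class-specific
  log-normals (defaults: median 3.2 ml, log-SD 0.9 non-invasive vs
  10.3 ml, 0.7 invasive — the clinical 16.0 vs 51.3 ml medians scaled to
  the phantom geometry); the outlined region grows outward from the tumor
  nearest-first until the drawn volume is realized.
* **Interface texture**: inside the shell 0..`invasion_depth_mm` (default
  4 mm) outside the tumor surface, the white tissue noise is blended with
  a spatially correlated Gaussian field of identical marginal variance:
  `sqrt(1−c²)·white + c·correlated` with correlation length 2 mm. The
  signal is therefore *purely* a change of spatial correlation length —
  invisible to first-order statistics and detectable only through pair
  statistics (GLCM/GLDM), so a band's discrimination grows with the
  fraction of the shell it captures and shrinks with dilution by
  unperturbed tissue. This choice is load-bearing: an earlier
  additive-variance signal was detectable through the skewness of the
  bimodal tumor/tissue intensity mixture, which is sharpest in the
  thinnest band and made BTI-2 dominate at every depth, destroying
  parameter recovery. `texture_contrast` = 0 removes the class signal
  from the image entirely (the null condition).

The default contrast c = 0.6 was calibrated once, by scanning
c ∈ {0.6, 0.8, 0.95}: it puts the best band's mean CV AUC near 0.86, the
discrimination range the modeled analysis operates in, while c ≥ 0.8
saturates every band near AUC 1 and erases the ranking signal.

A second "rater" is simulated by displacing the mask surface with a
smooth random field clipped to ±`rater_jitter_mm`; voxels farther than
the jitter from the surface are provably unchanged, and expected Dice
decreases with jitter (jitter below the voxel spacing cannot flip any
voxel center). The blood panel is drawn from log-normals around published
cohort medians; derived indices use the standard definitions NLR = N/L,
dNLR = N/(WBC−N), PLR = Plt/L, SII = Plt·N/L, MLR = Mono/L,
PNI = albumin (g/L) + 5·lymphocytes (×10⁹/L), with undefined ratios
returned as NaN and flagged rather than dropping the subject.

**What the phantom does not emulate**: anatomy (no gyri, no tissue-class
heterogeneity), MR physics (no sequence simulation, no realistic bias
fields or motion), true infiltration patterns (the shell model is a
statistical stand-in — the spatial statistics of real invasive interfaces
are uncharacterized), and edema is not rendered in the CE-T1-like
intensities (it exists only as the FLAIR-outlined mask and volume).
Passing tests therefore demonstrate that the *pipeline* recovers planted
structure under its own assumptions, not that the clinical effect sizes
transfer to real MR data.

## Problem sizes and numerical choices

The cohort-scale experiments (parameter recovery, null control) run 20
seeds × 200 subjects on 48³ grids at 1.5 mm spacing with a reduced
extraction configuration — original image only, first-order + GLCM +
GLDM (53 features), native-resolution grid, `edt` distances — and 10
CV iterations per cohort; these sizes keep a full run in minutes while
leaving the ranking statistics stable. The full filter bank, resampling
and all five texture families are exercised in the unit tests and
available through configuration. Tolerances: texture oracles 1e-6
relative; ICC vs ANOVA sums 1e-10; varimax communalities 1e-8; signed
distances vs the pairwise oracle exact. Ties in discretization use
floor semantics; ties in the Spearman filter and LASSO ranking break
lexicographically; the temporal split breaks date ties by subject id.

## Known limitations

* The `edt` band convention biases thin-band volumes low (up to ~13% at
  N = 2 on spheres); use `mesh` where band-volume fidelity matters.
* The LASSO active set at the CV-minimum penalty includes suppressor
  features with coefficients comparable to signal features; claims about
  "selected" features are therefore made on the |coefficient| ranking
  prefix, not the full active set.
* GLDM's "fully dependent neighborhood" idealization (dependence
  nonuniformity → 1) is not attained on finite grids because corner and
  edge voxels have truncated neighborhoods.
* Reported clinical-table reproductions validate the metric arithmetic,
  not patient-level performance, which is not reproducible without the
  original cohorts.
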