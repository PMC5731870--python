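# Methods

This note records the modeling choices, parameter conventions and known
limitations of `gliotex`, in the spirit of a model-description appendix.

## Preprocessing chain

Stages run in the order **normalize → reslice → quantize**, per modality.

* **NAWM normalization.** Every voxel is divided by the mean intensity
  over the contralateral normal-appearing-white-matter mask, so tumor
  intensities are expressed relative to normal tissue (NAWM mean = 1
  after the step). The operation is invariant to global positive
  rescaling, which is the property that makes multi-scanner intensities
  comparable. Inputs are assumed bias-field corrected upstream (N3-style
  correction with signal threshold 1.0, field distance 50 mm, kernel
  FWHM 0.15 is the reference protocol); the pipeline neither implements
  nor needs a specific correction algorithm.
* **Isotropic reslicing** to 1 mm voxels: trilinear interpolation for
  intensities, nearest-neighbor for masks, half-voxel-centered grid over
  the same physical extent (`scipy.ndimage.zoom`, `grid_mode=True`,
  edge-clamped). Physical mask volume is preserved to well within 5% for
  ellipsoidal ROIs at 2 mm → 1 mm. Single-slice axes are rejected rather
  than extrapolated.
* **Quantization** to G = 8 equal-width bins over the per-ROI min–max
  range, `level = 1 + floor(G·(x−min)/(max−min))` with the maximum
  clamped into level G; a constant ROI maps to level 1. Equal-width
  binning was chosen over equal-probability binning because it is the
  standard radiomics reading, is invariant to positive affine intensity
  transforms, and keeps gray-level contrast features meaningful. The
  gray-level count is configurable (4–32 are common choices; 8 is the
  default everywhere).

## The 86-feature panel

43 features per modality (T1-post, FLAIR), named
`{modality}_{family}_{feature}`; the canonical ordering ships as a JSON
registry resource.

Conventions that are fixed and documented rather than configurable:

* **GLCM (19 features):** distance-1 co-occurrence over the 13 unique 3D
  directions, counted only when both voxels are in-mask, symmetrized,
  **pooled (summed) over directions before normalization**, logs base 2.
  Pooling keeps the feature count at 19 instead of 19×13 and averages out
  directional sampling noise on anisotropically shaped ROIs. The feature
  list is the Haralick set (energy, contrast, correlation, sum-of-squares
  variance, inverse difference moment, sum average/variance/entropy,
  entropy, difference variance/entropy, IMC1, IMC2) extended by
  autocorrelation, cluster shade/prominence/tendency, dissimilarity and
  maximum probability.
* **NGTDM (5):** Amadasun–King coarseness, contrast, busyness,
  complexity, strength; 26-neighborhoods restricted to in-mask voxels;
  voxels without in-mask neighbors are excluded from the table.
* **GLSZM (11):** zones are 26-connected components of equal gray level;
  the conservation identity Σᵢⱼ j·Z(i,j) = N (in-mask voxels) is asserted
  in tests. 26-connectivity is the standard reading of "3D zones".
* **Histogram (6):** mean, population variance, skewness, kurtosis,
  base-2 entropy of the level distribution, uniformity (Σp²).
  **Kurtosis is Pearson (non-excess), m₄/m₂²** — a normal distribution
  scores 3 — and this convention is used everywhere.
* **Regional (2):** tumor volume in mm³ and the sum of NAWM-normalized
  intensities over the mask.

Degenerate inputs produce documented sentinels plus a per-feature quality
flag instead of NaN/inf: zero-variance histograms report skewness and
kurtosis 0; a constant GLCM reports correlation and IMC1 0; NGTDM
coarseness of a zero-deviation ROI is capped at 10⁶; busyness/strength
with empty denominators report 0. This keeps downstream feature matrices
finite without silently hiding the degeneracy.

## Robustness screening

Eight canonical geometric perturbations of the tumor mask are applied on
the resliced 1 mm grid ("pixel" = in-plane voxel): x-translation and
x+y-translation by 2 voxels, in-plane rotations by 1° and 5° about the
mask centroid (nearest-neighbor), per-slice contour jitter with
zero-mean Gaussian normal displacements at sd 0.1 and 0.5 voxels
(re-rasterized polygons; seeds recorded), and dilation/erosion by a
1-voxel 6-connected spherical element. Two small-print behaviors are
intentional: a 1° rotation and sd-0.1 jitter are sub-voxel operations, so
on small or rotationally symmetric ROIs they can reproduce the original
mask exactly — that is the correct nearest-neighbor/rasterization
outcome, and it simply yields ICC = 1 for those versions.

Per feature, agreement across the 9 ROI versions is summarized by the
**one-way random-effects ICC(1,1)** = (MSB − MSW)/(MSB + (k−1)MSW),
k = 9; ICC(3,1) is available as an option when per-version systematic
offsets should be discounted. Zero-total-variance matrices are defined as
ICC 1 (identical measurements); negative estimates are clamped to 0 at
report time with a flag. Features pass at ICC ≥ 0.6, screened per
modality (a feature answers only for its own modality's perturbed
re-measurements).

## All-relevant selection

The shadow-feature procedure is reimplemented rather than wrapped: each
round permutes every feature column into a shadow copy, fits a
`RandomForestRegressor` (100 trees, mtry = √p) on the augmented matrix
against the **continuous** CD3 z-score, and scores a hit for every
undecided feature whose impurity importance exceeds the maximum shadow
importance. Hits after r rounds are tested two-sidedly against
Binomial(r, ½) at α = 0.01 with Bonferroni correction over features;
significance confirms or rejects. The loop caps at 100 rounds; remaining
undecided features are resolved by comparing their median importance with
the median of the max-shadow trace. Impurity (Gini) importance is used —
it is the common default of shadow-feature implementations and an order
of magnitude cheaper than permutation importance at 86 + 86 columns; the
√p feature subsampling is what gives correlated informative features
independent chances to score hits (the all-relevant property).

Confirmed features are pruned greedily in descending median importance:
keep a feature iff |Pearson r| < 0.6 against every already-kept feature;
the higher-importance member of a correlated pair survives. The retained
set provably has all pairwise |r| below threshold.

A frozen 6-feature CD3-associated panel (T1-post histogram kurtosis,
NGTDM contrast, GLSZM small-zone emphasis, low/high gray-level zone
emphasis, small-zone high-gray-level emphasis) ships as a package
resource so the classifier can run without re-selection.

## Symbolic-regression classifier

A generational GP evolves expression trees over the selected features:
primitives {+, −, ×, protected ÷} (denominators within 1e-12 of zero
yield 1; outputs clipped to ±1e12), terminals = feature variables and
ephemeral constants U(−1, 1). Defaults: population 500, 50 generations,
ramped half-and-half initialization at depths 2–4, tournament size 3,
subtree crossover 0.8 / subtree mutation 0.15, depth cap 6, elitism of
one; fully deterministic under the seed. **Fitness is training ROC AUC**
(rank-based), not squared error, because the endpoint is binary
classification; the continuous expression output is thresholded at the
training-set Youden point (max sensitivity + specificity − 1). The fit
never sees test outcomes — the interface takes the training half only.
A logistic regression on standardized features is provided as a
transparent comparator behind the same `TrainedModel` interface.

Cohorts are split 50/50 at random (training takes the extra case when n
is odd), redrawing up to 100 times if either half lacks a class, with a
Kruskal–Wallis balance report per checked covariate.

## Evaluation statistics

* AUC is the normalized Mann–Whitney U with ties counted ½ (verified
  exhaustively against a pairwise-count oracle for n ≤ 12).
* AUC CIs: percentile interval of B = 2000 class-stratified bootstrap
  resamples (resampling within each class keeps every replicate
  two-class).
* Accuracy CIs: exact Clopper–Pearson (beta quantile) intervals.
* Covariate adjustment: one multivariate **linear** model of the
  continuous CD3 measurement on age, gender, KPS, both tumor volumes,
  both total intensities, and the model predictions; per-term p-values.
  The linear reading was chosen because a single p per term is reported
  for a continuous outcome; a logistic variant on the binary label is a
  trivial substitution if needed. Columns are scale-normalized before
  numerical rank checking so mm³-scale volumes cannot mask true
  collinearity, and rank deficiency is reported with the offending
  columns named.
* AUC comparison between two models on the same cases: paired case
  bootstrap of the AUC difference; observed difference divided by the
  bootstrap SE, referred to the normal distribution, two-sided.
  Identical score vectors give p = 1 by definition.
* "High infiltration" is the positive class in every metric.

## The phantom generator

Each synthetic patient lives on a 64×56×18 grid at anisotropic
0.9×0.9×3.0 mm native spacing (so reslicing is genuinely exercised; the
z-spacing sits inside the range seen in multi-site glioma archives). The
tumor is an ellipsoid (per-patient semi-axes drawn from 13–18 × 11–16 ×
9–14 mm, ≈ 6–15 cm³ — scaled down from clinical glioblastoma volumes to
keep desk-scale runtimes); the FLAIR mask is the same ellipsoid inflated
by 3 mm per axis, mimicking the larger hyperintense tumor + edema region
contoured on FLAIR. A disjoint 5 mm NAWM sphere provides the
normalization reference; overlap is rejected at generation time.

Intensities are `1 + tumor contrast + amplitude·GRF + rim + noise`: the
GRF is white noise convolved with an isotropic (in mm) Gaussian of the
stated correlation length, standardized to unit variance — correlation
length is a direct dial for texture coarseness (longer ⇒ larger
quantized zones, a property asserted over ≥ 20 seeds); the rim term is a
Gaussian ridge on the tumor boundary (T1-post only by default),
emulating enhancing rims; the noise term is i.i.d. Gaussian speckle.
Per-patient texture parameters are drawn uniformly from stated ranges
(e.g. correlation length 2.5–3.5 mm, field amplitude 0.30–0.40, T1-post
rim 0.20–0.30, noise sd 0.03–0.25).

**CD3 link.** The continuous CD3 z-score is a linear function of
population-standardized true texture parameters plus N(0, 0.25) noise;
the binary label is z > 0. The default link puts unit weight on the
T1-post noise amplitude, i.e. *fine-scale heterogeneity*: the package's
working hypothesis is that immune influx raises fine-grained textural
diversity, and speckle amplitude is the generator's cleanest control of
that property. Speckle fragments the quantized zone partition, so the
designated causal readouts are the zone-count statistics (GLSZM zone
percentage and zone-size non-uniformity); at desk-scale ROI sizes these
respond far more reliably than coarseness-driven statistics, whose
seed-to-seed sampling variance is large. Clinical covariates (age, sex,
KPS) are drawn independently of CD3, giving covariate-adjustment
analyses a known null.

What the phantoms do **not** emulate: anatomy (no brain, skull, or
tissue classes), bias fields, registration error between modalities,
scanner-specific noise spectra, or segmentation variability. Passing the
end-to-end tests therefore demonstrates that the pipeline recovers a
known texture–outcome link through its own preprocessing, screening,
selection and classification stages — not that any particular clinical
effect size is reproducible.

## Problem sizes and numerical choices

* The parameter-recovery experiment runs 10 cohorts of n = 150 (75/75
  split) and trains the GP at population 300 / 25 generations — the
  package's standard desk-scale experiment configuration; selection runs
  at its defaults (100 trees, cap 100 rounds).
* The recovery criterion is two-sided: every designated causal feature
  confirmed in ≥ 80% of seeds, held-out AUC > 0.8 in ≥ 8/10 seeds.
* Bootstrap defaults: B = 2000, percentile intervals.
* All stochastic stages take explicit integer seeds; cohort generation,
  selection, splitting, GP search and bootstraps are bit-reproducible
  under them.

## Known limitations

* The GLCM 19-feature identity list and the histogram 6-feature list are
  fixed conventions of this package; other radiomics toolboxes ship
  slightly different tails (e.g. inverse variance instead of
  dissimilarity), so cross-toolbox numerical comparison requires mapping
  names, dialects (pooled vs averaged directions) and log bases.
* ICC(1,1) treats perturbation versions as exchangeable; if a
  perturbation introduced a systematic offset across all subjects,
  ICC(3,1) would be the better screen (available via `form="icc3"`).
* The GP engine optimizes rank separation only; expression complexity is
  controlled solely by the depth cap, so reported expressions are not
  minimal descriptions.
* Boruta decisions at small n (< ~30) are underpowered; the
  implementation refuses n < 10 outright.
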