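# Methods

`usradiomics` implements a complete ultrasound-radiomics study design for
binary nodule classification — benign vs malignant — on grayscale B-mode
frames with binary ROI masks. Because labelled patient ultrasound is rarely
shareable, the package ships a synthetic cohort generator that reproduces
the *statistical structure* of such a study (class imbalance, texture
contrast between classes) so that every downstream stage is exercised
end-to-end by code alone.

## Synthetic cohort model

Each case is a single elliptical nodule ROI rendered on a smooth echogenic
base profile (mid-grey centre, mildly darker margins, plus low-frequency
smooth variation) carrying multiplicative gamma speckle with unit mean and
shape `speckle_shape` (CV = `1/sqrt(shape)`). The default cohort design is
102 benign + 40 malignant training cases (28.2% malignant) and a 15 + 6
external cohort (~29% malignant). Malignant nodules differ in two ways:

* a Poisson(`malignant_focus_rate`) number of dark circular foci fully
  inside the ROI, each multiplying intensity by `focus_intensity_factor`
  (< 1, hypoechoic), radius drawn from `focus_radius_range`;
* speckle CV inside the ROI inflated by `malignant_speckle_contrast`.

Defaults: 256×256 8-bit images, 0.1 mm isotropic spacing, ROI semi-axes
30–60 px, `speckle_shape = 30`, `malignant_focus_rate = 10`,
`focus_radius_range = (2, 5)` px, `focus_intensity_factor = 0.2`,
`malignant_speckle_contrast = 1.3`.

The generator defaults were calibrated once so that the class ordering of
the two leading texture markers matches the ordering reported for real
thyroid cohorts: the malignant median of NGLDM *dependence count energy* on
the gradient-filtered image and of NGTDM *complexity* on the square-filtered
image both exceed the benign medians. These two features pull in opposite
directions mechanically: inflating speckle widens the gradient grey-level
histogram (lowering dependence count energy) while deep, sharp-edged foci
stretch the FBN range of the gradient image and compress the bulk into few
levels (raising it). A relatively smooth baseline speckle (shape 30),
moderate contrast inflation (1.3) and deep foci (factor 0.2) satisfy both
orderings robustly across cohort seeds.

What the generator does *not* emulate: physically propagated wavefronts,
depth-dependent attenuation and focus, probe/TGC artefacts, operator
variability, anatomy outside the nodule, 3D structure. Passing tests
therefore demonstrate the correctness and internal consistency of the
pipeline and its statistics under a controlled texture model — not clinical
performance on patient images.

## Preprocessing

Images and masks are resampled to isotropic pixel spacing before feature
computation, using the coarser of the two input spacings as the target
(down-sampling only; bilinear for the image, nearest-neighbour for the
mask, which stays strictly binary). If the resampled mask would exceed a
size cap — 10⁷ pixels for the texture-matrix families, 10⁶ for the
first-order families — the target spacing is coarsened uniformly by the
smallest factor that brings the mask under the cap (with a minimum step to
absorb integer shape rounding, making the rule idempotent).

ROI intensities are discretized with a fixed bin number (FBN, default 64):
`level(x) = floor(n_bins (x − min)/(max − min)) + 1`, the maximum mapping to
`n_bins`, a constant ROI mapping to level 1. Levels are invariant under
positive affine rescaling of ROI intensities.

## Filter bank

Five intensity transforms precede extraction, each contributing its own
feature namespace: identity; gradient magnitude (central differences on the
mm grid, reflect padding); Laplacian of Gaussian (σ default 1.0 mm, kernel
truncated at 4σ, response shifted so the ROI minimum is ≥ 0 — the shift
leaves FBN levels unchanged but keeps intensity statistics well defined);
square `(x/x_max)² x_max` and square root `sqrt(x/x_max) x_max`, with
`x_max` the bit-depth maximum so both are monotone bijections of `[0,
x_max]`. Filtered images are re-discretized per filter over the filtered
ROI's own min/max. The LoG scale, gradient operator and padding are
package choices (the feature definitions do not fix them); all are recorded
in the run manifest.

## Feature families

Seven families per (filter, ROI) pair, ~290 features in the default bank:
intensity statistics (on raw intensities; percentiles by linear
interpolation between order statistics; variance is the population variance;
kurtosis is excess kurtosis; the quartile coefficient of dispersion is
`(P75 − P25)/(P75 + P25)`, 0 with a warning when the denominator vanishes),
intensity histogram (on FBN levels; entropy in bits; mode ties break toward
the smaller level), GLCM, GLRLM, GLSZM, NGTDM and NGLDM.

Matrix conventions (2D, single-frame):

* **Directions.** The 4 unique 2D offsets (0°, 45°, 90°, 135°); per-direction
  matrices are normalized then averaged. Count-based non-uniformity
  statistics (GLNU/RLNU, run percentage), which are not well defined on an
  averaged probability table, are computed per direction from the raw count
  matrices and averaged.
* **GLCM**: symmetric, distance 1, pairs with either pixel outside the ROI
  skipped. Correlation of a single-level ROI is defined as 1.
* **GLRLM**: runs broken by the ROI boundary.
* **GLSZM**: zones are 8-connected components of equal level.
* **NGTDM**: Chebyshev-radius-1 neighbourhoods restricted to the ROI; only
  pixels with ≥ 1 in-ROI neighbour enter. Coarseness is `1/Σ pᵢsᵢ`, capped
  at 10⁶ (also when the denominator vanishes); complexity carries the `1/N`
  normalization.
* **NGLDM**: dependence count `j = 1 +` number of Chebyshev-1 in-ROI
  neighbours whose level differs from the centre by ≤ α (default α = 0); the
  `1` is the centre pixel, so `j ≥ 1` and dependence count energy lies in
  `(0, 1]`, reaching 1 only when the ROI occupies a single (level, count)
  cell — which for a constant ROI requires uniform neighbour counts (e.g. a
  2×2 ROI); larger constant ROIs split over boundary-dependent counts.

Every matrix feature is checked against an independent brute-force oracle
(pair enumeration, run walks, flood fill, per-pixel neighbourhood loops) on
random grids to 1e−9 relative tolerance.

Feature names are `<filter>__<family>__<feature>`, e.g.
`gradient__ngldm__dependence_count_energy`. The default bank is a
documented, self-consistent set — it does not attempt to reproduce the
777-feature bank of any commercial package.

## Feature selection

Two univariate screens applied to the training cohort: (1) drop features
with unbiased sample variance < 0.1 on the raw scale (a near-constancy
screen — meaningful only as such, since raw variance is scale-dependent;
this caveat is recorded in the selection report); (2) discretize each
survivor into 10 equal-frequency bins and keep features whose plug-in
mutual information with the class label (in nats) is ≥ 0.19. Keeping
high-MI features is the reading consistent with retaining the *most
informative* predictors; the opposite direction is available via
`drop_high_mi=True`. Selection is deterministic and idempotent; fewer cases
than bins reduces the bin count with a warning.

The pipeline applies selection once, globally, before cross-validation —
mirroring how such studies report a single predictor list. This is a known,
deliberate simplification: selection inside each CV rotation would be the
stricter guard against selection bias, and the permutation-null checks
(below) quantify that the optimism from global screening is small at this
feature-to-case ratio when the screens are label-blind (variance) or when
labels are permuted before the screen.

## Rebalancing and ensembles

ADASYN (β = 1, k = 5) oversamples the minority (malignant) class inside
each training split only: `G = (m_l − m_s)β` synthetic targets are
distributed over minority points in proportion to the fraction of majority
points among each point's k nearest neighbours (uniform when all
neighbourhoods are minority-pure), and each synthetic point is
`xᵢ + λ(x_z − xᵢ)` with λ ~ U(0,1) and `x_z` a random minority neighbour.
Originals are preserved; with the 102/40 design, G = 62.

Three ensemble kinds, each 16 members diversified by bootstrap resampling
with per-member seeds (the minimal assumption that makes majority voting
meaningful): random forests (Gini criterion, 50 trees per member), and
SVM / k-NN members behind a standardize → PCA (95% variance) → Fisher
Discriminant Ratio ranking → top-10-component chain fitted on the training
data only. Prediction is by majority vote; an exact 8–8 tie goes to the
malignant class (the clinically conservative default, configurable). The
continuous score is the mean member positive-class probability (SVM
decision values pass through a logistic map).

## Evaluation

Nested 4-fold stratified CV: rotation *r* tests fold *r*, validates fold
*r+1 (mod 4)*, trains on the rest, so each fold is internal-tested exactly
once. ADASYN, standardization, PCA and FDR ranking are fitted per rotation
on the training folds only (verified by a tamper test: altering test-fold
values changes no fitted parameter).

Six metrics on the percent scale: ROC-AUC (rank-based, ties averaged),
accuracy, sensitivity, specificity, PPV, NPV. The positive class is
explicit (default malignant) and both orientations of any confusion matrix
are reported. Internal testing is summarized two ways: the *mean* over the
64 member × rotation values, with normal-approximation 95% CIs and
one-sided Wilcoxon signed-rank p-values against chance levels (50 for
AUC/accuracy/sensitivity/specificity; the design prevalences 72/28 for
PPV/NPV) — 64 member-level samples are used because 4 rotation-level values
cannot reach small signed-rank p-values; and the *majority vote* of the
pooled per-case predictions. External testing pools all 4 rotation
ensembles (64 members) per case. Proportion CIs are Wilson intervals; the
external AUC CI uses the Hanley–McNeil approximation; the CI method is a
package choice recorded per cell. The best model is the argmax of internal
mean ROC-AUC (ties: majority-vote AUC, then model order).

Univariate feature statistics: per-feature class medians with
distribution-free binomial order-statistic 95% CIs, two-sided Mann–Whitney
U (exact for small tie-free samples, tie-corrected normal approximation
otherwise), Bonferroni–Holm step-down adjustment over the selected set, and
significance stars at 0.05 (*) and 0.005 (**).

## Numerical and degenerate-input choices

Constant ROIs: discretization maps to level 1; histogram entropy 0;
quartile coefficient 0 (warned when `P75 + P25 = 0` with unequal
quartiles); GLCM correlation 1; NGTDM coarseness capped at 10⁶, complexity
0; Mann–Whitney p = 1 for constant features. The signed-rank test drops
zero differences and returns p = 1 when none remain. Bootstrap resamples
are redrawn until both classes are present. All randomness flows from one
global seed through named substreams (`numpy.random.SeedSequence`), making
every output table reproducible byte-for-byte.

## Problem sizes

Tests and the acceptance script run the study at desk scale: 128×128 images
with ROI semi-axes 15–30 px (and 64×64 for the smallest unit fixtures),
keeping the default class design (102/40 + 15/6) and default malignant
effect sizes. The 256×256 default remains the generator's reference
geometry. Permutation-null checks use 5–20 permutation seeds; the
end-to-end recovery check uses 10 cohort seeds.

## Known limitations

* The texture generator is a first-order speckle approximation; absolute
  feature values are not comparable to any scanner's output.
* Global (pre-CV) feature selection, as discussed above.
* The feature bank is a documented superset of the families needed by the
  study design, not a reconstruction of any proprietary bank.
* 2D only; no shape/morphology features (the study design's predictor list
  contains none).
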