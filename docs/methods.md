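# Methods

`pkdrad` implements a CT-radiomics analysis pipeline for autosomal dominant
polycystic kidney disease (ADPKD): grey-level co-occurrence (GLCM) texture
features computed from kidney-parenchyma ROIs, clinical renal endpoints
derived from serum creatinine series, a univariate screening/decorrelation
feature-selection cascade, and logistic classification models validated
with a battery of small-sample procedures. A synthetic phantom-cohort
generator makes every stage testable end to end without patient data.

## Imaging and ROI

Volumes and masks are NIfTI images on a shared grid; arrays are indexed
`(slice, row, col)` with axis 0 along the scanner z-axis, which defines the
2D planes for texture. Left and right kidney masks are merged with a
voxelwise OR; the ROI is the set of foreground voxels with their HU values.
No resampling is performed — features are computed on the grid as stored,
with voxel spacing used only by morphology. Mask values are thresholded at
0.5 (with a warning for non-binary files) so fractional masks from external
resampling are ingested without silent reinterpretation. Exclusion of the
renal hilum and pelvis is the segmenter's responsibility; masks are treated
as ground truth.

## Texture features

Grey levels default to *no discretization*: HU values are rounded and
re-indexed to `1..Ng`, so `Ng` is data dependent. `fixed_bin_size` (bin
width in HU) and `fixed_bin_count` are available and are the recommended
choice when robustness across scanners matters, because undiscretized CT
noise inflates `Ng` and thins the co-occurrence matrices.

Co-occurrence matrices are built per slice at distance 1 voxel for the four
in-plane Chebyshev directions, always symmetric (each pair counted in both
orientations, so the row and column marginals coincide). Four aggregations
are emitted, named by prefix:

| prefix | aggregation |
|---|---|
| `F_cm` | feature per (slice, direction), averaged |
| `F_cm_merged` | directions merged per slice, feature per slice, averaged |
| `F_cm_25d` | slices merged per direction, feature per direction, averaged |
| `F_cm_25d_merged` | all matrices merged, single feature |

The suite comprises joint maximum/average/variance/entropy, angular second
moment, contrast, dissimilarity, inverse difference, correlation and
cluster tendency. Correlation is the normalized covariance of co-occurring
levels, clamped to [-1, 1]; a degenerate matrix (zero marginal variance,
e.g. a flat ROI) returns 1 by convention — a perfectly uniform region is
maximally self-correlated. Cluster tendency is
`sum_{ij} (i + j - 2 mu)^2 p(i,j)`, which for a symmetric matrix equals
`2 sigma^2 (1 + rho)` in level units: it is *large* for regions whose
in-plane variance is high, and falls when fine-grained variance is replaced
by spatially coherent structure. Slices/directions yielding no valid pair
are excluded from merges and averages; if every matrix is empty the feature
is recorded as missing.

Intensity features use population moments (variance, skewness, excess
kurtosis, percentiles, energy, RMS, mean absolute deviation). Morphology
counts exposed voxel faces for surface area, from which sphericity
`pi^(1/3) (6V)^(2/3) / A` is derived, plus principal-axis elongation and
flatness from the coordinate covariance eigenvalues. Cohort feature tables
are z-scored per column with the sample (n-1) SD; constant columns are
dropped with a warning.

## Renal endpoints

eGFR comes from the CKD-EPI creatinine equation; the 2009 form without the
race coefficient is the default (appropriate to a European cohort), with
the 2021 race-free refit selectable. Baseline class is *late* CKD when
baseline eGFR < 60 mL/min/1.73 m² (60 itself is early). The per-patient
eGFR slope is the OLS slope of eGFR on time in years, restricted to
patients with ≥ 3 creatinine values spanning ≥ 6 months; exclusions are
reported with reasons. A patient is a *rapid progressor* when the decline
exceeds 3 mL/min/1.73 m²/year, i.e. fitted slope < -3 (exactly -3 is
non-rapid). An age/ht-TKV risk class (1A–1E) is provided from theoretical
growth trajectories 150·(1+r)^(age-20) mL/m for r in {1.5, 3, 4.5, 6}%/yr,
as an external-reference implementation for labelling synthetic cohorts.

## Feature selection

Per feature: two-sided Wilcoxon–Mann–Whitney between the two endpoint
classes (exact p by enumeration when the pooled n ≤ 12 with no ties, else
the tie- and continuity-corrected normal approximation), then
Benjamini–Hochberg at alpha 0.05. The candidate set consists of the
significant features tied at the lowest adjusted p when rounded to four
decimals (reporting precision). Among candidates, the selected feature is
the one with the lowest mean absolute Pearson correlation with the others;
when exactly two candidates are near-duplicates (|r| ≥ 0.95, e.g. two
aggregations of the same statistic) the one with the lower raw p is kept.
The 0.4 Pearson threshold is reported against the selected feature's mean
|r| with a warning when exceeded; the argmin rule is the operative
selection. An empty screen is an explicit status, never a silent fallback.
The one-to-ten events-per-variable rule bounds model size
(`floor(min(events, non-events)/10)`, at least 1) and raises a warning when
a requested model exceeds it.

## Models and validation

Logistic regression is fitted by IRLS on internally standardized
covariates (convergence when the max coefficient step < 1e-8, at most 100
iterations). A standardized coefficient exceeding 15 in absolute value
flags complete/quasi-separation; the coefficients are capped there and the
metrics are still computed from the capped fit. Validation battery:

- **Calibration**: refit the outcome on the model's linear predictor with
  free intercept and slope; likelihood-ratio test of (0, 1), 2 df
  chi-square. In-sample this is exact (statistic 0, p 1); it has power on
  external or resampled data.
- **Discrimination**: Mann–Whitney AUC (equals the trapezoidal ROC area);
  95% CI by class-stratified percentile bootstrap with B = 2000.
- **Model comparison**: paired DeLong test from placement values;
  identical rankings yield zero variance and are reported as p = 1.
- **Operating point**: Youden's J over observed score thresholds with the
  rule "positive iff score ≥ threshold", ties toward the lowest threshold
  (favouring sensitivity). Accuracy, sensitivity (positive class = late
  CKD / rapid progressor) and specificity carry Jeffreys
  Beta(x+1/2, n-x+1/2) 95% intervals, with the conventional 0/1 limits at
  the boundaries.
- **Internal validation**: stratified 3-fold CV repeated 5 times, Youden
  threshold chosen on each training fold, test predictions pooled per
  repetition, summary = mean/SD over repetitions; and (for the progression
  models) a bootstrap "average model": B = 1000 class-stratified
  resamples, refit each, exclude separation-flagged replicates (counted),
  average the coefficients and evaluate the averaged model on the full
  cohort.

A note on the Jeffreys interval: its exact frequentist coverage oscillates
with (n, p); at n = 26 it is 0.949 at p = 0.3 but 0.925 at p = 0.5 and
0.896 at p = 0.9 (identical numbers are obtained from the statsmodels
reference implementation). This is a property of the interval, not of the
implementation, and is inherited by any analysis that relies on it at
small n.

## Synthetic phantom cohort

One latent severity `s ~ N(0,1)` per patient drives every observable:
`ln(ht-TKV) = ln 900 + beta_tkv·s + noise` (mL/m); baseline
`eGFR = 100 - (age-40) - beta_egfr·s + noise`, clipped to [5, 120] (values
above ~128 are unreachable by CKD-EPI inversion for older women); texture
heterogeneity `h = logistic(beta_texture·s + noise)`; true slope
`-(1.5 + beta_slope·h) + noise`. Visit-level eGFR adds measurement noise
on a schedule of 5 visits at 4.6-month intervals (span 18.4 months), and
serum creatinine is obtained by bisection-inverting the CKD-EPI equation
(tolerance 1e-8 on [0.2, 20] mg/dL), so the clinical table round-trips
exactly through the endpoint derivation. Defaults: n = 58, beta_tkv 0.5,
beta_egfr 70 (gives a late-CKD fraction of roughly 0.16–0.38 across
seeds), beta_texture 1.5, beta_slope 3, age ~ N(47, 11) truncated to
[25, 75], 45% male. A configurable number of patients receive only two
creatinine values, reproducing the eligibility-filter structure (e.g. 58
generated, 51 analyzable).

Phantoms are two ellipsoidal kidneys (default semi-axes 30×25×16 mm on a
48×96×96 grid at 1.5×1×1 mm) whose size scales with the patient's ht-TKV.
The parenchyma field mixes fine speckle (weight falling with `h`), an
in-plane smooth structural field and a slice-wise drift (weight rising
with `h`), rank-remapped to an exact Gaussian marginal (mean 35 HU, SD
12 HU): the histogram of a cyst-free phantom is thus identical across `h`
and heterogeneity lives purely in the spatial arrangement, which is what
co-occurrence features measure. Spherical fluid cysts (lower HU, nearly
uniform) grow in number, size and contrast with `h`. Consequences, tested
as invariants: `F_cm.corr` increases and `F_cm_merged.clust.tend`
decreases with `h`.

What the generator does *not* emulate: scanner noise physics and dose
modulation, contrast phases, anatomically realistic kidney and cyst
geometry, partial-volume effects at cyst walls, or inter-observer
segmentation variability. Passing tests therefore demonstrate that the
pipeline recovers a planted texture–outcome association under controlled
conditions, not that the specific features are biomarkers in real ADPKD
cohorts.

## Problem sizes in the test suite

Tests use a reduced phantom grid (24×48×48, semi-axes 14×12×8 mm) and
reduced bootstrap sizes (B = 100/50) so the full suite runs in minutes;
the texture-oracle and statistical-calibration checks run at the sizes
stated in their docstrings (50 random images, 2000-replicate type-I-error
runs, 500-replicate coverage runs). The end-to-end recovery test uses 20
cohorts of n = 150 with a dominant texture effect (beta_texture 2.0,
sd_texture 1.5, beta_slope 4.0, sd_slope 0.5, measurement SD 1.5,
cyst-free phantoms) chosen from a latent-variable Monte Carlo as
conditions under which texture, not kidney volume, carries the progression
signal. `scripts/acceptance.py` runs the full study (n = 58, full-size
phantoms, B = 2000/1000); at n = 51 a cohort can draw so weak a latent
coupling that the FDR screen retains nothing — such cohorts are not
analyzable and the script draws the next seeded cohort instead.

## Known limitations

- With no discretization the effective `Ng` of a real CT ROI is large;
  matrices are accumulated densely per slice, which is fine at phantom
  sizes but a bin-width discretization is advisable for large ROIs.
- Which exact aggregation the field's `F_cm` vs `F_cm_merged` prefixes
  denote varies between toolkits; here `F_cm` = per-(slice, direction)
  averaging and `F_cm_merged` = per-slice direction merging, and both
  2.5D variants are also emitted so any mapping can be tested.
- The repeated CV reuses the globally selected feature rather than
  re-running selection inside each fold; the optimism this induces is the
  documented trade-off of following the sequential recipe.
- The calibration test is the recalibration likelihood-ratio test; a
  Hosmer–Lemeshow-style alternative is deliberately not the default.
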