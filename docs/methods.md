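# Methods

This note documents the models, parameter choices and numerical
conventions of `cemradial`, and what the synthetic cohort can and cannot
establish about real contrast-enhanced mammography (CEM) data.

## Radial-distribution features

**Center of mass.** The intensity-weighted mean pixel coordinate of the
density image restricted to the hand-drawn contour. Pixel coordinates
are 0-based row/column indices with pixel centers at integer positions;
the contour mask includes a pixel when its center is inside or on the
polygon (boundary-inclusive; rasterization uses exact geometric
coverage tests, equivalent to the even-odd rule for the simple polygons
accepted). A contour with fewer than three vertices or zero area is
rejected; an all-zero masked region raises a degenerate-input error
rather than returning a silent centroid.

**Radial histogram.** Band edges partition `[0, r_max]` into B
equal-width half-open intervals (last band closed), with `r_max` the
distance from the center to the farthest image-corner pixel. Each pixel
joins the band containing its center-to-center distance; per-band mass
is the intensity sum and per-band area the empirical pixel count, which
correctly handles annuli clipped by the ROI boundary. The per-area
profile is rescaled to unit sum so findings are comparable regardless
of exposure; an area-only mode (`normalize="area"`) is available since
the exact normalization chain is a genuinely open design point. Before
rescaling, the band masses sum exactly to the total image intensity
(exact in the integer-valued image domain).

Defaults and rationale:

- **B = 32 bands** (configurable). The properties of the pipeline hold
  across B ∈ {8, 16, 32, 64}; 32 gives sub-3-pixel band widths on a
  300-px ROI without producing empty bands.
- **Per-case `r_max`** (relative-radius bands) so every histogram has
  length B despite different centers; a fixed-pixel `r_max` can be
  passed explicitly.
- **Empty bands get value 0 with a logged warning** rather than an
  error, so large B on small images degrades gracefully.
- **Full-ROI support**: the contour is used only for the center; a
  contour-restricted mode exists but is not the default, because the
  discriminating signal includes the tissue immediately around the
  finding.
- The density-derived center is reused for the contrast channel (the
  two CEM channels are assumed co-registered), and concatenated
  features keep each channel's own unit sum (no cross-block
  renormalization).

## Penalized LDA and cross-validation

The classifier is ridge-penalized Fisher LDA:
`w = (S_w + λI)⁻¹(μ₊ − μ₋)` with `S_w` the pooled within-class scatter
normalized by n − 2. The decision threshold is the projected-mean
midpoint shifted by the log prior odds; ties go to the negative class.
λ = 0 with p ≥ n is refused with a message instructing a positive
penalty. As λ → 0 on well-conditioned data the direction converges to
the classical Fisher solution (verified to 1e−4 relative at λ = 1e−10);
as λ → ∞ it aligns with the class-mean difference.

Evaluation uses stratified 5-fold × 5-repetition cross-validation.
λ is selected per training split by inner 3-fold CV over the grid
10^{−4..2} (7 log-spaced points, ties to the smaller penalty). Fold
layouts depend only on the labels, fold counts and seed, so different
feature sets evaluated with one seed share fold assignments and their
25 fold accuracies support a paired two-sided t-test. An optional
Nadeau–Bengio variance correction accounts for the overlap of training
sets across repetitions; the plain paired test is the default summary.
Summary metrics (sensitivity, specificity, F1, Cohen's kappa) are
computed from pooled out-of-fold predictions per repetition and
averaged; the headline accuracy is the fold-size-weighted mean of the
25 fold accuracies (pooled-per-repetition accuracy is retained in the
summary for comparison). Single-class truth leaves the undefined rate
as NaN, never 0.

The chance baseline trains the identical pipeline on once-permuted
labels, reproducing the slightly-below-majority empirical rate of a
classifier fit to pure noise — a more faithful null than a coin flip.

## Clinical models

Odds-ratio regressions code the covariates dichotomously: White vs. all
other races, non-dense (fatty/scattered) vs. dense, BPE minimal or
moderate vs. marked, pre- vs. post-menopausal; age is continuous in
years. Univariable mode fits one model per covariate; multivariable
mode fits all six jointly. CIs are Wald intervals on the log-odds scale
(`exp(β ± 1.96·SE)`); perfect separation is flagged and coefficients
are kept finite with a weak ridge, with CIs reported as NaN rather than
fabricated.

Predictive models combine the clinical covariates (without BPE) with
the continuous cross-validated imaging discriminant score, averaged
over repetitions; passing in-fold scores is an error by construction.
The headline AUC comes from out-of-fold predicted probabilities of the
logistic model itself (5-fold, seeded); the apparent in-sample AUC is
reported alongside. AUC uses the Mann–Whitney identity with half-count
ties, which equals the trapezoidal ROC integral to machine precision.
AUC differences use the paired DeLong test on placement-value
covariances (statistic 0 and p = 1 for identical scores); a seeded
2000-resample bootstrap is the fallback when the variance estimate
degenerates. The DeLong p-value is uniform under the null within
Kolmogorov–Smirnov tolerance at 500 replicates.

## Synthetic cohort generator

The generator is the test bed for the entire pipeline and encodes the
study conditions directly:

- **Class mix** 70 benign : 10 high-risk : 8 atypia : 71 malignant per
  159 findings, allocated deterministically by largest remainder
  (multinomial draws behind `exact_mix=False`); 51/71 of malignant
  findings are invasive.
- **Lesion model**: isotropic radial profile `A·exp(−d·r)` on a 300-px
  ROI, parameterized by the total integrated lesion mass, so
  `A = mass·d²/2π`. A faster decay therefore means the *same* lesion
  burden concentrated closer to the center — this is what makes the
  malignant central fraction strictly larger, not a brightness
  difference. Defaults: `d` = 0.04/px benign (and high-risk/atypia,
  generated benign-like to exercise exclusion logic), 0.08/px
  malignant, +0.04/px extra for invasive disease on the density
  channel only (density alone is designed to carry the invasiveness
  signal). An anisotropy factor is exposed, default 1.
- **Per-case, per-channel lognormal decay jitter** (sd 0.35 on the log
  scale) creates within-class variability and, because the two
  channels jitter independently, gives the concatenated features
  genuinely complementary information — the mechanism behind the
  expected ordering concatenated ≥ density > chance.
- **Intensity scale**: 16-bit range, density background mean at 20% of
  full scale (contrast at 8%), low-frequency Gaussian-filtered
  background texture (correlation length 1/8 of the ROI) scaled on the
  contrast channel by the BPE category (×1.0/1.6/2.6), additive pixel
  noise (sd 1500), clipped to [0, 65535] and quantized — so written
  TIFFs round-trip bit-identically. `contrast_snr` (default 4) fixes
  the benign-decay lesion amplitude on the contrast channel relative
  to the texture amplitude.
- **Contours**: the half-maximum isocontour of the noiseless kernel,
  polygonized at 64 vertices and clipped to the image — a stand-in for
  hand-drawn contours, adequate because only the enclosed center of
  mass is consumed downstream.
- **Covariates**: ages are class-conditional equal-variance normals
  (sd 12 y, non-malignant mean 52 y) whose malignant shift
  `log(OR)·sd²` makes the log-odds of malignancy exactly linear in age
  with the configured odds ratio (default 1.07/year); menopausal
  status thresholds age plus noise at 51.5 y; race, history, breast
  density, BPE and finding category are drawn from the reference
  cohort's frequencies, independent of class.
- **Determinism**: the seed stream is split per stage and per case, so
  identical configurations give bit-identical cohorts regardless of
  consumption order.

What the generator does **not** emulate: real lesion morphology
(spiculation, irregular margins, calcification patterns), craniocaudal/
mediolateral view geometry, dual-energy physics, inter-reader contour
variability, covariate–covariate structure beyond the age–menopause
link, and any dependence of breast density or BPE on malignancy.
Passing tests therefore demonstrate that the pipeline recovers the
structure it assumes when that structure is present — not that real CEM
findings carry it; synthetic accuracies and AUCs are higher than one
should expect on clinical data.

## Problem sizes

The test suite and the acceptance script run the full pipeline on
159-finding, 300-px cohorts (the reference scale) for the ordering,
determinism and report checks, averaging 3–20 seeds where a mean is
asserted; oracle-equivalence checks use exhaustive brute-force loops on
images up to 32×32; covariate-link recovery uses n = 2000. Smaller
ROIs (64–128 px) are used where only relative structure matters.

## Known limitations

- The penalized-LDA variant is ridge-penalized scatter; sparse/fused
  penalties are out of scope.
- Wald CIs are first-order; profile-likelihood intervals are not
  implemented.
- The bootstrap fallback for AUC comparison resamples cases, not
  repetitions, and so ignores CV-induced score dependence.
- High-risk and atypia findings are excluded from the primary task by
  default (`include_atypia_as_benign=True` pools atypia with benign).
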