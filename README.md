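# cemradial

Quantitative analysis of contrast-enhanced mammography (CEM) findings:
radial-distribution features around a lesion's center of mass, penalized
linear discriminant classification of malignant vs. benign (and invasive
vs. non-invasive) findings under repeated cross-validation, and logistic /
AUC-ROC models that combine the imaging score with clinical covariates.

## The problem

A CEM exam produces two co-registered grayscale images per finding: a
low-energy image that looks like a standard mammogram (the **density**
channel) and a recombined image showing iodinated-contrast uptake (the
**contrast** channel, a proxy for lesion vascularity). Radiologists
annotate each suspicious finding with a rectangular ROI crop and a
hand-drawn contour. The question for computer-aided diagnosis: do simple,
interpretable descriptors of how density and contrast are distributed
around the lesion center discriminate malignant from benign findings —
and does combining the two channels, or adding clinical covariates, help?

## The method

For each finding the pipeline computes the intensity-weighted **center of
mass** of the contour-masked density image,

    c = Σ_p I(p) · p / Σ_p I(p),

lays B concentric equal-width annuli ("bands") around it out to the
farthest ROI corner, and forms the **radial histogram**: per-band summed
intensity divided by the band's pixel area, rescaled to unit sum. Density
and contrast histograms share the density-derived center and can be
concatenated into a 2B-vector.

Classification uses **penalized LDA**: the discriminant direction

    w = (S_w + λI)⁻¹ (μ₊ − μ₋)

with S_w the pooled within-class scatter — ridge regularization handles
the strong correlation between neighboring bands. Accuracy is estimated
by stratified 5-fold × 5-repetition cross-validation (λ tuned by inner
3-fold CV), feature sets are compared by paired t-tests over the 25
shared fold accuracies, and an empirical chance baseline re-runs the
identical protocol on permuted labels. Clinical covariates (age, race,
personal history of breast cancer, menopausal status, breast density,
background parenchymal enhancement) enter univariable/multivariable
logistic models with Wald odds-ratio CIs; predictive models combining
the cross-validated imaging score with covariates are compared by
AUC-ROC with the DeLong test.

Because clinical CEM archives are not publicly deposited, the package
includes a first-class synthetic cohort generator that emulates the
structure the analysis relies on: malignant lesions concentrate the same
lesion mass closer to the center (faster radial decay), invasive
malignancies decay faster still on the density channel only, background
parenchymal texture scales with the BPE category, and the odds of
malignancy rise by a configurable factor per year of age (default 1.07).

## Worked example

`python examples/03_classify_lesions.py` (100 synthetic findings,
128-px ROIs, 16 bands) prints:

```
retained 89/100 cases (dropped: {'high_risk': 7, 'atypia': 4})

      density: accuracy 88.09%  sens 0.831  spec 0.932  F1 0.876  kappa 0.762
     contrast: accuracy 78.88%  sens 0.653  spec 0.927  F1 0.757  kappa 0.579
 concatenated: accuracy 94.83%  sens 0.898  spec 1.000  F1 0.946  kappa 0.897
     permuted: accuracy 52.58%  (chance-level baseline)

concatenated vs density: mean diff +6.72 points, t(24) = 4.66, p = 0.0001
```

High-risk and atypia findings are excluded from the malignant-vs-benign
task. Both single channels classify far above the permuted baseline, and
concatenating density and contrast significantly improves on density
alone — the qualitative ordering the method is designed to expose. The
other examples cover cohort simulation, class-average radial profiles,
odds-ratio/AUC models, and the end-to-end report bundle.

A thin CLI wraps the same functions:

```bash
cem-radial simulate --n-findings 60 --out cohort/
cem-radial classify cohort/manifest.csv --feature-set concatenated
cem-radial report --out report/
```

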