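# Methods

`ofrad` implements an end-to-end pipeline for predicting out-of-field
recurrence (OFR) of locally advanced cervical cancer within 36 months of
concurrent chemoradiotherapy (CCRT), from pretreatment MRI radiomics combined
with para-aortic lymph-node (PALN) status. Because the clinical imaging data
this kind of study rests on is private and multi-institutional, the package
ships a synthetic phantom cohort generator that reproduces the statistical
structure the analysis assumes, so that every stage — feature extraction,
selection, model fitting, evaluation — can be exercised and validated on
self-contained data.

## The prediction problem

The event is OFR within 36 months of treatment start; patients followed
beyond 36 months without OFR are non-events, and OFR-free survival treats
later follow-up as censoring. Deaths without OFR are censored at last
follow-up (the alternative — treating death as an event — changes the
estimand; censoring is the package's default and only behaviour). The
clinical predictor is PALN status at treatment initiation; the imaging
predictors are radiomic features of the segmented primary tumour.

## Synthetic cohort generator

`CohortConfig` defaults encode the study conditions:

* 180 patients across 13 institutions (three large sites with >20 patients,
  the rest ~10 each; two institutions, "H" and "J", carry no events and are
  therefore never eligible as held-out test sites in institution-wise
  validation);
* PALN prevalence 21/180; P(OFR | PALN+) = 12/21; P(OFR | PALN−) = 26/159 —
  the printed contingency structure;
* covariates drawn from published marginal ranges (age 29–80 years, tumour
  diameter 2.2–17.2 cm, volume 3.0–557.4 ml, performance status, histology,
  nodal classes, treatment doses);
* event times uniform on (1, 36) months and non-event follow-up uniform on
  (36, 96) months — the uniform choice is non-informative with respect to the
  features, since no time distribution is published;
* zero-event institutions are realized by assigning event patients only to
  event-eligible institutions, which preserves the configured conditional OFR
  probabilities exactly (post-hoc zeroing of events would bias them).

Each patient's tumour is an ellipsoid (log-normal axis ratios, volume matched
to the clinical record within 10%) of base intensity 100 over background 20,
on a 64³ grid of 2 mm isotropic voxels. The interior texture is a Gaussian
random field: white noise smoothed with a Gaussian kernel of width
`texture_base_sigma` = 0.8 voxels and rescaled to SD 15. For OFR cases the
kernel width and field SD are inflated by factors (1 + e) and (1 + e/2)
respectively, where `e = texture_effect_size`; the correlation-length shift
is the planted, normalization-invariant signal that gray-level texture
statistics (GLCM correlation, run/zone sizes, busyness) can detect. The
default effect size is 0.75, a moderate signal; e = 0 yields label-free
images and e = 2 a strong planted signal (used for the planted-signal
validation). Institution effects are affine intensity distortions (scale
log-normal with σ = 0.15, offset normal with σ = 10 intensity units) plus
additive noise — exactly the nuisance that ROI-restricted normalization is
meant to absorb.

What the generator does **not** emulate: MRI physics (coil profiles, bias
fields, k-space artifacts), anatomy, inter-observer contour variability, and
any *real* association between imaging texture and recurrence. Passing tests
on these phantoms therefore demonstrate that the pipeline recovers planted
signal and does not invent absent signal — not that radiomics predicts
recurrence in patients.

## Image preparation

* Resampling to 2×2×2 mm voxels: trilinear for images, nearest-neighbour for
  masks, over the original extent.
* Wavelet bank: single-level undecimated (stationary) separable 3D transform
  with `coif1` analysis filters, symmetric (mirror) boundary handling, eight
  sub-bands labelled L/H per axis in (x, y, z) order plus the original image
  under band code `ROI` — nine images per sequence, all on the original grid
  so one mask serves every band. Internally the volume is mirror-padded by
  the filter length and filtered circularly; because the conjugate-quadrature
  pair satisfies |H(ω)|² + |G(ω)|² = 2, synthesis-filtering each sub-band and
  halving per axis reconstructs the input exactly (tested to < 1e−8).
* Normalization is applied **per band after** the wavelet transform (the
  nine images are normalized, not the input), ROI-restricted, in two
  variants: min–max to [0, 1] and z-score with population SD. Both are
  invariant to positive affine transforms of the raw image, which is the
  stated rationale for normalizing multi-institutional data at all.
* Gray levels: equal-width binning of ROI intensities into 32 levels
  (`level = min(floor((v−min)/(max−min)·Ng)+1, Ng)`); the bin count is a
  registry parameter. Constant-intensity bands are flagged and take explicit
  degeneracy conventions (correlation 0, busyness 0, skewness 0) rather than
  being imputed.

## Feature set

The registry makes the feature composition explicit: per band — Mean,
Variance, Skewness, Energy (Σv², the binding chosen for "Energy"),
GLCM correlation from the direction-merged matrix (`GCorrelation1`) and
averaged over per-direction matrices (`GCorrelation`), GLRLM run-length
variance (`RLV`), seven GLSZM statistics (LZE, ZLV, GLV, SZLGE, LGZE, LZLGE,
LZHGE), and NGTDM busyness — 15 × 9 bands = 135 features; plus four shape
features (Volume, SurfaceArea, Max3Ddiameter, SpheDisproportion), 139 per
sequence and normalization. Texture matrices pool the 13 unique 3D
directions; zones and neighbourhoods use 26-connectivity. Surface area is
measured on a marching-cubes mesh of the lightly smoothed mask (the raw
binary staircase overestimates a sphere's area by ~9%);
`SpheDisproportion = A / (4πr²)` with `r = (3V/4π)^{1/3}`. Every texture
statistic is verified against brute-force enumeration oracles on randomized
small volumes, exactly.

## Feature selection

Two routes, as in the study design:

* **LASSO-embedded**: the sparse model selects features itself; per-fold
  nonzero-coefficient sets are reported with stability counts (how many of
  the 5 folds selected each feature).
* **Survival-informed ranking** (for Ridge / naive Bayes / random forest):
  each feature is median-split (ties to the low group), groups are compared
  by log-rank test on OFR-free survival, features are ranked by ascending p
  (ties broken by name — the "decreasing p-value" phrasing in the source
  literature is read as ranking by significance, the only reading that keeps
  predictive features), then a greedy pass drops candidates with |Pearson r|
  > 0.7 against any kept feature, stopping at 10. Spearman is available by
  flag.

On planted designs with correlated decoys (r ≈ 0.9), a decoy carries ~90% of
the original's effect, so no selector can reliably rank the pristine original
above its own noisy copy; the property the pruner does guarantee — and the
one we validate at ≥90% — is that the kept set contains exactly one
representative of every planted signal cluster.

## Models

All families predict OFR within 36 months from standardized features
(standardization learned on training folds only). Class imbalance is handled
with balanced weights `w_c = n/(2n_c)` multiplying each sample's loss.

* **Penalized logistic regression** (the core estimator, authored in-package):
  objective `(1/n) Σ w_i ℓ_i + λ‖β‖₁` (LASSO) or `+ (λ/2)‖β‖₂²` (Ridge),
  intercept unpenalized. λ is chosen by leave-one-out weighted log-loss over
  50 grid points log-spaced on [1e−4, 1e+2], ties to the larger λ. The
  solver is batched FISTA: all n leave-one-out subsets plus the full
  training set share the design matrix, so one proximal-gradient iteration
  updates every model with two matrix products; the path is solved from
  large λ down with warm starts, an active-set/KKT loop for l1, and an
  intercept-only shortcut above the critical λ. Coefficient tolerance 1e−4
  (the λ chosen is insensitive to tightening this to 1e−6; fixed-λ fits are
  verified against scikit-learn's liblinear to ~1e−3).
* **Gaussian naive Bayes** with weighted class priors (balanced weighting
  makes them ½, ½); zero-variance features are floored by variance smoothing
  and flagged.
* **Random forest**: 500 Gini trees, √p features per split, seeded,
  out-of-bag probabilities available.

Designs: `clinical_only` (the PALN indicator, fitted with Ridge),
`radiomics_only`, `combined` (PALN + features).

## Survival analysis

Kaplan–Meier, log-rank and Cox proportional hazards are implemented
in-package (cross-checked against `lifelines` in the test suite): Cox uses
Newton–Raphson on the Breslow partial likelihood (gradient norm < 1e−8, ≤100
iterations, step halving); monotone likelihoods are detected by coefficient
capping at |β| = 20 on the standardized scale and flagged. Breslow is the
only tie rule — the generator produces continuous times, where Breslow and
Efron coincide. The prognostic screen dichotomizes each clinical variable at
its published cut (age 56, diameter 5.1 cm, volume 33 ml, whole-pelvis dose
50 Gy, point-A dose 24.2 Gy, ...), reports per-stratum 3-year OFR-free
percentages read off the KM curve at month 36, a per-variable log-rank p and
one multivariate Cox fit; the selected clinical predictor is the variable
significant in both.

## Evaluation

* `fivefold`: label-stratified, reshuffled up to 10 times if a training fold
  lacks a class. Selection and standardization are re-run inside each
  training fold (leakage-free; a `global_selection` switch exists for the
  literal single-pass reading).
* `leave_one_institution_out` and `three_institution_holdout` (each >20-
  patient site held out once; the five inner fold-models' probabilities are
  averaged on the held-out site). Zero-event institutions always stay in
  training.
* ROC: AUC by the Mann–Whitney rank formulation with tie correction, per
  fold (mean ± SD) and pooled over out-of-fold probabilities — the dotted
  (per-fold) vs solid (aggregate) distinction.
* Threshold metrics at probability 0.5; undefined rates reported as NaN.
* Continuous (category-free) NRI and IDI, both **new minus reference**, with
  seeded 2000-resample bootstrap percentile CIs and two-sided bootstrap
  p-values. (A negative published NRI/IDI alongside an AUC improvement is a
  sign-convention question; this package fixes new-minus-reference and makes
  no attempt to mirror other conventions.)
* Harrell's C-index of the out-of-fold probability against OFR-free survival
  (ties 0.5), and risk-group KM curves split at probability 0.5 with a
  log-rank comparison.

## Validation problem sizes

The package's own acceptance checks run at: null and planted-signal cohorts
of 200 patients (64³ voxel phantoms, full volume range) under 5-fold CV with
the LASSO radiomics model; ten paired combined-vs-clinical replicates at 96
patients (48³ voxels, volumes ≤180 ml, effect size 1.5); 2000 null
replicates (n=100) for log-rank calibration; n=2000 for Cox hazard-ratio
recovery; 100 random ≤6³ volumes for texture-oracle equivalence; 30
replicates for selector recovery. The null-cohort AUC is averaged over two
cohorts to keep its sampling SD (~0.035) well inside the ±0.08 acceptance
band.

## Known limitations

* Phantom realism is deliberately minimal (see above); absolute AUC values
  on phantoms say nothing about patients.
* The LOO criterion re-uses class weights computed on the full training
  fold rather than re-deriving them per LOO subset (the weights are part of
  the model specification, not the data split).
* GLCM distance is fixed at 1 by default; multi-distance matrices are not
  pooled.
* The 458-feature count quoted for the original feature bank is not
  decomposed in the source; this registry is explicit (139 per sequence ×
  normalization) and auditable instead of guessing a composition.
* No DICOM ingestion; NIfTI only.
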