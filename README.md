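# ofrad

Prediction of **out-of-field recurrence (OFR)** of locally advanced cervical
cancer after concurrent chemoradiotherapy (CCRT), from pretreatment MRI
radiomics combined with para-aortic lymph-node (PALN) status — implemented as
a tested, reusable pipeline exercised end-to-end on a synthetic phantom
cohort.

The package is for methodologists and imaging scientists who want to study
*how* such a multi-institutional radiomics analysis behaves — leakage-free
cross-validation, survival-informed feature selection, imbalance-weighted
sparse classification, site-wise validation — without access to patient data.

## What it computes

Given tumour volumes with segmentation masks and a clinical table, the
pipeline:

1. resamples image + mask to isotropic 2 mm voxels;
2. builds the 9-image bank of a single-level undecimated 3D wavelet
   transform (8 sub-bands `LLL…HHH` + the original as `ROI`), normalizes each
   band inside the ROI (min–max or z-score), and discretizes to 32 gray
   levels;
3. extracts 139 named features per sequence/normalization: first-order
   statistics, 3D GLCM / GLRLM / GLSZM / NGTDM texture statistics
   (13-direction pooling, 26-connectivity) and shape features, with names
   like `HHHRLV`, `LLHMean`, `SpheDisproportion`;
4. selects features either through the LASSO's own sparsity or by
   Kaplan–Meier ranking: median-split each feature, rank by log-rank p on
   OFR-free survival, greedily prune at |r| > 0.7, keep the top 10;
5. fits class-weighted models — weights `w_c = n/(2 n_c)` — with the penalty
   strength of the penalized-logistic families chosen by **leave-one-out**
   weighted log-loss inside the training cohort:

   minimize over β:  (1/n) Σᵢ wᵢ ℓᵢ(β) + λ‖β‖₁   (LASSO; ½λ‖β‖₂² for Ridge)

6. evaluates by stratified 5-fold CV (per-fold and pooled ROC/AUC,
   accuracy/sensitivity/specificity at probability 0.5), by
   leave-one-institution-out and three-institution holdout, and compares
   models with continuous NRI, IDI (both new − reference, bootstrap CIs),
   Harrell's C-index and risk-group Kaplan–Meier curves split at 0.5.

The synthetic cohort generator plants its signal in the tumour interior: a
Gaussian random field whose correlation length shifts with the outcome, a
contrast that survives per-band intensity normalization and is visible to
texture statistics. Institution effects are affine intensity distortions plus
noise; two institutions carry no events. `docs/methods.md` documents every
model, parameter and convention.

## Worked example

```python
from ofrad.cohort import CohortConfig, simulate_cohort
from ofrad.pipeline import extract_cohort
from ofrad.evaluation import ModelSpec, run_experiment, compare_reports

cfg = CohortConfig(n_patients=80, seed=11, image_shape=(48, 48, 48),
                   volume_range_ml=(3.0, 180.0))
cohort = simulate_cohort(cfg)                       # phantoms + clinical table
features = extract_cohort(cohort, normalization="zscore")

combined = run_experiment(cohort.records, features,
                          ModelSpec("lasso", "combined"), "fivefold", seed=11)
clinical = run_experiment(cohort.records, None,
                          ModelSpec("ridge", "clinical_only"), "fivefold", seed=11)
print(combined.summary())
comp = compare_reports(combined, clinical, cohort.records, seed=11)
```

prints

```
model: lasso / combined  scheme: fivefold
AUC mean +/- SD over 5 folds: 1.000 +/- 0.000   pooled AUC: 1.000
pooled accuracy 1.000  sensitivity 1.000  specificity 1.000  (threshold 0.5)
features selected (folds): paln (5), ROIMean (5), ROIGCorrelation (5), ...
```

and for the clinical-only reference `AUC mean 0.694 +/- 0.106`, with
`NRI +2.000`, `IDI +0.852 [0.746, 0.956]`, `C-index 0.935 vs 0.611`,
risk-group log-rank p ≈ 1e−29. Read: the PALN indicator alone is a fair
predictor (every PALN-positive patient is high-risk, but most events are
PALN-negative); adding radiomic texture recovers the planted signal almost
perfectly. Phantom texture statistics are estimated from thousands of voxels,
so planted effects separate far more cleanly than real MRI ever would — the
interesting regime for validation is `texture_effect_size=0`, where the
cross-validated radiomics AUC must collapse to 0.5.

The same pipeline runs from the shell:

```bash
ofrad simulate --config run.yaml
ofrad extract  --config run.yaml
ofrad select   --config run.yaml
ofrad evaluate --config run.yaml
ofrad report   --config run.yaml     # ROC + KM plots, text summary
```

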