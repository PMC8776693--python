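"""Cross-validation, ROC analysis and model-comparison statistics.

Schemes
-------
* ``fivefold`` — label-stratified random partition; every fold model is
  trained with selection and standardization re-run inside the training fold
  only (leakage-free default; a ``global_selection`` switch mirrors a literal
  single-pass selection).
* ``leave_one_institution_out`` — one split per institution that carries at
  least one event; zero-event institutions always stay in training.
* ``three_institution_holdout`` — each institution with more than 20 patients
  serves once as the test cohort; the remaining institutions are used for
  5-fold model development and the five fold-models' probabilities are
  averaged on the held-out institution.

Comparison statistics follow the threshold-free definitions: continuous NRI,
IDI (both new-minus-reference), and Harrell's C-index of the out-of-fold
probability against OFR-free survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .exceptions import ConfigurationError, DataError
from .models import GaussianNBModel, PenalizedLogit, RandomForestModel, make_design
from .selection import select_features
from .survival import km_estimate, logrank_test

__all__ = [
    "ModelSpec",
    "CVScheme",
    "assign_folds",
    "roc_and_auc",
    "auc_mann_whitney",
    "threshold_metrics",
    "nri",
    "idi",
    "BootstrapComparison",
    "c_index",
    "risk_group_km",
    "EvalReport",
    "run_experiment",
    "institution_holdout_experiment",
    "compare_reports",
]


@dataclass
class ModelSpec:
    """Which classifier family on which design."""

    family: str = "lasso"  # lasso | ridge | naive_bayes | random_forest
    design: str = "radiomics_only"  # clinical_only | radiomics_only | combined
    class_weighted: bool = True
    lambda_grid: np.ndarray | None = None
    n_trees: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.family not in ("lasso", "ridge", "naive_bayes", "random_forest"):
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.design not in ("clinical_only", "radiomics_only", "combined"):
            raise ConfigurationError(f"unknown design {self.design!r}")


@dataclass
class CVScheme:
    kind: str
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train positional idx, test positional idx)
    always_train_institutions: set = field(default_factory=set)


def assign_folds(
    records: pd.DataFrame, kind: str = "fivefold", n_folds: int = 5, seed: int = 0
) -> CVScheme:
    """Build the fold partition for one scheme (see module docstring)."""
    y = records["ofr_event"].to_numpy(dtype=int)
    n = len(records)
    if kind == "fivefold":
        for attempt in range(10):
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
            folds = [(tr, te) for tr, te in skf.split(np.zeros(n), y)]
            if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
                return CVScheme("fivefold", folds)
        raise DataError("could not build folds with both classes in every training set")
    if "institution" not in records.columns:
        raise DataError("institution schemes require an institution column")
    inst = records["institution"].to_numpy()
    by_inst = pd.Series(np.arange(n)).groupby(inst).apply(lambda s: s.to_numpy())
    events_by_inst = records.groupby("institution")["ofr_event"].sum()
    zero_event = set(events_by_inst[events_by_inst == 0].index)
    if kind == "leave_one_institution_out":
        folds = []
        for name, idx in by_inst.items():
            if name in zero_event:
                continue
            folds.append((np.setdiff1d(np.arange(n), idx), idx))
        return CVScheme("leave_one_institution_out", folds, always_train_institutions=zero_event)
    if kind == "three_institution_holdout":
        sizes = records.groupby("institution").size()
        big = [name for name in sizes[sizes > 20].index if name not in zero_event]
        folds = [(np.setdiff1d(np.arange(n), by_inst[name]), by_inst[name]) for name in big]
        return CVScheme("three_institution_holdout", folds, always_train_institutions=zero_event)
    raise ConfigurationError(f"unknown scheme {kind!r}")


# ---------------------------------------------------------------------------
# ROC / threshold metrics
# ---------------------------------------------------------------------------

def auc_mann_whitney(probabilities, labels) -> float:
    """AUC by the rank (Mann–Whitney) formulation with tie correction."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataError("both classes required for AUC")
    ranks = stats.rankdata(p)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_and_auc(probabilities, labels):
    """(fpr, tpr, thresholds, auc) by threshold sweep + rank-formulation AUC."""
    from sklearn.metrics import roc_curve

    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    auc = auc_mann_whitney(p, y)
    fpr, tpr, thr = roc_curve(y, p)
    return fpr, tpr, thr, auc


def threshold_metrics(probabilities, labels, threshold: float = 0.5) -> dict[str, float]:
    """Confusion-matrix metrics at a fixed probability threshold.

    Undefined rates (no positives / no negatives) are reported as NaN.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pred = p >= threshold
    tp = int((pred & y).sum())
    tn = int((~pred & ~y).sum())
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    return {
        "accuracy": (tp + tn) / y.size,
        "sensitivity": tp / n_pos if n_pos else float("nan"),
        "specificity": tn / n_neg if n_neg else float("nan"),
    }


# ---------------------------------------------------------------------------
# NRI / IDI / C-index
# ---------------------------------------------------------------------------

@dataclass
class BootstrapComparison:
    value: float
    ci_low: float
    ci_high: float
    p: float


def _nri_point(p_ref, p_new, y):
    up = p_new > p_ref
    down = p_new < p_ref
    ev, ne = y, ~y
    return float(
        (up[ev].mean() - down[ev].mean()) - (up[ne].mean() - down[ne].mean())
    )


def _idi_point(p_ref, p_new, y):
    ev, ne = y, ~y
    return float((p_new[ev].mean() - p_ref[ev].mean()) - (p_new[ne].mean() - p_ref[ne].mean()))


def _bootstrap(stat_fn, p_ref, p_new, y, n_boot, seed) -> BootstrapComparison:
    point = stat_fn(p_ref, p_new, y)
    rng = np.random.default_rng(seed)
    n = y.size
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.all() or not yb.any():
            vals[b] = np.nan
            continue
        vals[b] = stat_fn(p_ref[idx], p_new[idx], yb)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return BootstrapComparison(point, np.nan, np.nan, np.nan)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    frac_le = (vals <= 0).mean()
    frac_ge = (vals >= 0).mean()
    p = min(1.0, 2.0 * min(frac_le, frac_ge))
    return BootstrapComparison(point, float(lo), float(hi), float(p))


def nri(p_ref, p_new, labels, n_boot: int = 2000, seed: int = 0) -> BootstrapComparison:
    """Continuous (category-free) net reclassification improvement,
    new minus reference, with bootstrap percentile CI."""
    p_ref = np.asarray(p_ref, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if p_ref.shape != p_new.shape or p_ref.shape != y.shape:
        raise DataError("probability vectors must cover the same patients")
    return _bootstrap(_nri_point, p_ref, p_new, y, n_boot, seed)


def idi(p_ref, p_new, labels, n_boot: int = 2000, seed: int = 0) -> BootstrapComparison:
    """Integrated discrimination improvement (difference of mean-probability
    gaps), new minus reference, with bootstrap percentile CI."""
    p_ref = np.asarray(p_ref, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if p_ref.shape != p_new.shape or p_ref.shape != y.shape:
        raise DataError("probability vectors must cover the same patients")
    return _bootstrap(_idi_point, p_ref, p_new, y, n_boot, seed)


def c_index(scores, times, events) -> float:
    """Harrell's concordance of a risk score against survival (ties 0.5)."""
    from lifelines.utils import concordance_index

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if not events.any():
        raise DataError("no comparable pairs (no events)")
    # lifelines scores concordance of predicted *survival* time: negate risk
    return float(concordance_index(times, -scores, events))


def risk_group_km(probabilities, records: pd.DataFrame, threshold: float = 0.5):
    """Split at the probability threshold and compare OFR-free survival.

    Returns (curve_high, curve_low, LogRankResult-or-None); a single-group
    split yields None for the test.
    """
    if not (0.0 < threshold < 1.0):
        raise ConfigurationError(f"threshold must be in (0, 1), got {threshold}")
    p = np.asarray(probabilities, dtype=float)
    times = records["time_months"].to_numpy(dtype=float)
    events = records["ofr_event"].to_numpy(dtype=bool)
    high = p >= threshold
    if high.all() or not high.any():
        only = km_estimate(times, events)
        return (only, None, None) if high.all() else (None, only, None)
    hi = km_estimate(times[high], events[high])
    lo = km_estimate(times[~high], events[~high])
    lr = logrank_test(times[high], events[high], times[~high], events[~high])
    return hi, lo, lr


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Cross-validated evaluation of one model spec on one cohort."""

    spec: ModelSpec
    scheme_kind: str
    fold_aucs: list[float]
    pooled_auc: float
    pooled_roc: tuple
    fold_rocs: list[tuple]
    fold_metrics: list[dict]
    pooled_metrics: dict
    oof_probs: pd.Series  # out-of-fold probability per patient_id
    labels: pd.Series
    selection_counts: pd.Series
    seed: int
    manifest: dict = field(default_factory=dict)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.fold_aucs, ddof=1)) if len(self.fold_aucs) > 1 else 0.0

    def summary(self) -> str:
        m = self.pooled_metrics
        lines = [
            f"model: {self.spec.family} / {self.spec.design}  scheme: {self.scheme_kind}",
            f"AUC mean +/- SD over {len(self.fold_aucs)} folds: "
            f"{self.mean_auc:.3f} +/- {self.sd_auc:.3f}   pooled AUC: {self.pooled_auc:.3f}",
            f"pooled accuracy {m['accuracy']:.3f}  sensitivity {m['sensitivity']:.3f}  "
            f"specificity {m['specificity']:.3f}  (threshold 0.5)",
        ]
        if len(self.selection_counts):
            top = ", ".join(f"{k} ({v})" for k, v in self.selection_counts.head(12).items())
            lines.append(f"features selected (folds): {top}")
        return "\n".join(lines)


def _fit_fold(spec: ModelSpec, X_tr: pd.DataFrame, y_tr, seed: int):
    if spec.family in ("lasso", "ridge"):
        model = PenalizedLogit(
            X_tr, y_tr, penalty="l1" if spec.family == "lasso" else "l2",
            class_weighted=spec.class_weighted, lambda_grid=spec.lambda_grid, seed=seed,
        )
        return model.fit()
    if spec.family == "naive_bayes":
        return GaussianNBModel(X_tr, y_tr, class_weighted=spec.class_weighted).fit()
    return RandomForestModel(
        X_tr, y_tr, n_estimators=spec.n_trees, class_weighted=spec.class_weighted,
        seed=seed, oob=False,
    ).fit()


def run_experiment(
    records: pd.DataFrame,
    features: pd.DataFrame | None,
    spec: ModelSpec,
    scheme: CVScheme | str = "fivefold",
    seed: int = 0,
    selection_k: int = 10,
    selection_threshold: float = 0.7,
    global_selection: bool = False,
) -> EvalReport:
    """Cross-validated training and evaluation of one model spec.

    Per fold: (for non-LASSO radiomics designs) survival-informed selection on
    the training fold, then standardization + fitting inside the fold, then
    prediction on the held-out fold.  LASSO designs use all features and rely
    on embedded selection.  Returns per-fold and pooled ROC/AUC, threshold
    metrics, out-of-fold probabilities and selection stability counts.
    """
    if isinstance(scheme, str):
        scheme = assign_folds(records, scheme, seed=seed)
    uses_radiomics = spec.design in ("radiomics_only", "combined")
    X_all, y_all = make_design(records, features, spec.design)

    pre_selected = None
    if uses_radiomics and spec.family != "lasso" and global_selection:
        pre_selected = select_features(
            features.loc[records["patient_id"]], records, selection_threshold, selection_k
        ).kept

    n = len(records)
    oof = np.full(n, np.nan)
    fold_aucs, fold_rocs, fold_metrics, fold_results = [], [], [], []
    for f, (tr, te) in enumerate(scheme.folds):
        rec_tr = records.iloc[tr]
        if uses_radiomics and spec.family != "lasso":
            kept = pre_selected if pre_selected is not None else select_features(
                features.loc[rec_tr["patient_id"]], rec_tr, selection_threshold, selection_k
            ).kept
            X, y = make_design(records, features, spec.design, feature_names=kept)
        else:
            X, y = X_all, y_all
        res = _fit_fold(spec, X.iloc[tr], y.iloc[tr].to_numpy(), seed=seed + f)
        fold_results.append(res)
        p_te = res.predict_proba(X.iloc[te])
        oof[te] = p_te
        y_te = y.iloc[te].to_numpy()
        if len(np.unique(y_te)) == 2:
            ffpr, ftpr, fthr, fauc = roc_and_auc(p_te, y_te)
            fold_aucs.append(fauc)
            fold_rocs.append((ffpr, ftpr, fthr))
            fold_metrics.append(threshold_metrics(p_te, y_te))

    labels = pd.Series(y_all.to_numpy(), index=records["patient_id"].to_numpy())
    covered = np.isfinite(oof)
    pooled = oof[covered]
    y_pool = y_all.to_numpy()[covered]
    fpr, tpr, thr, pooled_auc = roc_and_auc(pooled, y_pool)
    from .selection import selection_stability

    counts = selection_stability(
        [r for r in fold_results if hasattr(r, "selected_features")]
    ) if fold_results else pd.Series(dtype=int)
    return EvalReport(
        spec=spec,
        scheme_kind=scheme.kind,
        fold_aucs=fold_aucs,
        pooled_auc=pooled_auc,
        pooled_roc=(fpr, tpr, thr),
        fold_rocs=fold_rocs,
        fold_metrics=fold_metrics,
        pooled_metrics=threshold_metrics(pooled, y_pool),
        oof_probs=pd.Series(oof, index=records["patient_id"].to_numpy())[covered],
        labels=labels,
        selection_counts=counts,
        seed=seed,
        manifest={"n_patients": n, "scheme": scheme.kind, "seed": seed,
                  "family": spec.family, "design": spec.design},
    )


def institution_holdout_experiment(
    records: pd.DataFrame,
    features: pd.DataFrame | None,
    spec: ModelSpec,
    seed: int = 0,
    **kwargs,
) -> list[dict]:
    """Hold out each >20-patient institution; train 5-fold on the rest and
    average the five fold-models' probabilities on the held-out site."""
    scheme = assign_folds(records, "three_institution_holdout", seed=seed)
    out = []
    for tr, te in scheme.folds:
        rec_tr = records.iloc[tr].reset_index(drop=True)
        rec_te = records.iloc[te]
        inner = assign_folds(rec_tr, "fivefold", seed=seed)
        uses_radiomics = spec.design in ("radiomics_only", "combined")
        probs = []
        for f, (itr, _ite) in enumerate(inner.folds):
            sub = rec_tr.iloc[itr]
            if uses_radiomics and spec.family != "lasso":
                kept = select_features(features.loc[sub["patient_id"]], sub, **{
                    k: v for k, v in kwargs.items() if k in ("threshold", "k")
                }).kept
                X_tr, y_tr = make_design(sub, features, spec.design, feature_names=kept)
                X_te, y_te = make_design(rec_te, features, spec.design, feature_names=kept)
            else:
                X_tr, y_tr = make_design(sub, features, spec.design)
                X_te, y_te = make_design(rec_te, features, spec.design)
            res = _fit_fold(spec, X_tr, y_tr.to_numpy(), seed=seed + f)
            probs.append(res.predict_proba(X_te))
        p_avg = np.mean(probs, axis=0)
        y_te = rec_te["ofr_event"].to_numpy(dtype=int)
        entry = {"institution": rec_te["institution"].iloc[0], "n_test": len(rec_te)}
        if len(np.unique(y_te)) == 2:
            entry["auc"] = auc_mann_whitney(p_avg, y_te)
            entry.update(threshold_metrics(p_avg, y_te))
        out.append(entry)
    return out


def compare_reports(
    new: EvalReport, ref: EvalReport, records: pd.DataFrame, n_boot: int = 2000, seed: int = 0
) -> dict:
    """NRI / IDI / C-index of one model against a reference, on the patients
    covered by both out-of-fold probability vectors, plus risk-group KM."""
    common = new.oof_probs.index.intersection(ref.oof_probs.index)
    rec = records.set_index("patient_id").loc[common]
    y = rec["ofr_event"].to_numpy(dtype=bool)
    p_new = new.oof_probs.loc[common].to_numpy()
    p_ref = ref.oof_probs.loc[common].to_numpy()
    times = rec["time_months"].to_numpy(dtype=float)
    rec_reset = rec.reset_index()
    return {
        "nri": nri(p_ref, p_new, y, n_boot=n_boot, seed=seed),
        "idi": idi(p_ref, p_new, y, n_boot=n_boot, seed=seed),
        "c_index_new": c_index(p_new, times, y),
        "c_index_ref": c_index(p_ref, times, y),
        "risk_groups_new": risk_group_km(p_new, rec_reset),
        "risk_groups_ref": risk_group_km(p_ref, rec_reset),
    }
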