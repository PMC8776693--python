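"""Survival-informed feature selection.

Each candidate feature is dichotomized at its per-cohort median (values equal
to the median go to the "low" group), the two groups are compared by a
log-rank test on OFR-free survival, and features are ranked by significance
(smallest p first; ties broken by name).  A greedy pass in rank order then
drops any candidate whose absolute Pearson correlation with an already-kept
feature exceeds 0.7, keeping at most the top 10 — the ranking-based selector
used with the Ridge / naive-Bayes / random-forest families.  The LASSO family
instead selects features through its own sparsity; ``lasso_selected_features``
and ``selection_stability`` expose which features carry nonzero coefficients
and in how many cross-validation folds.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import NotFittedError
from .survival import logrank_test

__all__ = [
    "SelectionResult",
    "km_rank_features",
    "prune_and_take",
    "select_features",
    "lasso_selected_features",
    "selection_stability",
]


@dataclass
class SelectionResult:
    ranked_features: list[tuple[str, float]]
    kept: list[str]
    dropped_for_correlation: list[tuple[str, str, float]] = field(default_factory=list)


def km_rank_features(features: pd.DataFrame, records: pd.DataFrame) -> list[tuple[str, float]]:
    """Rank features by the log-rank p of their median split (ascending p).

    Unrankable features (constant, or fewer than 2 patients in either median
    group) are placed last with p = 1.
    """
    ids = records["patient_id"].to_numpy()
    feats = features.loc[ids]
    times = records["time_months"].to_numpy(dtype=float)
    events = records["ofr_event"].to_numpy(dtype=bool)
    ranked = []
    for name in feats.columns:
        v = feats[name].to_numpy(dtype=float)
        med = np.median(v)
        low = v <= med  # median ties go to the low group
        if low.sum() < 2 or (~low).sum() < 2:
            ranked.append((name, 1.0))
            continue
        res = logrank_test(times[low], events[low], times[~low], events[~low])
        ranked.append((name, res.p))
    ranked.sort(key=lambda t: (t[1], t[0]))
    return ranked


def prune_and_take(
    ranked: list[tuple[str, float]],
    features: pd.DataFrame,
    threshold: float = 0.7,
    k: int = 10,
    method: str = "pearson",
) -> SelectionResult:
    """Greedy correlation pruning in rank order, keeping at most ``k`` features."""
    if not ranked:
        raise ValueError("ranked feature list is empty")
    corr = features.corr(method=method).abs()
    kept: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for name, _p in ranked:
        if len(kept) >= k:
            break
        partner = None
        for kname in kept:
            r = float(corr.loc[name, kname])
            if r > threshold:
                partner = (name, kname, r)
                break
        if partner is None:
            kept.append(name)
        else:
            dropped.append(partner)
    return SelectionResult(ranked_features=ranked, kept=kept, dropped_for_correlation=dropped)


def select_features(
    features: pd.DataFrame,
    records: pd.DataFrame,
    threshold: float = 0.7,
    k: int = 10,
    method: str = "pearson",
) -> SelectionResult:
    """KM-ranking followed by correlation pruning, in one call."""
    return prune_and_take(km_rank_features(features, records), features, threshold, k, method)


def lasso_selected_features(results) -> list[str]:
    """Names of features with nonzero coefficients in a fitted sparse model."""
    if not hasattr(results, "coef"):
        raise NotFittedError("expected fitted penalized-model results")
    return list(results.selected_features)


def selection_stability(fold_results) -> pd.Series:
    """How many folds selected each feature (bounded by the number of folds)."""
    counts: Counter = Counter()
    for res in fold_results:
        if hasattr(res, "selected_features"):
            counts.update(res.selected_features)
        else:
            counts.update(res)
    return pd.Series(dict(counts), dtype=int).sort_values(ascending=False)
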