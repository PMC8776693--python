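"""Basic ROC and Kaplan–Meier plots for pipeline reports."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .evaluation import risk_group_km, roc_and_auc
from .survival import SurvivalCurve

__all__ = ["plot_roc_from_oof", "plot_km_groups", "plot_survival_curve"]


def plot_roc_from_oof(oof: pd.DataFrame, path) -> None:
    fpr, tpr, _, auc = roc_and_auc(oof["oof_prob"].to_numpy(), oof["label"].to_numpy())
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, lw=2, label=f"pooled AUC = {auc:.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_survival_curve(ax, curve: SurvivalCurve, label: str, **kwargs) -> None:
    t = np.concatenate([[0.0], curve.event_times])
    s = np.concatenate([[1.0], curve.survival])
    ax.step(t, s, where="post", label=label, **kwargs)


def plot_km_groups(oof: pd.DataFrame, records: pd.DataFrame, path, threshold: float = 0.5) -> None:
    rec = records.set_index("patient_id").loc[oof.index].reset_index()
    hi, lo, lr = risk_group_km(oof["oof_prob"].to_numpy(), rec, threshold)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    if hi is not None:
        plot_survival_curve(ax, hi, f"high risk (p >= {threshold})")
    if lo is not None:
        plot_survival_curve(ax, lo, f"low risk (p < {threshold})")
    title = "OFR-free survival by predicted risk"
    if lr is not None:
        title += f"  (log-rank p = {lr.p:.3g})"
    ax.set_title(title, fontsize=9)
    ax.set_xlabel("months since treatment start")
    ax.set_ylabel("OFR-free survival")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
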