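"""End-to-end orchestration: simulate -> extract -> select -> train -> evaluate -> report.

Each stage is a plain function over the library; the CLI wraps them with a
YAML run configuration.  All randomness flows from the single run seed, which
is recorded in every output manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from .cohort import Cohort, CohortConfig, read_cohort, simulate_cohort, write_cohort
from .evaluation import EvalReport, ModelSpec, compare_reports, run_experiment
from .exceptions import ConfigurationError
from .features import DEFAULT_REGISTRY, extract_all, load_registry
from .selection import select_features

log = logging.getLogger("ofrad")

__all__ = ["RunConfig", "extract_cohort", "stage_simulate", "stage_extract",
           "stage_select", "stage_evaluate", "stage_report", "config_hash"]


class RunConfig:
    """YAML-backed run configuration with schema checking."""

    _ALLOWED = {
        "cohort", "normalization", "registry_path", "model", "scheme", "seed",
        "out_dir", "selection_k", "selection_threshold", "n_boot",
    }

    def __init__(self, data: dict):
        unknown = set(data) - self._ALLOWED
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        self.seed = int(data.get("seed", 0))
        cohort_cfg = dict(data.get("cohort", {}))
        cohort_cfg.setdefault("seed", self.seed)
        self.cohort = CohortConfig.from_dict(cohort_cfg)
        self.normalization = data.get("normalization", "zscore")
        if self.normalization not in ("minmax", "zscore"):
            raise ConfigurationError(f"normalization must be minmax|zscore, got {self.normalization}")
        self.registry = (
            load_registry(data["registry_path"]) if data.get("registry_path") else DEFAULT_REGISTRY
        )
        model = dict(data.get("model", {}))
        self.model = ModelSpec(
            family=model.get("family", "lasso"),
            design=model.get("design", "combined"),
            class_weighted=bool(model.get("class_weighted", True)),
            seed=self.seed,
        )
        self.scheme = data.get("scheme", "fivefold")
        self.out_dir = Path(data.get("out_dir", "ofrad_run"))
        self.selection_k = int(data.get("selection_k", 10))
        self.selection_threshold = float(data.get("selection_threshold", 0.7))
        self.n_boot = int(data.get("n_boot", 2000))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})


def config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def extract_cohort(
    cohort: Cohort,
    registry: dict = DEFAULT_REGISTRY,
    normalization: str = "zscore",
) -> pd.DataFrame:
    """Feature table (patients x named features) for a whole cohort."""
    rows = {}
    for pid in cohort.records["patient_id"]:
        feats, flags = extract_all(
            cohort.images[pid], cohort.masks[pid], registry, normalization
        )
        if flags:
            log.debug("patient %s degenerate bands: %s", pid, flags)
        rows[pid] = feats
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# CLI stages
# ---------------------------------------------------------------------------

def _timed(name):
    def deco(fn):
        def wrapper(*a, **k):
            t0 = time.time()
            out = fn(*a, **k)
            log.info("stage %s finished in %.1f s", name, time.time() - t0)
            return out
        return wrapper
    return deco


@_timed("simulate")
def stage_simulate(cfg: RunConfig) -> Path:
    cohort = simulate_cohort(cfg.cohort)
    out = cfg.out_dir / "cohort"
    write_cohort(cohort, out)
    return out


@_timed("extract")
def stage_extract(cfg: RunConfig, cohort_dir=None) -> Path:
    cohort = read_cohort(cohort_dir or cfg.out_dir / "cohort")
    table = extract_cohort(cohort, cfg.registry, cfg.normalization)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    path = cfg.out_dir / f"features_{cfg.normalization}.csv"
    table.to_csv(path, index_label="patient_id")
    return path


@_timed("select")
def stage_select(cfg: RunConfig, features_path=None) -> Path:
    features = pd.read_csv(
        features_path or cfg.out_dir / f"features_{cfg.normalization}.csv", index_col="patient_id"
    )
    records = pd.read_csv(cfg.out_dir / "cohort" / "clinical.csv")
    sel = select_features(features, records, cfg.selection_threshold, cfg.selection_k)
    out = cfg.out_dir / "selection.json"
    with open(out, "w") as fh:
        json.dump(
            {
                "kept": sel.kept,
                "ranked": sel.ranked_features[:50],
                "dropped_for_correlation": sel.dropped_for_correlation,
                "seed": cfg.seed,
            },
            fh, indent=2,
        )
    return out


@_timed("evaluate")
def stage_evaluate(cfg: RunConfig) -> dict:
    records = pd.read_csv(cfg.out_dir / "cohort" / "clinical.csv")
    features = pd.read_csv(
        cfg.out_dir / f"features_{cfg.normalization}.csv", index_col="patient_id"
    )
    report = run_experiment(
        records, features, cfg.model, cfg.scheme, seed=cfg.seed,
        selection_k=cfg.selection_k, selection_threshold=cfg.selection_threshold,
    )
    ref_spec = ModelSpec(family="ridge", design="clinical_only", seed=cfg.seed)
    ref = run_experiment(records, None, ref_spec, cfg.scheme, seed=cfg.seed)
    comp = compare_reports(report, ref, records, n_boot=cfg.n_boot, seed=cfg.seed)
    summary = {
        "seed": cfg.seed,
        "config_hash": config_hash(cfg.cohort.to_dict()),
        "model": {"family": cfg.model.family, "design": cfg.model.design},
        "auc_mean": report.mean_auc,
        "auc_sd": report.sd_auc,
        "auc_pooled": report.pooled_auc,
        "fold_aucs": report.fold_aucs,
        "pooled_metrics": report.pooled_metrics,
        "reference": {
            "auc_mean": ref.mean_auc, "auc_sd": ref.sd_auc, "auc_pooled": ref.pooled_auc,
        },
        "nri": vars(comp["nri"]),
        "idi": vars(comp["idi"]),
        "c_index_new": comp["c_index_new"],
        "c_index_ref": comp["c_index_ref"],
        "selection_counts": {str(k): int(v) for k, v in report.selection_counts.items()},
    }
    with open(cfg.out_dir / "evaluation.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    # keep the reports for the report stage
    _save_oof(report, cfg.out_dir / "oof_model.csv")
    _save_oof(ref, cfg.out_dir / "oof_reference.csv")
    return summary


def _save_oof(report: EvalReport, path: Path) -> None:
    pd.DataFrame({"oof_prob": report.oof_probs, "label": report.labels.loc[report.oof_probs.index]}).to_csv(
        path, index_label="patient_id"
    )


@_timed("report")
def stage_report(cfg: RunConfig) -> Path:
    from .plotting import plot_km_groups, plot_roc_from_oof

    records = pd.read_csv(cfg.out_dir / "cohort" / "clinical.csv")
    with open(cfg.out_dir / "evaluation.json") as fh:
        summary = json.load(fh)
    oof = pd.read_csv(cfg.out_dir / "oof_model.csv", index_col="patient_id")
    plot_roc_from_oof(oof, cfg.out_dir / "roc.png")
    plot_km_groups(oof, records, cfg.out_dir / "km_risk_groups.png")
    lines = [
        f"run seed {summary['seed']} (config {summary['config_hash']})",
        f"{summary['model']['family']} / {summary['model']['design']}: "
        f"AUC {summary['auc_mean']:.3f} +/- {summary['auc_sd']:.3f} (pooled {summary['auc_pooled']:.3f})",
        f"accuracy {summary['pooled_metrics']['accuracy']:.3f}, "
        f"sensitivity {summary['pooled_metrics']['sensitivity']:.3f}, "
        f"specificity {summary['pooled_metrics']['specificity']:.3f}",
        f"reference (ridge/clinical_only): AUC {summary['reference']['auc_mean']:.3f} "
        f"+/- {summary['reference']['auc_sd']:.3f}",
        f"NRI {summary['nri']['value']:+.4f} [{summary['nri']['ci_low']:.4f}, {summary['nri']['ci_high']:.4f}]",
        f"IDI {summary['idi']['value']:+.4f} [{summary['idi']['ci_low']:.4f}, {summary['idi']['ci_high']:.4f}]",
        f"C-index {summary['c_index_new']:.3f} (reference {summary['c_index_ref']:.3f})",
    ]
    out = cfg.out_dir / "report.txt"
    out.write_text("\n".join(lines) + "\n")
    return out
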