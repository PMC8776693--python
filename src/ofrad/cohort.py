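"""Synthetic phantom cohort: clinical table, tumour phantoms, institution effects.

The generator emulates the statistical structure the downstream analysis
assumes for a multi-institutional stage-IIB cervical-cancer cohort treated
with chemoradiotherapy:

* a clinical table whose default contingency matches the study design —
  para-aortic lymph-node (PALN) metastasis prevalence 21/180, out-of-field
  recurrence (OFR) within 36 months in 12/21 PALN-positive and 26/159
  PALN-negative patients — plus covariates drawn from published marginal
  ranges (age 29–80, tumour diameter 2.2–17.2 cm, volume 3.0–557.4 ml, ...);
* an ellipsoidal tumour phantom per patient whose interior texture is a
  Gaussian random field whose correlation length (and variance) shift with
  the OFR outcome by ``texture_effect_size`` — the planted radiomic signal;
* per-institution affine intensity distortions (scale, offset) plus additive
  noise, emulating scanner/protocol differences across ~13 sites, with two
  institutions carrying no events (so they can never serve as test sites in
  institution-wise validation).

All randomness flows from one cohort seed; per-patient streams are derived
from ``(seed, patient_index)`` so cohorts are extensible without reshuffling.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import ConfigurationError, GenerationError
from .image import ImageVolume, ROIMask, read_mask, read_volume, write_mask, write_volume

__all__ = [
    "CohortConfig",
    "Cohort",
    "sample_clinical_table",
    "generate_phantom",
    "apply_institution_effect",
    "institution_effect_params",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "cohort_from_counts",
    "contingency_summary",
]

CLINICAL_COLUMNS = [
    "patient_id", "age", "performance_status", "histology", "tumor_max_diameter_cm",
    "tumor_volume_ml", "pelvic_ln_class", "common_iliac_ln", "paln", "wp_dose_gy",
    "boost_to_ln", "bt_pointA_dose_gy", "chemo_class", "institution", "ofr_event",
    "time_months",
]


def _default_institutions(n: int) -> tuple[str, ...]:
    return tuple(chr(ord("A") + i) for i in range(n))


@dataclass
class CohortConfig:
    """Study conditions of the phantom cohort.

    Defaults reproduce the printed contingency structure of the 180-patient
    cohort: PALN prevalence 21/180, P(OFR | PALN+) = 12/21,
    P(OFR | PALN-) = 26/159; 13 institutions of which the first three are
    large (>20 patients) and two ("H", "J") carry no events.
    """

    n_patients: int = 180
    prevalence_paln: float = 21 / 180
    p_ofr_given_paln_pos: float = 12 / 21
    p_ofr_given_paln_neg: float = 26 / 159
    n_institutions: int = 13
    institutions_without_events: tuple[str, ...] = ("H", "J")
    texture_effect_size: float = 0.75
    image_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    noise_sd: float = 2.0
    seed: int = 0
    # interior texture model: correlation length sigma (voxels) and field SD
    texture_base_sigma: float = 0.8
    texture_base_sd: float = 15.0
    tumor_base_intensity: float = 100.0
    background_intensity: float = 20.0
    # tumour volume range (ml); published cohort range
    volume_range_ml: tuple[float, float] = (3.0, 557.4)

    def __post_init__(self) -> None:
        for name in ("prevalence_paln", "p_ofr_given_paln_pos", "p_ofr_given_paln_neg"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if self.n_institutions < 1:
            raise ConfigurationError("n_institutions must be >= 1")
        if self.texture_effect_size < 0:
            raise ConfigurationError("texture_effect_size must be >= 0")
        unknown = set(self.institutions_without_events) - set(self.institutions)
        if unknown:
            raise ConfigurationError(f"institutions_without_events not in cohort: {sorted(unknown)}")

    @property
    def institutions(self) -> tuple[str, ...]:
        return _default_institutions(self.n_institutions)

    def institution_sizes(self) -> dict[str, int]:
        """Patients per institution: three large sites, the rest small."""
        weights = np.ones(self.n_institutions)
        big = min(3, self.n_institutions)
        weights[:big] = (3.0, 2.6, 2.4)[:big]
        raw = weights / weights.sum() * self.n_patients
        sizes = np.floor(raw).astype(int)
        # largest-remainder rounding to hit n_patients exactly
        rem = self.n_patients - sizes.sum()
        order = np.argsort(-(raw - sizes))
        sizes[order[:rem]] += 1
        return dict(zip(self.institutions, sizes.tolist()))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        kwargs = dict(d)
        for k in ("institutions_without_events", "image_shape", "voxel_spacing_mm", "volume_range_ml"):
            if k in kwargs and isinstance(kwargs[k], list):
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)


@dataclass
class Cohort:
    """In-memory cohort: clinical table plus per-patient image/mask pairs."""

    config: CohortConfig
    records: pd.DataFrame
    images: dict[str, ImageVolume] = field(default_factory=dict)
    masks: dict[str, ROIMask] = field(default_factory=dict)


def _patient_rng(seed: int, patient_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, patient_index)))


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

def sample_clinical_table(config: CohortConfig) -> pd.DataFrame:
    """Draw the per-patient clinical covariates, outcomes and institutions."""
    n = config.n_patients
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xC11)))
    if n == 0:
        return pd.DataFrame(columns=CLINICAL_COLUMNS)

    paln = rng.random(n) < config.prevalence_paln
    p_event = np.where(paln, config.p_ofr_given_paln_pos, config.p_ofr_given_paln_neg)
    ofr = rng.random(n) < p_event
    time_months = np.where(ofr, rng.uniform(1.0, 36.0, n), rng.uniform(36.0, 96.0, n))

    age = rng.integers(29, 81, n)
    performance_status = rng.choice([0, 1, 2], size=n, p=[132 / 180, 45 / 180, 3 / 180])
    histology = rng.choice(["SCC", "other"], size=n, p=[167 / 180, 13 / 180])
    diameter = np.clip(np.exp(rng.normal(np.log(5.1), 0.35, n)), 2.2, 17.2)
    vol_lo, vol_hi = config.volume_range_ml
    volume = np.clip(0.2487 * diameter**3 * np.exp(rng.normal(0.0, 0.25, n)), vol_lo, vol_hi)
    pelvic_ln_class = rng.choice([0, 1, 2], size=n, p=[112 / 180, 49 / 180, 19 / 180])
    common_iliac = rng.random(n) < 19 / 180
    wp_low = rng.random(n) < 136 / 180
    wp_dose = np.where(wp_low, rng.uniform(45.0, 50.0, n), rng.uniform(50.001, 60.6, n))
    node_positive = (pelvic_ln_class > 0) | common_iliac | paln
    boost = node_positive & (rng.random(n) < 0.75)
    bt_dose = rng.uniform(12.0, 36.1, n)
    chemo = rng.choice(
        ["weekly_cddp", "daily_cddp", "other"], size=n, p=[133 / 180, 15 / 180, 32 / 180]
    )

    institution = _assign_institutions(config, ofr, rng)

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "age": age,
            "performance_status": performance_status,
            "histology": histology,
            "tumor_max_diameter_cm": np.round(diameter, 2),
            "tumor_volume_ml": np.round(volume, 1),
            "pelvic_ln_class": pelvic_ln_class,
            "common_iliac_ln": common_iliac,
            "paln": paln,
            "wp_dose_gy": np.round(wp_dose, 1),
            "boost_to_ln": boost,
            "bt_pointA_dose_gy": np.round(bt_dose, 1),
            "chemo_class": chemo,
            "institution": institution,
            "ofr_event": ofr,
            "time_months": np.round(time_months, 2),
        }
    )
    return df


def _assign_institutions(config: CohortConfig, ofr: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Fill the configured institution sizes; event patients only go to
    event-eligible institutions, so the configured zero-event sites stay
    event-free without distorting the conditional OFR probabilities."""
    sizes = config.institution_sizes()
    no_event = set(config.institutions_without_events)
    eligible_slots = []
    ineligible_slots = []
    for inst, k in sizes.items():
        (ineligible_slots if inst in no_event else eligible_slots).extend([inst] * k)
    n_events = int(ofr.sum())
    if n_events > len(eligible_slots):
        raise ConfigurationError(
            f"{n_events} events exceed capacity of event-eligible institutions ({len(eligible_slots)})"
        )
    eligible_slots = list(rng.permutation(eligible_slots))
    event_insts = eligible_slots[:n_events]
    rest = list(rng.permutation(eligible_slots[n_events:] + ineligible_slots))
    out = np.empty(len(ofr), dtype=object)
    out[ofr] = event_insts
    out[~ofr] = rest
    return out


# ---------------------------------------------------------------------------
# Phantom generation
# ---------------------------------------------------------------------------

def generate_phantom(record, config: CohortConfig) -> tuple[ImageVolume, ROIMask]:
    """Generate one tumour phantom: ellipsoidal mask + textured interior.

    The mask is an ellipsoid of random orientation-free axis ratios whose
    voxelized volume matches ``record.tumor_volume_ml`` within 10%.  Interior
    intensity is a base level plus a band-limited Gaussian random field whose
    smoothing length and SD increase with ``texture_effect_size`` when the
    patient is an OFR case.  Deterministic under ``(config.seed, patient_id)``.
    """
    pid = record["patient_id"] if isinstance(record, (dict, pd.Series)) else record.patient_id
    idx = int(str(pid).lstrip("P"))
    rec = record if isinstance(record, (dict, pd.Series)) else vars(record)
    rng = _patient_rng(config.seed, idx)

    shape = np.array(config.image_shape, dtype=int)
    spacing = np.array(config.voxel_spacing_mm, dtype=float)
    extent = shape * spacing
    target_mm3 = float(rec["tumor_volume_ml"]) * 1000.0

    r_eff = (3.0 * target_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    ratios = np.exp(rng.normal(0.0, 0.12, 3))
    ratios /= ratios.prod() ** (1.0 / 3.0)
    semi = r_eff * ratios
    # clamp axes to the image extent, redistributing to preserve volume
    limit = extent / 2.0 - spacing
    if np.any(limit <= 0):
        raise GenerationError("image extent too small for any tumour")
    for _ in range(4):
        over = semi > limit
        if not over.any():
            break
        scale = (semi[over] / limit[over]).prod()
        semi[over] = limit[over]
        free = ~over
        if free.any():
            semi[free] *= scale ** (1.0 / free.sum())
    semi = np.minimum(semi, limit)
    achieved = 4.0 / 3.0 * np.pi * semi.prod()
    if achieved < 0.9 * target_mm3:
        raise GenerationError(
            f"tumour volume {rec['tumor_volume_ml']} ml does not fit in image extent {extent.tolist()} mm"
        )

    centre_mm = extent / 2.0 + rng.uniform(-0.05, 0.05, 3) * np.maximum(
        extent / 2.0 - semi - spacing, 0.0
    )
    grids = np.meshgrid(*[(np.arange(s) + 0.5) * sp for s, sp in zip(shape, spacing)], indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre_mm, semi))
    mask_arr = q <= 1.0
    if not mask_arr.any():
        raise GenerationError("degenerate phantom mask")

    event = bool(rec["ofr_event"])
    bump = config.texture_effect_size if event else 0.0
    sigma = config.texture_base_sigma * (1.0 + bump)
    field_sd = config.texture_base_sd * (1.0 + 0.5 * bump)
    white = rng.normal(0.0, 1.0, tuple(shape))
    fld = ndimage.gaussian_filter(white, sigma=sigma, mode="wrap")
    fld *= field_sd / fld.std()

    values = np.full(tuple(shape), config.background_intensity)
    values[mask_arr] = config.tumor_base_intensity + fld[mask_arr]

    img = ImageVolume(values, tuple(spacing), (0.0, 0.0, 0.0))
    mask = ROIMask(mask_arr, tuple(spacing), (0.0, 0.0, 0.0))
    return img, mask


# ---------------------------------------------------------------------------
# Institution effects
# ---------------------------------------------------------------------------

def institution_effect_params(institution: str, config: CohortConfig) -> tuple[float, float, float]:
    """(scale, offset, noise_sd) for one institution, derived from the cohort seed."""
    if institution not in config.institutions:
        raise ConfigurationError(f"unknown institution {institution!r}")
    idx = config.institutions.index(institution)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x1257, idx)))
    scale = float(np.exp(rng.normal(0.0, 0.15)))
    offset = float(rng.normal(0.0, 0.1 * config.tumor_base_intensity))
    noise_sd = float(config.noise_sd * rng.uniform(0.5, 1.5))
    return scale, offset, noise_sd


def apply_institution_effect(
    img: ImageVolume,
    institution: str,
    config: CohortConfig,
    params: tuple[float, float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> ImageVolume:
    """Affine intensity distortion plus additive scanner noise.

    ``params`` overrides the seed-derived (scale, offset, noise_sd); ``rng``
    supplies the noise stream (pass a per-patient generator so patients of the
    same institution do not share a noise pattern).
    """
    scale, offset, noise_sd = params if params is not None else institution_effect_params(institution, config)
    values = scale * img.values + offset
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(
                np.random.SeedSequence((config.seed, 0x401E, config.institutions.index(institution)))
            )
        values = values + rng.normal(0.0, noise_sd, img.shape)
    return ImageVolume(values, img.spacing_mm, img.origin_mm)


# ---------------------------------------------------------------------------
# Full simulation + persistence
# ---------------------------------------------------------------------------

def simulate_cohort(config: CohortConfig, with_images: bool = True) -> Cohort:
    """Clinical table plus (optionally) phantoms with institution effects applied."""
    records = sample_clinical_table(config)
    cohort = Cohort(config=config, records=records)
    if not with_images:
        return cohort
    for i, rec in records.iterrows():
        img, mask = generate_phantom(rec, config)
        rng = _patient_rng(config.seed, 0x70000 + int(str(rec["patient_id"]).lstrip("P")))
        img = apply_institution_effect(img, rec["institution"], config, rng=rng)
        cohort.images[rec["patient_id"]] = img
        cohort.masks[rec["patient_id"]] = mask
    return cohort


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write per-patient NIfTI image+mask, the clinical CSV and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for pid in cohort.records["patient_id"]:
        img_path = out / f"{pid}_img.nii.gz"
        mask_path = out / f"{pid}_mask.nii.gz"
        write_volume(cohort.images[pid], img_path)
        write_mask(cohort.masks[pid], mask_path)
        files.extend([img_path.name, mask_path.name])
    csv_path = out / "clinical.csv"
    cohort.records.to_csv(csv_path, index=False)
    manifest = {
        "seed": cohort.config.seed,
        "config": cohort.config.to_dict(),
        "n_patients": int(len(cohort.records)),
        "clinical_csv": csv_path.name,
        "files": files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_cohort(in_dir) -> Cohort:
    """Round-trip reader for :func:`write_cohort` output."""
    p = Path(in_dir)
    with open(p / "manifest.json") as fh:
        manifest = json.load(fh)
    config = CohortConfig.from_dict(manifest["config"])
    records = pd.read_csv(p / manifest["clinical_csv"])
    cohort = Cohort(config=config, records=records)
    for pid in records["patient_id"]:
        cohort.images[pid] = read_volume(p / f"{pid}_img.nii.gz")
        cohort.masks[pid] = read_mask(p / f"{pid}_mask.nii.gz")
    return cohort


# ---------------------------------------------------------------------------
# Printed-count reconstruction
# ---------------------------------------------------------------------------

def cohort_from_counts(
    n_total: int = 180,
    n_paln_pos: int = 21,
    n_ofr_among_paln_pos: int = 12,
    n_ofr_among_paln_neg: int = 26,
) -> pd.DataFrame:
    """Deterministic records table realizing an exact PALN x OFR contingency.

    Event times are spread evenly inside the 36-month horizon and follow-up
    times beyond it, so survival-side code can run on the table.
    """
    n_paln_neg = n_total - n_paln_pos
    if n_ofr_among_paln_pos > n_paln_pos or n_ofr_among_paln_neg > n_paln_neg:
        raise ConfigurationError("event counts exceed group sizes")
    paln = np.zeros(n_total, dtype=bool)
    paln[:n_paln_pos] = True
    ofr = np.zeros(n_total, dtype=bool)
    ofr[:n_ofr_among_paln_pos] = True
    ofr[n_paln_pos : n_paln_pos + n_ofr_among_paln_neg] = True
    n_events = int(ofr.sum())
    times = np.empty(n_total)
    times[ofr] = np.linspace(2.0, 35.0, n_events)
    times[~ofr] = np.linspace(37.0, 95.0, n_total - n_events)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n_total)],
            "paln": paln,
            "ofr_event": ofr,
            "time_months": times,
        }
    )


def contingency_summary(records: pd.DataFrame) -> dict[str, float]:
    """OFR/PALN contingency percentages (rounded to 1 decimal, as printed)."""
    paln = records["paln"].to_numpy(dtype=bool)
    ofr = records["ofr_event"].to_numpy(dtype=bool)
    out = {
        "ofr_rate_paln_positive_pct": 100.0 * ofr[paln].mean() if paln.any() else float("nan"),
        "ofr_rate_paln_negative_pct": 100.0 * ofr[~paln].mean() if (~paln).any() else float("nan"),
        "paln_negative_share_of_ofr_pct": 100.0 * (~paln)[ofr].mean() if ofr.any() else float("nan"),
    }
    return {k: round(v, 1) for k, v in out.items()}
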