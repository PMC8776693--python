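"""Survival machinery: Kaplan–Meier, log-rank, Cox proportional hazards.

The event of interest is out-of-field recurrence (OFR) within 36 months of
treatment start; later times are follow-up and enter as censored.  The Cox
model maximizes the Breslow partial likelihood by Newton iterations
(convergence at gradient norm < 1e-8, at most 100 iterations); monotone
likelihoods (complete separation) are detected by coefficient capping and
flagged rather than silently diverging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError

__all__ = [
    "SurvivalCurve",
    "km_estimate",
    "LogRankResult",
    "logrank_test",
    "CoxResults",
    "cox_fit",
    "CoxPHModel",
    "prognostic_screen",
    "DEFAULT_DICHOTOMIES",
]

EVENT_HORIZON_MONTHS = 36.0


@dataclass
class SurvivalCurve:
    """Product-limit estimate: step function over the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """S(t); S(0) = 1 and the curve is right-continuous."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimator (censored subjects leave the risk
    set after their time)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise DataError("empty input")
    if np.any(times <= 0):
        raise DataError("times must be positive")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq = np.unique(t[e])
    n = len(t)
    at_risk = np.empty(len(uniq))
    d = np.empty(len(uniq))
    surv = np.empty(len(uniq))
    s = 1.0
    for i, ti in enumerate(uniq):
        r = int((t >= ti).sum())
        di = int(((t == ti) & e).sum())
        s *= 1.0 - di / r
        at_risk[i], d[i], surv[i] = r, di, s
    return SurvivalCurve(uniq, surv, at_risk, d, n)


@dataclass
class LogRankResult:
    chi2: float
    p: float
    no_events: bool = False


def logrank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group log-rank test (observed-minus-expected over pooled event
    times, hypergeometric variance, 1 df)."""
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise DataError("both groups must be non-empty")
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    group = np.concatenate([np.zeros(ta.size, bool), np.ones(tb.size, bool)])
    if not events.any():
        return LogRankResult(0.0, 1.0, no_events=True)
    uniq = np.unique(times[events])
    o_minus_e = 0.0
    var = 0.0
    for t in uniq:
        at = times >= t
        n_t = int(at.sum())
        n1 = int((at & group).sum())
        d_t = int((events & (times == t)).sum())
        d1 = int((events & (times == t) & group).sum())
        if n_t < 2:
            continue
        exp1 = d_t * n1 / n_t
        o_minus_e += d1 - exp1
        var += d_t * (n1 / n_t) * (1 - n1 / n_t) * (n_t - d_t) / (n_t - 1)
    if var <= 0:
        return LogRankResult(0.0, 1.0, no_events=True)
    chi2 = o_minus_e**2 / var
    return LogRankResult(float(chi2), float(stats.chi2.sf(chi2, 1)))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties, Newton-Raphson)
# ---------------------------------------------------------------------------

@dataclass
class CoxResults:
    """Fitted Cox model: coefficients, Wald inference, convergence diagnostics."""

    names: list[str]
    params: np.ndarray
    se: np.ndarray
    converged: bool
    n_iter: int
    monotone: bool = False
    n: int = 0
    n_events: int = 0

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    @property
    def pvalues(self) -> np.ndarray:
        z = np.where(self.se > 0, self.params / self.se, 0.0)
        return np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "HR": self.hazard_ratios,
                "se": self.se,
                "p": self.pvalues,
            },
            index=self.names,
        )


_BETA_CAP = 20.0


def _cox_derivatives(x, times, events, beta):
    """Breslow partial log-likelihood, gradient and Hessian.

    Subjects sorted by descending time so risk sets are cumulative prefixes.
    """
    order = np.argsort(-times, kind="stable")
    xs, ts, es = x[order], times[order], events[order]
    eta = xs @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    cw = np.cumsum(w)
    cwx = np.cumsum(xs * w[:, None], axis=0)
    cwxx = np.cumsum(np.einsum("ij,ik->ijk", xs, xs) * w[:, None, None], axis=0)
    # risk set at time t includes every subject with time >= t: advance the
    # prefix to the last subject sharing the same time (ties)
    ll, g = 0.0, np.zeros(x.shape[1])
    h = np.zeros((x.shape[1], x.shape[1]))
    i = 0
    n = len(ts)
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] == ts[i]:
            j += 1
        ev = np.nonzero(es[i : j + 1])[0] + i
        d = len(ev)
        if d:
            s0 = cw[j]
            s1 = cwx[j]
            s2 = cwxx[j]
            ll += eta[ev].sum() - d * np.log(s0)
            g += xs[ev].sum(axis=0) - d * s1 / s0
            h -= d * (s2 / s0 - np.outer(s1, s1) / s0**2)
        i = j + 1
    return ll, g, h


def cox_fit(covariates, times, events, max_iter: int = 100, tol: float = 1e-8) -> CoxResults:
    """Fit the Cox model by Newton iterations with step halving."""
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        x = covariates.to_numpy(dtype=float)
    else:
        x = np.asarray(covariates, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = [f"x{i}" for i in range(x.shape[1])]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n, p = x.shape
    if not np.all(np.isfinite(x)):
        raise DataError("non-finite covariates")
    if np.any(x.std(axis=0) == 0):
        raise DataError("constant covariate")
    if np.linalg.matrix_rank(x - x.mean(axis=0)) < p:
        raise DataError("collinear covariates")
    n_events = int(events.sum())
    if n_events < p:
        raise DataError(f"{n_events} events < {p} covariates")

    mu, sd = x.mean(axis=0), x.std(axis=0)
    xs = (x - mu) / sd
    beta = np.zeros(p)
    ll, g, h = _cox_derivatives(xs, times, events, beta)
    converged = False
    it = 0
    monotone = False
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(h - 1e-9 * np.eye(p), g)
        except np.linalg.LinAlgError:
            step = g * 1e-3
        new_beta = beta - step
        new_ll, new_g, new_h = _cox_derivatives(xs, times, events, new_beta)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 20:
            step /= 2.0
            new_beta = beta - step
            new_ll, new_g, new_h = _cox_derivatives(xs, times, events, new_beta)
            halvings += 1
        beta, ll, g, h = new_beta, new_ll, new_g, new_h
        if np.any(np.abs(beta) > _BETA_CAP):
            monotone = True
            beta = np.clip(beta, -_BETA_CAP, _BETA_CAP)
            ll, g, h = _cox_derivatives(xs, times, events, beta)
            break
        if np.linalg.norm(g) < tol:
            converged = True
            break
    cov = np.linalg.inv(-(h - 1e-9 * np.eye(p)))
    se_s = np.sqrt(np.clip(np.diag(cov), 0, None))
    return CoxResults(
        names=names,
        params=beta / sd,
        se=se_s / sd,
        converged=converged,
        n_iter=it,
        monotone=monotone,
        n=n,
        n_events=n_events,
    )


class CoxPHModel:
    """Model-object wrapper around :func:`cox_fit` (fit() -> CoxResults)."""

    def __init__(self, covariates, times, events):
        self.covariates = covariates
        self.times = times
        self.events = events

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, covariate_cols, time_col="time_months", event_col="ofr_event"):
        return cls(df[list(covariate_cols)], df[time_col].to_numpy(), df[event_col].to_numpy())

    def fit(self, **kwargs) -> CoxResults:
        return cox_fit(self.covariates, self.times, self.events, **kwargs)


# ---------------------------------------------------------------------------
# Prognostic-factor screen
# ---------------------------------------------------------------------------

# (label, indicator function records -> bool array for the "high" stratum, high/low labels)
DEFAULT_DICHOTOMIES = [
    ("Age >56", lambda r: r["age"] > 56),
    ("Performance status 2", lambda r: r["performance_status"] >= 2),
    ("Histology non-SCC", lambda r: r["histology"] != "SCC"),
    ("Max diameter >5.1 cm", lambda r: r["tumor_max_diameter_cm"] > 5.1),
    ("Tumor volume >33 ml", lambda r: r["tumor_volume_ml"] > 33.0),
    ("Pelvic LN metastasis", lambda r: r["pelvic_ln_class"] > 0),
    ("Pelvic LN >=3", lambda r: r["pelvic_ln_class"] >= 2),
    ("Common iliac LN metastasis", lambda r: r["common_iliac_ln"].astype(bool)),
    ("PALN metastasis", lambda r: r["paln"].astype(bool)),
    ("WP dose >50 Gy", lambda r: r["wp_dose_gy"] > 50.0),
    ("Boost to LN", lambda r: r["boost_to_ln"].astype(bool)),
    ("Point A dose >24.2 Gy", lambda r: r["bt_pointA_dose_gy"] > 24.2),
    ("Chemo other than weekly CDDP", lambda r: r["chemo_class"] != "weekly_cddp"),
]


def prognostic_screen(records: pd.DataFrame, dichotomies=None, alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable log-rank screen plus one multivariate Cox fit.

    For each dichotomized variable: group sizes, 3-year OFR-free % read off
    the KM curve at month 36, log-rank p; then a single Cox model over all
    usable indicators gives the multivariate p.  ``selected`` marks variables
    significant in both tests (the clinical-predictor criterion).
    Degenerate strata (an empty group or no events overall) are skipped with a
    note.
    """
    dichotomies = dichotomies if dichotomies is not None else DEFAULT_DICHOTOMIES
    times = records["time_months"].to_numpy(dtype=float)
    events = records["ofr_event"].to_numpy(dtype=bool)
    rows = []
    usable = {}
    for label, fn in dichotomies:
        ind = np.asarray(fn(records), dtype=bool)
        if ind.all() or (~ind).all():
            rows.append(
                {"variable": label, "n_high": int(ind.sum()), "n_low": int((~ind).sum()),
                 "ofr_free_36m_high_pct": np.nan, "ofr_free_36m_low_pct": np.nan,
                 "logrank_p": np.nan, "cox_p": np.nan, "selected": False,
                 "note": "degenerate stratum"}
            )
            continue
        km_hi = km_estimate(times[ind], events[ind])
        km_lo = km_estimate(times[~ind], events[~ind])
        lr = logrank_test(times[ind], events[ind], times[~ind], events[~ind])
        usable[label] = ind.astype(float)
        rows.append(
            {"variable": label, "n_high": int(ind.sum()), "n_low": int((~ind).sum()),
             "ofr_free_36m_high_pct": round(100.0 * km_hi.survival_at(EVENT_HORIZON_MONTHS), 1),
             "ofr_free_36m_low_pct": round(100.0 * km_lo.survival_at(EVENT_HORIZON_MONTHS), 1),
             "logrank_p": lr.p, "cox_p": np.nan, "selected": False, "note": ""}
        )
    if usable and events.sum() >= len(usable):
        X = pd.DataFrame(usable)
        # drop collinear columns greedily so the joint fit is well-posed
        keep = []
        for c in X.columns:
            cand = X[keep + [c]].to_numpy()
            if np.linalg.matrix_rank(cand - cand.mean(axis=0)) == len(keep) + 1:
                keep.append(c)
        fit = CoxPHModel(X[keep], times, events).fit()
        pmap = dict(zip(keep, fit.pvalues))
        for row in rows:
            if row["variable"] in pmap:
                row["cox_p"] = pmap[row["variable"]]
                row["selected"] = bool(row["logrank_p"] < alpha and row["cox_p"] < alpha)
    return pd.DataFrame(rows)
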