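"""Batched solver for class-weighted penalized logistic regression.

Minimizes, for each weight column ``w`` (one model per column),

    (1/s) * sum_i w_i * logloss_i(beta)  +  lambda * ||beta_coef||_1      (l1)
    (1/s) * sum_i w_i * logloss_i(beta)  +  (lambda/2) * ||beta_coef||_2^2  (l2)

with ``s`` the number of samples with positive weight and the intercept
unpenalized.  All models (e.g. the n leave-one-out subsets plus the full
training set) share the design matrix, so one FISTA iteration updates every
model at once with two matrix products; the regularization path is solved
from the largest lambda down with warm starts, and lambdas above the
column-wise critical value (where the l1 solution is intercept-only) cost no
iterations.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["penalized_logistic_path"]


def _soft(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def _intercept_only(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted-base-rate logit per weight column."""
    num = (w * y[:, None]).sum(axis=0)
    den = w.sum(axis=0)
    p = np.clip(num / den, 1e-10, 1 - 1e-10)
    return np.log(p / (1 - p))


def penalized_logistic_path(
    Z: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    lam_grid: np.ndarray,
    penalty: str = "l1",
    tol: float = 1e-4,
    max_iter: int = 5000,
) -> np.ndarray:
    """Coefficients along the path.

    Parameters
    ----------
    Z : (n, p) standardized features (no intercept column).
    y : (n,) binary labels.
    weights : (n, m) per-sample weights, one column per model; a zero weight
        excludes the sample (leave-one-out columns).
    lam_grid : increasing penalty grid.
    penalty : 'l1' or 'l2'.

    Returns
    -------
    (len(lam_grid), p + 1, m) array; row 0 of axis 1 is the intercept.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    W = np.asarray(weights, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    n, p = Z.shape
    m = W.shape[1]
    Z1 = np.concatenate([np.ones((n, 1)), Z], axis=1)
    s = np.maximum((W > 0).sum(axis=0), 1).astype(float)
    # Lipschitz constant of the smooth part, shared across models
    lip = (np.linalg.norm(Z1, 2) ** 2) * W.max() / (4.0 * s.min())

    order = np.argsort(-np.asarray(lam_grid, dtype=float))
    out = np.empty((len(lam_grid), p + 1, m))
    B = np.zeros((p + 1, m))
    B[0] = _intercept_only(y, W)
    # critical lambda per model: above it the l1 solution is intercept-only
    if penalty == "l1":
        p0 = expit(Z1 @ B)
        lam_max = np.abs(Z.T @ (W * (p0 - y[:, None]))).max(axis=0) / s
    else:
        lam_max = np.full(m, np.inf)

    def _fista(Zsub, Bsub, lam, l1_rows):
        """FISTA on a feature subset; ``l1_rows`` marks penalized rows of Bsub."""
        step = 1.0 / (lip + (0.0 if penalty == "l1" else lam))
        Bk = Bsub.copy()
        Y = Bsub.copy()
        t_m = 1.0
        for _ in range(max_iter):
            pr = expit(Zsub @ Y)
            G = Zsub.T @ (W * (pr - y[:, None])) / s[None, :]
            if penalty == "l2":
                G[1:] += lam * Y[1:]
            Bn = Y - step * G
            if penalty == "l1":
                Bn[l1_rows] = _soft(Bn[l1_rows], step * lam)
            t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_m * t_m))
            Y = Bn + ((t_m - 1.0) / t_next) * (Bn - Bk)
            delta = np.abs(Bn - Bk).max()
            Bk = Bn
            t_m = t_next
            if delta < tol:
                break
        return Bk

    for k in order:
        lam = float(lam_grid[k])
        if penalty == "l1" and lam >= lam_max.max():
            out[k] = B
            continue
        if penalty == "l2":
            B = _fista(Z1, B, lam, slice(1, None))
            out[k] = B
            continue
        # l1: solve on the active feature set, then verify the KKT conditions
        # (|gradient| <= lam at zero) on the excluded features and grow the set
        active = np.nonzero(np.abs(B[1:]).max(axis=1) > 0)[0]
        for _ in range(20):
            cols = np.concatenate([[0], active + 1]).astype(int)
            Bsub = _fista(Z1[:, cols], B[cols], lam, slice(1, None))
            B = np.zeros_like(B)
            B[cols] = Bsub
            pr = expit(Z1 @ B)
            G = Z1.T @ (W * (pr - y[:, None])) / s[None, :]
            viol = np.nonzero(np.abs(G[1:]).max(axis=1) > lam * (1.0 + 1e-6))[0]
            new = np.setdiff1d(viol, active)
            if new.size == 0:
                break
            active = np.union1d(active, new)
        out[k] = B
    return out
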