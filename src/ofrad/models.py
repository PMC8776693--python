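"""Classifier families for 3-year out-of-field recurrence.

Four families mirror the study design: penalized logistic regression (LASSO
for radiomics / combined designs, Ridge for the clinical-only design),
Gaussian naive Bayes, and a Gini random forest.  Class imbalance is handled
by weighting each sample's loss term with the balanced weight
``w_c = n / (2 n_c)``, and the penalty strength is tuned by leave-one-out
(LOO) weighted log-loss on the training cohort only — never on test data.
Feature standardization parameters are likewise learned on the training data
and stored with the fitted results.

Model classes follow the ``Model(...).fit() -> Results`` idiom; Results
objects carry coefficients, the chosen hyperparameter, the standardization
parameters, and ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB

from .exceptions import DataError, NotFittedError

__all__ = [
    "class_weights",
    "make_design",
    "PenalizedLogit",
    "PenalizedLogitResults",
    "GaussianNBModel",
    "RandomForestModel",
    "SklearnResults",
    "predict_probability",
    "default_lambda_grid",
]


def class_weights(labels) -> tuple[float, float]:
    """Balanced class weights ``w_c = n / (2 n_c)`` -> (w_pos, w_neg)."""
    y = np.asarray(labels, dtype=bool)
    n = y.size
    n_pos = int(y.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataError("both classes must be present to compute class weights")
    return n / (2.0 * n_pos), n / (2.0 * n_neg)


def _sample_weights(y: np.ndarray, weighted: bool) -> np.ndarray:
    if not weighted:
        return np.ones(y.size)
    w_pos, w_neg = class_weights(y)
    return np.where(y, w_pos, w_neg)


def make_design(
    records: pd.DataFrame,
    features: pd.DataFrame | None = None,
    design: str = "clinical_only",
    feature_names: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble (X, y) for one design.

    ``clinical_only`` uses the PALN indicator; ``radiomics_only`` the selected
    (or all) feature columns; ``combined`` their concatenation.  ``y`` is the
    OFR-within-36-months indicator.  ``features`` must be indexed by
    patient_id.
    """
    ids = records["patient_id"]
    y = pd.Series(records["ofr_event"].to_numpy(dtype=int), index=ids.to_numpy(), name="ofr_event")
    clinical = pd.DataFrame({"paln": records["paln"].to_numpy(dtype=int)}, index=ids.to_numpy())
    if design == "clinical_only":
        return clinical, y
    if features is None:
        raise DataError("radiomics designs require a feature table")
    missing = [pid for pid in ids if pid not in features.index]
    if missing:
        raise DataError(f"patients missing from feature table: {missing[:5]}")
    rad = features.loc[ids.to_numpy()]
    if feature_names is not None:
        rad = rad[list(feature_names)]
    if design == "radiomics_only":
        return rad, y
    if design == "combined":
        return pd.concat([clinical, rad], axis=1), y
    raise ValueError(f"unknown design {design!r}")


def default_lambda_grid(n: int = 50) -> np.ndarray:
    return np.logspace(-4, 2, n)


@dataclass
class PenalizedLogitResults:
    """Fitted penalized logistic model."""

    family: str
    feature_names: list[str]
    coef: np.ndarray
    intercept: float
    lambda_: float
    loo_path: pd.DataFrame
    mean_: np.ndarray
    scale_: np.ndarray
    sample_weighted: bool

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            np.concatenate([[self.intercept], self.coef]),
            index=["intercept"] + self.feature_names,
        )

    @property
    def selected_features(self) -> list[str]:
        return [n for n, c in zip(self.feature_names, self.coef) if c != 0.0]

    def predict_proba(self, X) -> np.ndarray:
        X = self._check_columns(X)
        z = (X - self.mean_) / self.scale_
        eta = z @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))

    def _check_columns(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if list(X.columns) != self.feature_names:
                if set(X.columns) != set(self.feature_names):
                    raise DataError(
                        f"feature columns do not match training columns: {list(X.columns)} vs {self.feature_names}"
                    )
                X = X[self.feature_names]
            return X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise DataError("feature count mismatch")
        return X

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef (standardized)": np.concatenate([[self.intercept], self.coef])},
            index=["intercept"] + self.feature_names,
        ).assign(selected=lambda d: d["coef (standardized)"] != 0.0)


class PenalizedLogit:
    """L1- or L2-penalized weighted logistic regression with LOO-tuned lambda.

    Objective: (1/n) sum_i w_i * logloss_i + lambda * ||beta||_1  (LASSO) or
    + (lambda/2) * ||beta||_2^2 (Ridge), on z-scored features.
    """

    def __init__(
        self,
        X,
        y,
        penalty: str = "l1",
        class_weighted: bool = True,
        lambda_grid: np.ndarray | None = None,
        seed: int = 0,
        tol: float = 1e-4,
    ):
        if isinstance(X, pd.DataFrame):
            self.feature_names = [str(c) for c in X.columns]
            self.X = X.to_numpy(dtype=float)
        else:
            self.X = np.asarray(X, dtype=float)
            self.feature_names = [f"x{i}" for i in range(self.X.shape[1])]
        if not np.all(np.isfinite(self.X)):
            raise DataError("non-finite features")
        self.y = np.asarray(y, dtype=int).ravel()
        if self.y.size != self.X.shape[0]:
            raise DataError("X/y length mismatch")
        if penalty not in ("l1", "l2"):
            raise ValueError(f"penalty must be 'l1' or 'l2', got {penalty!r}")
        self.penalty = penalty
        self.class_weighted = class_weighted
        self.lambda_grid = np.sort(np.asarray(lambda_grid if lambda_grid is not None else default_lambda_grid()))
        self.seed = seed
        self.tol = tol

    def _standardize(self, X):
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        return (X - mu) / sd, mu, sd

    def fit(self, method: str = "loo") -> PenalizedLogitResults:
        """Pick lambda by leave-one-out weighted log-loss, then refit on all data.

        All n leave-one-out subsets and the full training set are solved
        jointly along the lambda path by the batched proximal-gradient solver
        (see :mod:`ofrad._glmsolver`).
        """
        from ._glmsolver import penalized_logistic_path

        X, y = self.X, self.y
        n = len(y)
        if len(np.unique(y)) < 2:
            raise DataError("both classes required")
        z, mu, sd = self._standardize(X)
        w = _sample_weights(y.astype(bool), self.class_weighted)
        if method == "loo":
            # columns 0..n-1: leave-one-out subsets; column n: full data
            W = np.repeat(w[:, None], n + 1, axis=1)
            W[np.arange(n), np.arange(n)] = 0.0
            path_B = penalized_logistic_path(z, y, W, self.lambda_grid, self.penalty, tol=self.tol)
            z1 = np.concatenate([np.ones((n, 1)), z], axis=1)
            losses = np.empty(len(self.lambda_grid))
            for j in range(len(self.lambda_grid)):
                eta = np.einsum("ip,pi->i", z1, path_B[j][:, :n])
                p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
                p = np.clip(p, 1e-12, 1 - 1e-12)
                losses[j] = float(-(w * (y * np.log(p) + (1 - y) * np.log(1 - p))).sum())
            # ties to the larger (more regularized) lambda
            best = len(losses) - 1 - int(np.argmin(np.round(losses[::-1], 10)))
            lam = float(self.lambda_grid[best])
            full = path_B[best][:, n]
            path = pd.DataFrame({"lambda": self.lambda_grid, "loo_weighted_logloss": losses})
        elif method == "fixed":
            lam = float(self.lambda_grid[0])
            path_B = penalized_logistic_path(z, y, w[:, None], np.array([lam]), self.penalty, tol=min(self.tol, 1e-6))
            full = path_B[0][:, 0]
            path = pd.DataFrame({"lambda": [lam], "loo_weighted_logloss": [np.nan]})
        else:
            raise ValueError(f"unknown method {method!r}")
        # exact zeros: the proximal step produces true zeros for l1
        coef = full[1:].copy()
        return PenalizedLogitResults(
            family="lasso" if self.penalty == "l1" else "ridge",
            feature_names=self.feature_names,
            coef=coef,
            intercept=float(full[0]),
            lambda_=lam,
            loo_path=path,
            mean_=mu,
            scale_=sd,
            sample_weighted=self.class_weighted,
        )


@dataclass
class SklearnResults:
    """Results wrapper for the naive-Bayes / random-forest families."""

    family: str
    feature_names: list[str]
    estimator: object
    flags: list[str] = field(default_factory=list)
    oob_proba: np.ndarray | None = None

    def predict_proba(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.rename(columns=str)
            if set(X.columns) != set(self.feature_names):
                raise DataError("feature columns do not match training columns")
            X = X[self.feature_names].to_numpy(dtype=float)
        return self.estimator.predict_proba(np.asarray(X, dtype=float))[:, 1]

    def summary(self) -> pd.DataFrame:
        if self.family == "random_forest":
            return pd.DataFrame(
                {"importance": self.estimator.feature_importances_}, index=self.feature_names
            )
        return pd.DataFrame(
            {
                "mean_neg": self.estimator.theta_[0],
                "mean_pos": self.estimator.theta_[1],
                "var_neg": self.estimator.var_[0],
                "var_pos": self.estimator.var_[1],
            },
            index=self.feature_names,
        )


class GaussianNBModel:
    """Gaussian class-conditional naive Bayes with weighted class priors."""

    def __init__(self, X, y, class_weighted: bool = True):
        self.feature_names = [str(c) for c in X.columns] if isinstance(X, pd.DataFrame) else [
            f"x{i}" for i in range(np.asarray(X).shape[1])
        ]
        self.X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int).ravel()
        self.class_weighted = class_weighted

    def fit(self) -> SklearnResults:
        y = self.y
        if len(np.unique(y)) < 2:
            raise DataError("both classes required")
        if self.class_weighted:
            # weighted class frequencies w_c * n_c / n = 1/2 each
            priors = np.array([0.5, 0.5])
        else:
            priors = np.array([(y == 0).mean(), (y == 1).mean()])
        flags = []
        for k, name in enumerate(self.feature_names):
            for cls in (0, 1):
                if self.X[y == cls, k].var() == 0:
                    flags.append(f"zero-variance feature {name} in class {cls}")
        est = GaussianNB(priors=priors)  # var_smoothing floors degenerate variances
        est.fit(self.X, y)
        return SklearnResults("naive_bayes", self.feature_names, est, flags=flags)


class RandomForestModel:
    """Gini random forest (500 trees, sqrt(p) features per split, seeded)."""

    def __init__(
        self,
        X,
        y,
        n_estimators: int = 500,
        max_depth: int | None = None,
        class_weighted: bool = True,
        seed: int = 0,
        oob: bool = True,
    ):
        self.feature_names = [str(c) for c in X.columns] if isinstance(X, pd.DataFrame) else [
            f"x{i}" for i in range(np.asarray(X).shape[1])
        ]
        self.X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int).ravel()
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.class_weighted = class_weighted
        self.seed = seed
        self.oob = oob

    def fit(self) -> SklearnResults:
        if len(np.unique(self.y)) < 2:
            raise DataError("both classes required")
        est = RandomForestClassifier(
            n_estimators=self.n_estimators,
            criterion="gini",
            max_features="sqrt",
            max_depth=self.max_depth,
            random_state=self.seed,
            oob_score=self.oob,
            class_weight="balanced" if self.class_weighted else None,
        )
        est.fit(self.X, self.y)
        oob = est.oob_decision_function_[:, 1] if self.oob else None
        return SklearnResults("random_forest", self.feature_names, est, oob_proba=oob)


def predict_probability(results, X) -> np.ndarray:
    """Per-patient probability of OFR within 36 months from any fitted Results."""
    if not hasattr(results, "predict_proba"):
        raise NotFittedError("object has no predict_proba; fit a model first")
    return np.asarray(results.predict_proba(X), dtype=float)
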