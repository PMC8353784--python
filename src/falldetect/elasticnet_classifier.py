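"""Elastic-net penalized logistic regression for the second detection stage.

The classifier maps the 40 windowed IMU features to a posterior fall
probability. Training minimises

    (1/n) sum_i -[y_i log p_i + (1 - y_i) log(1 - p_i)]
        + lam * (alpha * ||w||_1 + (1 - alpha)/2 * ||w||_2^2)

with p_i = sigmoid(b + w . x_i), the intercept unpenalized and features
standardized (zero mean, unit sample std) before fitting. The deployment
defaults are alpha = 0.6, lam = 0.015 with the alert threshold 0.908 — the
5th percentile of the training-fall posteriors, targeting 95 % training
sensitivity.

The solver is deterministic cyclic coordinate descent with soft-thresholding
on a quadratic majorization of the logistic loss (curvature bound 1/4), which
descends monotonically on this jointly convex objective.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .feature_extraction import FEATURE_NAMES, N_FEATURES, FeatureVector, compute_features
from .imu_core import SensorWindow

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1
DEFAULT_ALPHA = 0.6
DEFAULT_LAM = 0.015
DEFAULT_THRESHOLD = 0.908  # deployment constant: 5th pct of training-fall posteriors

_EPS = 1e-15


@dataclass
class ElasticNetModel:
    """A fitted (or default-initialised) elastic-net logistic model.

    Weights live in standardized feature space; zero-variance features carry
    std 1 and weight exactly 0.
    """

    feature_means: np.ndarray
    feature_stds: np.ndarray
    weights: np.ndarray
    intercept: float
    alpha: float = DEFAULT_ALPHA
    lam: float = DEFAULT_LAM
    threshold: float = DEFAULT_THRESHOLD
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.feature_means = np.asarray(self.feature_means, dtype=np.float64)
        self.feature_stds = np.asarray(self.feature_stds, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")
        if np.any(self.feature_stds <= 0):
            raise ValueError("feature_stds must be positive")

    def to_json(self) -> str:
        return json.dumps(
            {
                "format_version": MODEL_FORMAT_VERSION,
                "feature_names": list(self.feature_names),
                "feature_means": self.feature_means.tolist(),
                "feature_stds": self.feature_stds.tolist(),
                "weights": self.weights.tolist(),
                "intercept": self.intercept,
                "alpha": self.alpha,
                "lam": self.lam,
                "threshold": self.threshold,
            },
            indent=1,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "ElasticNetModel":
        doc = json.loads(text)
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format {doc.get('format_version')!r}")
        return cls(
            feature_means=np.array(doc["feature_means"]),
            feature_stds=np.array(doc["feature_stds"]),
            weights=np.array(doc["weights"]),
            intercept=float(doc["intercept"]),
            alpha=float(doc["alpha"]),
            lam=float(doc["lam"]),
            threshold=float(doc["threshold"]),
            feature_names=tuple(doc["feature_names"]),
        )

    @classmethod
    def load(cls, path) -> "ElasticNetModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


@dataclass
class TrainingSet:
    """Feature matrix, binary labels (1 = fall) and participant groups.

    By construction of the two-stage detector, only windows that passed the
    2 g screen belong in a training set.
    """

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y)
        self.groups = np.asarray(self.groups)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-d")
        if not (len(self.X) == len(self.y) == len(self.groups)):
            raise ValueError("X, y, groups must align")
        if not np.all(np.isin(self.y, (0, 1))):
            raise ValueError("y must be binary (1 = fall)")
        self.y = self.y.astype(np.float64)

    def subset(self, mask: np.ndarray) -> "TrainingSet":
        return TrainingSet(self.X[mask], self.y[mask], self.groups[mask])


def training_set_from_windows(
    windows: Sequence[SensorWindow],
    groups: Sequence[str],
) -> TrainingSet:
    """Build a TrainingSet from labeled valid windows (label 'fall' -> 1)."""
    X = np.vstack([compute_features(w).values for w in windows])
    y = np.array([1.0 if w.label == "fall" else 0.0 for w in windows])
    return TrainingSet(X, y, np.asarray(groups))


def standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column means and sample stds; zero-variance columns get std 1.

    Columns reported with std exactly 1 because their variance is zero are
    masked from fitting by :func:`fit` (their weight stays 0).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("X must be 2-d with at least 2 rows")
    means = X.mean(axis=0)
    stds = X.std(axis=0, ddof=1)
    stds = np.where(_near_zero_std(stds, means), 1.0, stds)
    return means, stds


def _near_zero_std(stds: np.ndarray, means: np.ndarray) -> np.ndarray:
    # scale-relative: a numerically constant column must count as zero-variance
    return stds <= 1e-12 * np.maximum(1.0, np.abs(means))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def objective(
    w: np.ndarray,
    b: float,
    X_std: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
) -> float:
    """Mean negative log-likelihood plus the elastic-net penalty (intercept free)."""
    p = np.clip(_sigmoid(X_std @ w + b), _EPS, 1.0 - _EPS)
    nll = -np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    penalty = lam * (alpha * np.sum(np.abs(w)) + 0.5 * (1.0 - alpha) * np.sum(w**2))
    return float(nll + penalty)


def _soft_threshold(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def fit(
    train: TrainingSet,
    alpha: float = DEFAULT_ALPHA,
    lam: float = DEFAULT_LAM,
    tol: float = 1e-8,
    max_cycles: int = 10_000,
) -> ElasticNetModel:
    """Fit the penalized model by cyclic coordinate descent.

    Each coordinate step minimises a quadratic upper bound of the logistic
    loss (second-derivative bound 1/4) plus the penalty, via
    soft-thresholding; the intercept gets an unpenalized bound step.
    Convergence: objective decrease below ``tol`` over a full cycle, at most
    ``max_cycles`` cycles, deterministic cyclic order.
    """
    y = train.y
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("fit requires both classes present")
    means, stds = standardize_fit(train.X)
    raw_stds = train.X.std(axis=0, ddof=1)
    active = ~_near_zero_std(raw_stds, means)
    Xs = (train.X - means) / stds
    Xs[:, ~active] = 0.0
    n, d = Xs.shape

    w = np.zeros(d)
    b = float(np.log(np.mean(y) / (1.0 - np.mean(y))))  # warm start at base rate
    score = np.full(n, b)
    # per-coordinate curvature bound: (1/4n) sum x_ij^2
    curv = 0.25 * np.mean(Xs**2, axis=0)
    curv_b = 0.25

    obj = objective(w, b, Xs, y, alpha, lam)
    l1 = lam * alpha
    l2 = lam * (1.0 - alpha)
    converged = False
    for _cycle in range(max_cycles):
        # intercept step
        g_b = float(np.mean(_sigmoid(score) - y))
        db = -g_b / curv_b
        b += db
        score += db
        for j in range(d):
            if not active[j]:
                continue
            g_j = float(np.mean((_sigmoid(score) - y) * Xs[:, j]))
            z = curv[j] * w[j] - g_j
            w_new = _soft_threshold(z, l1) / (curv[j] + l2)
            if w_new != w[j]:
                score += (w_new - w[j]) * Xs[:, j]
                w[j] = w_new
        new_obj = objective(w, b, Xs, y, alpha, lam)
        if obj - new_obj < tol:
            obj = new_obj
            converged = True
            break
        obj = new_obj
    if not converged:
        warnings.warn(
            f"coordinate descent did not converge in {max_cycles} cycles "
            f"(last objective {obj:.6g})",
            RuntimeWarning,
        )
    return ElasticNetModel(
        feature_means=means,
        feature_stds=stds,
        weights=w,
        intercept=b,
        alpha=alpha,
        lam=lam,
    )


def predict_posterior(model: ElasticNetModel, features) -> np.ndarray | float:
    """Posterior fall probability, strictly inside (0, 1).

    Accepts a single FeatureVector / 1-d array (returns a float) or an
    (n, 40) matrix (returns an array).
    """
    if isinstance(features, FeatureVector):
        x = features.values
    else:
        x = np.asarray(features, dtype=np.float64)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    z = (X - model.feature_means) / model.feature_stds
    p = np.clip(_sigmoid(z @ model.weights + model.intercept), _EPS, 1.0 - _EPS)
    return float(p[0]) if single else p


def calibrate_threshold(model: ElasticNetModel, X_fall: np.ndarray) -> float:
    """The 5th percentile (linear interpolation) of training-fall posteriors.

    Placing the alert cutoff here leaves at least 95 % of the training falls
    at or above the threshold. Requires at least 20 fall windows.
    """
    X_fall = np.atleast_2d(np.asarray(X_fall, dtype=np.float64))
    if len(X_fall) < 20:
        raise ValueError("calibrate_threshold requires >= 20 fall windows")
    posteriors = predict_posterior(model, X_fall)
    return float(np.percentile(posteriors, 5.0))


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation.

    Equals the probability that a random positive outranks a random negative,
    ties counted one half.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auroc requires both classes present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def loso_cv(
    train: TrainingSet,
    alpha: float = DEFAULT_ALPHA,
    lam: float = DEFAULT_LAM,
) -> tuple[dict[str, float], float]:
    """Leave-one-participant-out cross-validation.

    For each participant, fits on everyone else and scores the held-out
    windows; returns per-fold AUROCs keyed by participant plus their mean.
    Folds whose test windows contain a single class are skipped with a
    warning.
    """
    participants = np.unique(train.groups)
    if len(participants) < 2:
        raise ValueError("loso_cv requires >= 2 participants")
    folds: dict[str, float] = {}
    for pid in participants:
        test_mask = train.groups == pid
        y_test = train.y[test_mask]
        if len(np.unique(y_test)) < 2 or len(np.unique(train.y[~test_mask])) < 2:
            warnings.warn(f"LOSO fold {pid!r} has a single class; skipped", RuntimeWarning)
            continue
        model = fit(train.subset(~test_mask), alpha=alpha, lam=lam)
        scores = predict_posterior(model, train.X[test_mask])
        folds[str(pid)] = auroc(scores, y_test)
    mean = float(np.mean(list(folds.values()))) if folds else float("nan")
    return folds, mean


def grid_search(
    train: TrainingSet,
    alpha_grid: Sequence[float] = (0.2, 0.4, 0.6, 0.8, 1.0),
    lam_grid: Sequence[float] = tuple(np.logspace(-4, 0, 10)),
) -> tuple[float, float, pd.DataFrame]:
    """Pick (alpha, lam) maximising mean LOSO AUROC over the grid.

    Ties break toward larger lam then larger alpha (the sparser model); the
    full table of mean AUROCs is returned alongside the winner.
    """
    if not len(alpha_grid) or not len(lam_grid):
        raise ValueError("grids must be non-empty")
    rows = []
    for a in alpha_grid:
        for l in lam_grid:
            _, mean_auc = loso_cv(train, alpha=a, lam=l)
            rows.append({"alpha": a, "lam": l, "mean_auroc": mean_auc})
    table = pd.DataFrame(rows)
    best = table.sort_values(
        ["mean_auroc", "lam", "alpha"], ascending=[False, False, False], kind="stable"
    ).iloc[0]
    return float(best["alpha"]), float(best["lam"]), table
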