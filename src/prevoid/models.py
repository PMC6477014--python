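"""Three bladder-state classifiers, their voting combination and CV schemes.

The classifier trio mirrors the reference system: a support-vector
classifier in the sequential-minimal-optimisation lineage (one-vs-one
multiclass, linear kernel by default), an ordinary-least-squares regression
on the ordinal state index with forward stepwise feature selection scored by
the Akaike information criterion, and a bootstrap-aggregated (bagging)
ensemble of decision trees.  Their three per-sample opinions are combined by
majority vote, falling back to the (weighted) mean ordinal index rounded
towards the higher — safer — state when all three disagree.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import LeaveOneOut, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .evaluation import ConfusionMatrix
from .features import FEATURE_TABLE_COLUMNS
from .states import BladderState

__all__ = [
    "MODEL_FEATURE_COLUMNS",
    "CVScheme",
    "StepwiseOrdinalRegression",
    "TrainedModelSet",
    "DegenerateTrainingError",
    "design_matrix",
    "train_models",
    "predict_states",
    "vote",
    "cross_validate",
]

#: feature-table columns that enter the model design matrix (sex is encoded)
MODEL_FEATURE_COLUMNS = FEATURE_TABLE_COLUMNS[:-1]  # everything but the label

_SEX_CODE = {"M": 0.0, "F": 1.0}


class DegenerateTrainingError(ValueError):
    """Raised when training data contain fewer than two classes."""


def design_matrix(features: pd.DataFrame) -> np.ndarray:
    """Numeric design matrix in the fixed column order; sex encoded M→0, F→1."""
    X = features.loc[:, MODEL_FEATURE_COLUMNS].copy()
    X["sex"] = X["sex"].map(_SEX_CODE) if X["sex"].dtype == object else X["sex"]
    return X.to_numpy(dtype=float)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


class StepwiseOrdinalRegression:
    """OLS on the ordinal state index with forward stepwise AIC selection.

    Features are added greedily while the Akaike criterion
    AIC = n·ln(RSS/n) + 2(k+1) improves; prediction is the linear output
    rounded half-up to the nearest index and clipped to the valid range.
    Deterministic; no randomness involved.
    """

    def __init__(self) -> None:
        self.selected_: list[int] = []
        self.coef_: np.ndarray | None = None

    @staticmethod
    def _aic(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        n = y.size
        rss = max(float(resid @ resid), 1e-12)
        return n * math.log(rss / n) + 2.0 * X.shape[1], beta

    def fit(self, X: np.ndarray, y: np.ndarray) -> "StepwiseOrdinalRegression":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        ones = np.ones((n, 1))
        best_aic, beta = self._aic(ones, y)
        selected: list[int] = []
        remaining = list(range(p))
        while remaining:
            trial = [
                (self._aic(np.column_stack([ones] + [X[:, j] for j in selected + [j_new]]), y), j_new)
                for j_new in remaining
            ]
            (cand_aic, cand_beta), j_best = min(trial, key=lambda t: (t[0][0], t[1]))
            if cand_aic >= best_aic - 1e-9:
                break
            best_aic, beta = cand_aic, cand_beta
            selected.append(j_best)
            remaining.remove(j_best)
        self.selected_ = selected
        self.coef_ = beta
        return self

    def _check_fitted(self) -> None:
        if self.coef_ is None:
            raise RuntimeError("regression model is not fitted")

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Raw continuous state index."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        design = np.column_stack([np.ones(X.shape[0])] + [X[:, j] for j in self.selected_])
        return design @ self.coef_

    def predict(self, X: np.ndarray) -> np.ndarray:
        raw = self.decision_function(X)
        lo, hi = min(BladderState), max(BladderState)
        return np.clip(_round_half_up(raw), lo, hi).astype(int)


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation scheme: holdout, k-fold (default 10) or leave-one-out."""

    kind: str = "k_fold"
    test_fraction: float = 0.1
    k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("holdout", "k_fold", "loocv"):
            raise ValueError(f"unknown CV scheme: {self.kind!r}")
        if self.kind == "holdout" and not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.kind == "k_fold" and self.k < 2:
            raise ValueError("k must be at least 2")


@dataclass
class TrainedModelSet:
    """The three fitted classifiers plus training metadata."""

    svm_model: Pipeline
    regression_model: StepwiseOrdinalRegression
    bagging_model: BaggingClassifier
    training_metadata: dict = field(default_factory=dict)

    def predict_all(self, X: np.ndarray) -> np.ndarray:
        """(n, 3) integer state indices: columns svm, regression, bagging."""
        X = np.asarray(X, dtype=float)
        return np.column_stack(
            [
                self.svm_model.predict(X).astype(int),
                self.regression_model.predict(X),
                self.bagging_model.predict(X).astype(int),
            ]
        )


def _make_models(seed: int, svm_kernel: str, n_bags: int):
    svm = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svc", SVC(kernel=svm_kernel, C=1.0, random_state=seed)),
        ]
    )
    reg = StepwiseOrdinalRegression()
    bag = BaggingClassifier(
        estimator=DecisionTreeClassifier(random_state=seed),
        n_estimators=n_bags,
        random_state=seed,
    )
    return svm, reg, bag


def train_models(
    features,
    labels,
    seed: int = 0,
    svm_kernel: str = "linear",
    n_bags: int = 10,
) -> TrainedModelSet:
    """Fit the three classifiers on one feature matrix / label vector.

    ``features`` may be a feature-table DataFrame or a numeric matrix;
    ``labels`` integer state indices, BladderState values or state labels.
    Deterministic given ``seed``.
    """
    X = design_matrix(features) if isinstance(features, pd.DataFrame) else np.asarray(features, float)
    y = _coerce_labels(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise DegenerateTrainingError("training data contain a single class")
    svm, reg, bag = _make_models(seed, svm_kernel, n_bags)
    svm.fit(X, y)
    reg.fit(X, y)
    bag.fit(X, y)
    meta = {
        "class_counts": {int(c): int(n) for c, n in zip(classes, counts)},
        "n_samples": int(y.size),
        "seed": seed,
        "svm_kernel": svm_kernel,
        "n_bags": n_bags,
    }
    return TrainedModelSet(svm, reg, bag, meta)


def _coerce_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OU":
        return np.array([BladderState.from_label(str(v)) for v in arr], dtype=int)
    return arr.astype(int)


def predict_states(models: TrainedModelSet, fv) -> tuple[BladderState, BladderState, BladderState]:
    """The three classifiers' opinions for one feature vector.

    ``fv`` may be an :class:`EchoFeatureVector`, a feature-table row or a
    numeric vector in the model column order.
    """
    from .features import EchoFeatureVector

    if isinstance(fv, EchoFeatureVector):
        row = [getattr(fv, c) for c in MODEL_FEATURE_COLUMNS]
        row = [_SEX_CODE.get(v, v) if isinstance(v, str) else v for v in row]
        x = np.asarray(row, dtype=float)[None, :]
    elif isinstance(fv, pd.Series):
        x = design_matrix(fv.to_frame().T)
    else:
        x = np.asarray(fv, dtype=float).reshape(1, -1)
    s, r, b = models.predict_all(x)[0]
    return BladderState(int(s)), BladderState(int(r)), BladderState(int(b))


def vote(opinions, weights=None) -> BladderState:
    """Combine exactly three state opinions into one.

    A strict (weighted) majority wins; with a three-way disagreement the
    weighted mean ordinal index is rounded, half-way ties going to the
    higher — safer — state.
    """
    ops = [BladderState(int(o)) for o in opinions]
    if len(ops) != 3:
        raise ValueError("vote expects exactly three opinions")
    w = np.ones(3) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (3,) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be three non-negative numbers, not all zero")
    score: dict[BladderState, float] = {}
    for o, wi in zip(ops, w):
        score[o] = score.get(o, 0.0) + wi
    total = float(w.sum())
    for state, s in score.items():
        if s > total / 2.0:
            return state
    mean_idx = float(np.dot(w, [int(o) for o in ops]) / total)
    return BladderState(int(min(max(BladderState), math.floor(mean_idx + 0.5))))


def cross_validate(features, labels, scheme: CVScheme) -> dict[str, ConfusionMatrix]:
    """Out-of-fold confusion matrices for each classifier and the vote.

    Folds are stratified (seeded shuffling); every sample is predicted
    exactly once out-of-fold for k-fold and leave-one-out, and the held-out
    part once for holdout.  Returns matrices keyed ``smo``, ``lr``, ``eb``
    and ``voting`` (rows predicted, columns true).
    """
    X = design_matrix(features) if isinstance(features, pd.DataFrame) else np.asarray(features, float)
    y = _coerce_labels(labels)
    n = y.size
    if scheme.kind == "k_fold" and scheme.k > n:
        raise ValueError("k may not exceed the number of samples")

    if scheme.kind == "holdout":
        idx = np.arange(n)
        train_idx, test_idx = train_test_split(
            idx, test_size=scheme.test_fraction, random_state=scheme.seed, stratify=y
        )
        splits = [(train_idx, test_idx)]
    elif scheme.kind == "k_fold":
        kf = StratifiedKFold(n_splits=scheme.k, shuffle=True, random_state=scheme.seed)
        splits = list(kf.split(X, y))
    else:
        splits = list(LeaveOneOut().split(X))

    k = len(BladderState)
    mats = {name: np.zeros((k, k), dtype=int) for name in ("smo", "lr", "eb", "voting")}
    for train_idx, test_idx in splits:
        models = train_models(X[train_idx], y[train_idx], seed=scheme.seed)
        preds = models.predict_all(X[test_idx])
        voted = np.array([int(vote(row)) for row in preds])
        for name, col in zip(("smo", "lr", "eb"), preds.T):
            np.add.at(mats[name], (col, y[test_idx]), 1)
        np.add.at(mats["voting"], (voted, y[test_idx]), 1)
    return {name: ConfusionMatrix(m) for name, m in mats.items()}
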