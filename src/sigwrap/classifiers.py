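"""The three wrapped binary classifiers behind one fit / predict / rank contract.

* PLS-DA — bespoke NIPALS engine (see :mod:`sigwrap.pls`); ranking metric is
  the Variable Importance in Projection (VIP).
* Random Forest — 500 Gini CART trees, mtry = floor(sqrt(p)), unscaled
  features; ranking metric is the out-of-bag error-rate (permutation)
  importance.
* Linear SVM — C-SVM with cost 1 on mean-centered unit-variance features;
  ranking metric is the squared primal weights.

Ranks are dense (1 = most important), ties broken by ascending feature
index, so the rank vector is always a permutation of 1..p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from . import _forest
from .core import BinaryLabels, FeatureTable
from .pls import PlsModel, ScalingParams, fit_plsda, predict_plsda, vip

__all__ = [
    "RandomForestModel",
    "LinearSvmModel",
    "TrainedClassifier",
    "fit_rf",
    "fit_svm",
    "fit_classifier",
    "rank_features",
    "metric_to_ranks",
    "METHODS",
]

METHODS = ("plsda", "rf", "svm")


@dataclass
class RandomForestModel:
    """Fitted forest: flat tree arrays plus OOB permutation importance."""

    n_trees: int
    mtry: int
    trees: tuple  # (feat, thr, left, right, leaf, inbag) numba arrays
    importance: np.ndarray
    feature_ids: tuple[str, ...]
    positive_level: str
    negative_level: str

    def predict_values(self, values: np.ndarray) -> tuple[str, ...]:
        feat, thr, left, right, leaf, _ = self.trees
        votes = _forest.forest_votes(
            feat, thr, left, right, leaf, np.ascontiguousarray(values, dtype=np.float64)
        )
        # majority vote; exact tie -> positive level (matches the >= vote rule)
        return tuple(
            self.positive_level if 2 * v >= self.n_trees else self.negative_level
            for v in votes
        )


@dataclass
class LinearSvmModel:
    """Linear C-SVM on the scaled feature space."""

    cost: float
    weights: np.ndarray   # primal w, one weight per feature (scaled space)
    intercept: float
    scaling: ScalingParams
    estimator: SVC
    feature_ids: tuple[str, ...]
    positive_level: str
    negative_level: str

    def squared_weights(self) -> np.ndarray:
        return self.weights**2

    def predict_values(self, values: np.ndarray) -> tuple[str, ...]:
        Xs = self.scaling.apply(values)
        dec = Xs @ self.weights + self.intercept
        return tuple(
            self.positive_level if d > 0 else self.negative_level for d in dec
        )


@dataclass
class TrainedClassifier:
    """A fitted model with the uniform predict / rank contract.

    ``predict`` and ``ranking_metric`` are defined for exactly the feature
    set the model was trained on.
    """

    method: str
    model: object
    feature_ids: tuple[str, ...]

    def predict(self, test: FeatureTable) -> tuple[str, ...]:
        if test.feature_ids != self.feature_ids:
            raise ValueError("test features do not match the training features")
        return self.predict_values(test.values)

    def predict_values(self, values: np.ndarray) -> tuple[str, ...]:
        """Predict from a raw array whose columns follow ``feature_ids``."""
        if self.method == "plsda":
            m: PlsModel = self.model  # type: ignore[assignment]
            if not m.informative:
                level = m.positive_level if m.majority_positive else m.negative_level
                return tuple(level for _ in range(values.shape[0]))
            Xs = m.scaling.apply(values)
            yhat = Xs @ m.coef + m.y_mean
            return tuple(
                m.positive_level if v > 0 else m.negative_level for v in yhat
            )
        return self.model.predict_values(values)  # type: ignore[union-attr]

    def ranking_metric(self) -> np.ndarray:
        """Per-feature importance (larger = more important)."""
        if self.method == "plsda":
            return vip(self.model)
        if self.method == "rf":
            return self.model.importance
        return self.model.squared_weights()


def fit_rf(
    train: FeatureTable,
    labels: BinaryLabels,
    seed: int,
    *,
    n_trees: int = 500,
    mtry: int | None = None,
) -> RandomForestModel:
    """Fit a random forest on unscaled features.  Deterministic per seed."""
    if train.p < 1:
        raise ValueError("cannot fit a forest on a zero-feature table")
    if mtry is None:
        mtry = max(1, int(np.floor(np.sqrt(train.p))))
    X = np.ascontiguousarray(train.values, dtype=np.float64)
    y = labels.as_binary().astype(np.int64)
    seed = int(seed) % (2**31 - 1)
    trees = _forest.build_forest(X, y, n_trees, mtry, seed)
    importance = _forest.oob_importance(*trees, X, y, (seed + 1) % (2**31 - 1))
    return RandomForestModel(
        n_trees=n_trees,
        mtry=mtry,
        trees=trees,
        importance=importance,
        feature_ids=train.feature_ids,
        positive_level=labels.positive_level,
        negative_level=labels.negative_level,
    )


def fit_svm(
    train: FeatureTable, labels: BinaryLabels, *, cost: float = 1.0
) -> LinearSvmModel:
    """Fit a linear SVM (libsvm C-SVC) on scaled features."""
    if train.p < 1:
        raise ValueError("cannot fit an SVM on a zero-feature table")
    scaling = ScalingParams.fit(train.values)
    Xs = scaling.apply(train.values)
    y = labels.as_binary()
    est = SVC(kernel="linear", C=cost)
    est.fit(Xs, y)
    w = np.asarray(est.coef_).ravel()
    b = float(est.intercept_[0])
    return LinearSvmModel(
        cost=cost,
        weights=w,
        intercept=b,
        scaling=scaling,
        estimator=est,
        feature_ids=train.feature_ids,
        positive_level=labels.positive_level,
        negative_level=labels.negative_level,
    )


def fit_classifier(
    method: str,
    train: FeatureTable,
    labels: BinaryLabels,
    seed: int = 0,
    *,
    n_trees: int = 500,
    svm_cost: float = 1.0,
) -> TrainedClassifier:
    """Fit one of the wrapped classifiers and wrap it in the uniform contract."""
    if method == "plsda":
        model = fit_plsda(train, labels, seed=seed)
    elif method == "rf":
        model = fit_rf(train, labels, seed, n_trees=n_trees)
    elif method == "svm":
        model = fit_svm(train, labels, cost=svm_cost)
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return TrainedClassifier(method=method, model=model, feature_ids=train.feature_ids)


def metric_to_ranks(metric: np.ndarray) -> np.ndarray:
    """Dense ranks (1 = largest metric), ties broken by ascending index."""
    metric = np.asarray(metric, dtype=float)
    p = len(metric)
    order = np.lexsort((np.arange(p), -metric))
    ranks = np.empty(p, dtype=int)
    ranks[order] = np.arange(1, p + 1)
    return ranks


def rank_features(model: TrainedClassifier) -> np.ndarray:
    """Rank the training features by the classifier's importance metric."""
    return metric_to_ranks(model.ranking_metric())
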