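"""Hazard-index scorers and their cross-validated evaluation.

The hazard index is the classifier's cancer-class posterior scaled to
[0, 100]: for weighted k-nearest-neighbours it is the squared-inverse-
distance weight fraction carried by cancer neighbours; for bagged decision
trees it is the fraction of trees voting cancer (so bagged hazards are
integer multiples of 100 / n_trees).

Weighted KNN is implemented directly because its conventions matter here:
squared-inverse (1/d^2) weights, inclusion of all neighbours tied with the
k-th distance, and the exact-match rule that zero-distance neighbours decide
the vote alone.  The bagged ensemble delegates bootstrap resampling and CART
growing to scikit-learn, with the split cap mapped to a leaf-count cap
(a binary tree with s splits has s + 1 leaves).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import rankdata
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "KnnSpec",
    "BaggedTreesSpec",
    "EvaluationResult",
    "KnnHazardModel",
    "BaggedHazardModel",
    "build_model",
    "knn_hazard",
    "bagged_hazard",
    "cross_validate",
    "rank_auc",
]

POSITIVE_LABEL = "cancer"


@dataclass(frozen=True)
class KnnSpec:
    """Weighted KNN: Euclidean distance, squared-inverse weights."""

    k: int = 10

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class BaggedTreesSpec:
    """Bootstrap-aggregated CART trees (Gini), capped at ``max_splits``."""

    n_trees: int = 30
    max_splits: int = 218
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.max_splits < 1:
            raise ValueError("n_trees and max_splits must be >= 1")


class KnnHazardModel:
    def __init__(self, spec: KnnSpec):
        self.spec = spec
        self._X: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def fit(self, X, y) -> "KnnHazardModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(X) == 0:
            raise ValueError("empty training set")
        if self.spec.k > len(X):
            raise ValueError(f"k={self.spec.k} exceeds training size {len(X)}")
        self._X, self._y = X, y
        return self

    def hazard(self, queries) -> np.ndarray:
        """Hazard in [0, 100] for each query row.

        All neighbours tied with the k-th smallest distance are included.
        Any zero-distance (exact match) neighbours decide the vote alone.
        """
        if self._X is None:
            raise RuntimeError("model is not fitted")
        Q = np.atleast_2d(np.asarray(queries, dtype=float))
        d = cdist(Q, self._X)
        out = np.empty(len(Q))
        k = self.spec.k
        for i in range(len(Q)):
            di = d[i]
            kth = np.partition(di, k - 1)[k - 1]
            neigh = np.flatnonzero(di <= kth)  # includes distance ties at k-th
            dn, yn = di[neigh], self._y[neigh]
            exact = dn == 0.0
            if exact.any():
                out[i] = 100.0 * np.mean(yn[exact] == POSITIVE_LABEL)
                continue
            w = 1.0 / dn**2
            out[i] = 100.0 * w[yn == POSITIVE_LABEL].sum() / w.sum()
        return out


class BaggedHazardModel:
    def __init__(self, spec: BaggedTreesSpec):
        self.spec = spec
        self._ensemble: BaggingClassifier | None = None
        self._single_class: str | None = None

    def fit(self, X, y) -> "BaggedHazardModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(X) == 0:
            raise ValueError("empty training set")
        classes = np.unique(y)
        if len(classes) < 2:
            # degenerate single-class training: constant output
            import warnings

            warnings.warn("single-class training set: hazard is constant", RuntimeWarning)
            self._single_class = str(classes[0])
            self._ensemble = None
            return self
        self._single_class = None
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_leaf_nodes=self.spec.max_splits + 1,
            min_samples_leaf=1,
        )
        self._ensemble = BaggingClassifier(
            estimator=tree,
            n_estimators=self.spec.n_trees,
            bootstrap=True,
            random_state=self.spec.seed,
        ).fit(X, y)
        return self

    def hazard(self, queries) -> np.ndarray:
        """100 x fraction of trees voting the cancer class (hard votes)."""
        Q = np.atleast_2d(np.asarray(queries, dtype=float))
        if self._single_class is not None:
            value = 100.0 if self._single_class == POSITIVE_LABEL else 0.0
            return np.full(len(Q), value)
        if self._ensemble is None:
            raise RuntimeError("model is not fitted")
        classes = self._ensemble.classes_
        votes = np.zeros(len(Q))
        for est, feats in zip(self._ensemble.estimators_, self._ensemble.estimators_features_):
            # inner estimators predict encoded class indices
            votes += classes.take(est.predict(Q[:, feats]).astype(int)) == POSITIVE_LABEL
        return 100.0 * votes / self.spec.n_trees


def build_model(spec: KnnSpec | BaggedTreesSpec):
    if isinstance(spec, KnnSpec):
        return KnnHazardModel(spec)
    if isinstance(spec, BaggedTreesSpec):
        return BaggedHazardModel(spec)
    raise TypeError(f"unknown model spec {type(spec).__name__}")


def knn_hazard(X, y, spec: KnnSpec, queries) -> np.ndarray:
    return KnnHazardModel(spec).fit(X, y).hazard(queries)


def bagged_hazard(X, y, spec: BaggedTreesSpec, queries) -> np.ndarray:
    return BaggedHazardModel(spec).fit(X, y).hazard(queries)


def rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank statistic (ties get midranks)."""
    pos = np.asarray(y) == POSITIVE_LABEL
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _roc_points(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Empirical ROC as (FPR, TPR) pairs, thresholds descending."""
    pos = np.asarray(y) == POSITIVE_LABEL
    order = np.argsort(-scores, kind="stable")
    s, p = scores[order], pos[order]
    tp = np.cumsum(p)
    fp = np.cumsum(~p)
    # collapse threshold ties: keep last index of each distinct score
    distinct = np.flatnonzero(np.diff(s, append=-np.inf) != 0)
    tpr = tp[distinct] / max(1, int(pos.sum()))
    fpr = fp[distinct] / max(1, int((~pos).sum()))
    return np.column_stack([np.concatenate([[0.0], fpr]), np.concatenate([[0.0], tpr])])


@dataclass
class EvaluationResult:
    """Out-of-fold hazard scores, per-fold ROC points and pooled rank AUC."""

    auc: float
    fold_assignment: np.ndarray
    scores: np.ndarray
    labels: np.ndarray
    roc_per_fold: list[np.ndarray]
    n_folds: int
    seed: int

    def roc_table(self) -> pd.DataFrame:
        rows = []
        for fold, roc in enumerate(self.roc_per_fold):
            for fpr, tpr in roc:
                rows.append({"fold": fold, "fpr": fpr, "tpr": tpr})
        return pd.DataFrame(rows)

    def to_json(self) -> dict:
        return {"auc": self.auc, "n_folds": self.n_folds, "seed": self.seed,
                "n_rows": int(len(self.scores))}


def cross_validate(
    X, y, spec: KnnSpec | BaggedTreesSpec, folds: int = 5, seed: int = 0
) -> EvaluationResult:
    """Stratified k-fold evaluation; every row is scored exactly once."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.full(len(y), np.nan)
    assignment = np.full(len(y), -1)
    roc_per_fold = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            raise ValueError(
                f"fold {fold} lacks a class: add data or reduce the fold count"
            )
        model = build_model(spec)
        model.fit(X[train_idx], y[train_idx])
        scores[test_idx] = model.hazard(X[test_idx])
        assignment[test_idx] = fold
        roc_per_fold.append(_roc_points(scores[test_idx], y[test_idx]))
    return EvaluationResult(
        auc=rank_auc(scores, y),
        fold_assignment=assignment,
        scores=scores,
        labels=y,
        roc_per_fold=roc_per_fold,
        n_folds=folds,
        seed=seed,
    )
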