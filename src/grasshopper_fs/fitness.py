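"""Wrapper fitness: KNN classification error on a feature subset plus a size penalty.

The objective of the feature-selection search is

    fitness = weight_alpha * error + weight_beta * |subset| / D

with ``error`` the misclassification fraction of a k-nearest-neighbour
classifier trained on the selected columns of the training split and scored on
the evaluation split (held-out test portion for the holdout scheme, validation
portion for the three-way scheme).  Features are min-max scaled with the
scaling fitted on the training portion only.

The classifier is a named plug-in (``fit(X, y)`` / ``predict(X)``); only
``knn`` ships.  The KNN vote is deterministic: neighbour distance ties are
broken by training-set index (stable sort) and vote ties by the label of the
nearest neighbour among the tied classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import train_test_split

from .config import SplitSpec

__all__ = [
    "Dataset",
    "KNNClassifier",
    "CLASSIFIERS",
    "FeatureSelectionProblem",
    "subset_error",
    "fitness_value",
]


@dataclass
class Dataset:
    """A tabular classification dataset.

    ``informative_mask`` is only populated for synthetic data and records
    which columns were generated as class-informative (ground truth for
    recovery tests).
    """

    features: np.ndarray                 # (n_samples, D) float
    labels: np.ndarray                   # (n_samples,) categorical
    feature_names: list[str] = None      # type: ignore[assignment]
    informative_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n, d = self.features.shape
        if self.feature_names is None:
            self.feature_names = [f"f{i}" for i in range(d)]
        if len(self.feature_names) != d:
            raise ValueError("feature_names length must match the feature count")
        if len(self.labels) != n:
            raise ValueError("labels length must match the sample count")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain missing or non-finite values")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("need at least 2 distinct labels")
        if n < 10:
            raise ValueError("need at least 10 samples")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


class KNNClassifier:
    """k-nearest-neighbour majority vote with deterministic tie-breaking.

    Euclidean distance; distance ties resolved by training index (stable
    sort); vote ties resolved by the nearest neighbour whose label belongs to
    the tied set.
    """

    def __init__(self, k: int = 5):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "KNNClassifier":
        features = np.asarray(features, dtype=float)
        if self.k >= features.shape[0]:
            raise ValueError(
                f"k={self.k} must be smaller than the training size {features.shape[0]}")
        self._X = features
        self._classes, self._y = np.unique(np.asarray(labels), return_inverse=True)
        return self

    def _neighbours(self, dist: np.ndarray) -> np.ndarray:
        """Indices of the k nearest training rows, nearest first.

        Selection uses argpartition for speed; the selected k are then ordered
        by (distance, training index).  Rows where a training point outside
        the selection ties the kth distance fall back to a full stable sort so
        distance ties are always broken by training index.
        """
        k = self.k
        part = np.argpartition(dist, k - 1, axis=1)[:, :k]
        pdist = np.take_along_axis(dist, part, axis=1)
        order = np.lexsort((part, pdist), axis=1)
        nearest = np.take_along_axis(part, order, axis=1)
        kth = pdist.max(axis=1)
        boundary_tie = (dist <= kth[:, None]).sum(axis=1) > k
        for i in np.flatnonzero(boundary_tie):
            nearest[i] = np.argsort(dist[i], kind="stable")[:k]
        return nearest

    def predict(self, features: np.ndarray) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        dist = cdist(X, self._X)
        neigh = self._y[self._neighbours(dist)]             # (n_eval, k)
        n_eval, n_classes = X.shape[0], len(self._classes)
        counts = np.zeros((n_eval, n_classes), dtype=np.int64)
        np.add.at(counts, (np.repeat(np.arange(n_eval), self.k), neigh.ravel()), 1)
        pred = counts.argmax(axis=1)
        top = counts.max(axis=1)
        tied = (counts == top[:, None]).sum(axis=1) > 1
        for i in np.flatnonzero(tied):
            tied_classes = np.flatnonzero(counts[i] == top[i])
            for lab in neigh[i]:                            # nearest first
                if lab in tied_classes:
                    pred[i] = lab
                    break
        return self._classes[pred]


#: classifier plug-in registry; contract: fit(features, labels), predict(features)
CLASSIFIERS = {"knn": KNNClassifier}


def fitness_value(error: float, subset_size: int, total_features: int,
                  weight_alpha: float = 0.99, weight_beta: float = 0.01) -> float:
    """Weighted combination of classification error and subset-size ratio."""
    if not 0.0 <= error <= 1.0:
        raise ValueError("error must lie in [0, 1]")
    if not 0 <= subset_size <= total_features:
        raise ValueError("subset_size must lie in [0, total_features]")
    if abs(weight_alpha + weight_beta - 1.0) > 1e-9:
        raise ValueError("weight_alpha + weight_beta must equal 1")
    return weight_alpha * error + weight_beta * subset_size / total_features


def _minmax_scale(train: np.ndarray, *others: np.ndarray):
    lo = train.min(axis=0)
    span = train.max(axis=0) - lo
    span[span == 0] = 1.0       # constant columns scale to 0
    return tuple((x - lo) / span for x in (train, *others))


def _split_indices(labels: np.ndarray, split: SplitSpec, seed: int):
    """Stratified (or plain) row indices for (train, eval, test?)."""
    idx = np.arange(len(labels))
    strat = labels if split.stratified else None
    if split.scheme == "holdout":
        tr, ev = train_test_split(idx, test_size=split.test_fraction,
                                  random_state=seed, stratify=strat)
        return tr, ev, None
    tr, rest = train_test_split(idx, train_size=split.train_fraction,
                                random_state=seed, stratify=strat)
    rel = split.test_fraction / (split.validation_fraction + split.test_fraction)
    strat_rest = labels[rest] if split.stratified else None
    val, te = train_test_split(rest, test_size=rel,
                               random_state=seed, stratify=strat_rest)
    return tr, val, te


class FeatureSelectionProblem:
    """Callable wrapper objective over bit masks, with the split fixed up front.

    Splitting and min-max scaling are performed once at construction so the
    same mask always maps to the same fitness within a run; restriction to a
    mask is just column selection on the pre-scaled matrices.
    """

    def __init__(self, dataset: Dataset, k: int = 5,
                 split: SplitSpec | None = None, seed: int | None = None,
                 weight_beta: float = 0.01, classifier: str = "knn"):
        split = split or SplitSpec()
        if seed is None:
            seed = split.seed
        if classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {classifier!r}; "
                             f"registered: {sorted(CLASSIFIERS)}")
        self.dataset = dataset
        self.k = k
        self.split = split
        self.seed = seed
        self.weight_beta = weight_beta
        self.weight_alpha = 1.0 - weight_beta
        self._clf_cls = CLASSIFIERS[classifier]

        tr, ev, te = _split_indices(dataset.labels, split, seed)
        if k >= len(tr):
            raise ValueError(f"k={k} must be smaller than the training size {len(tr)}")
        X = dataset.features
        if te is None:
            self._Xtr, self._Xev = _minmax_scale(X[tr], X[ev])
            self._Xte = None
        else:
            self._Xtr, self._Xev, self._Xte = _minmax_scale(X[tr], X[ev], X[te])
            self._yte = dataset.labels[te]
        self._ytr = dataset.labels[tr]
        self._yev = dataset.labels[ev]

    @property
    def n_features(self) -> int:
        return self.dataset.n_features

    def _error_on(self, mask: np.ndarray, X_eval: np.ndarray, y_eval: np.ndarray) -> float:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != (self.n_features,):
            raise ValueError(f"mask must have shape ({self.n_features},)")
        if not mask.any():
            raise ValueError("empty mask: repair before evaluating the wrapper error")
        clf = self._clf_cls(self.k).fit(self._Xtr[:, mask], self._ytr)
        pred = clf.predict(X_eval[:, mask])
        return float(np.mean(pred != y_eval))

    def error(self, mask: np.ndarray) -> float:
        """Misclassification fraction on the search evaluation split."""
        return self._error_on(mask, self._Xev, self._yev)

    def test_error(self, mask: np.ndarray) -> float:
        """Misclassification fraction on the reserved test split (three-way only)."""
        if self._Xte is None:
            raise ValueError("no test split: use the three-way scheme")
        return self._error_on(mask, self._Xte, self._yte)

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask).astype(bool)
        return fitness_value(self.error(mask), int(mask.sum()), self.n_features,
                             self.weight_alpha, self.weight_beta)


def subset_error(dataset: Dataset, mask: np.ndarray, k: int = 5,
                 split: SplitSpec | None = None, seed: int | None = None) -> float:
    """One-off wrapper error of a single mask.

    Convenience wrapper around :class:`FeatureSelectionProblem`; when the same
    dataset/split is evaluated on many masks, build the problem once instead.
    """
    return FeatureSelectionProblem(dataset, k=k, split=split, seed=seed).error(mask)
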