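"""Distance-based classification on distributional features.

Classification works on the per-OTU posterior weight vectors: both L2
metrics are quadratic forms in weight differences, so a sample is
represented by one weight vector per OTU and distances add across OTUs.

* supervised k-means: the class "centre" per OTU is the arithmetic mean of
  member weight vectors (the minimizer of summed L2 distances); a sample is
  assigned to the nearest class centre by total distance.
* k-NN: a sample takes the modal label of its k nearest training samples
  under total distance; k is chosen by cross-validation on the training set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .distances import cc_l2_gram, d_l2_gram, pairwise_quadratic
from .mixture import ComponentSet
from .sample_dist import SampleDistribution


def as_weight_matrices(features) -> list[np.ndarray]:
    """Normalize per-OTU features to a list of (n_samples, n_comp) arrays.

    Accepts either weight matrices directly or per-OTU lists of
    :class:`SampleDistribution`.
    """
    out = []
    for f in features:
        if isinstance(f, np.ndarray):
            out.append(f)
        else:
            out.append(np.vstack([d.w for d in f]))
    return out


def metric_grams(
    components: Sequence[ComponentSet], metric: str
) -> list[np.ndarray]:
    """Per-OTU Gram matrices realizing the chosen metric in weight space."""
    if metric == "d_l2":
        return [d_l2_gram(c).G for c in components]
    if metric == "cc_l2":
        return [cc_l2_gram(c).G for c in components]
    raise ValueError(f"unknown metric {metric!r}")


def total_pairwise_distances(
    feats_a, feats_b, grams: Sequence[np.ndarray]
) -> np.ndarray:
    """Total (summed over OTUs) pairwise distances between two sample sets."""
    Wa = as_weight_matrices(feats_a)
    Wb = as_weight_matrices(feats_b)
    if not (len(Wa) == len(Wb) == len(grams)):
        raise ValueError("feature lists and Gram matrices cover different OTU sets")
    D = np.zeros((Wa[0].shape[0], Wb[0].shape[0]))
    for A, B, G in zip(Wa, Wb, grams):
        D += pairwise_quadratic(A, B, G)
    return D


@dataclass
class KMeansModel:
    """Per-class mean weight vectors for each OTU."""

    class_labels: np.ndarray
    class_mean_weights: list[np.ndarray]  # per OTU: (K, n_comp)
    components: list[ComponentSet]


@dataclass
class KNNModel:
    """Stored training weights and labels for neighbour search."""

    train_weights: list[np.ndarray]  # per OTU: (n_train, n_comp)
    train_labels: np.ndarray
    k: int
    components: list[ComponentSet]

    def __post_init__(self):
        n_train = self.train_weights[0].shape[0]
        if not 1 <= self.k <= n_train:
            raise ValueError("k must satisfy 1 <= k <= training size")


@dataclass
class PredictionReport:
    """Predicted labels with accuracy and, for binary tasks, P/R/F1."""

    y_pred: np.ndarray
    accuracy: float
    precision: Optional[float] = None
    recall: Optional[float] = None
    f1: Optional[float] = None
    tp: Optional[int] = None
    fp: Optional[int] = None
    fn: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
        }


def kmeans_fit(features, labels, components: Sequence[ComponentSet]) -> KMeansModel:
    """Class mean weight vectors per OTU (the summed-L2 minimizer)."""
    W = as_weight_matrices(features)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    means = []
    for Wj in W:
        M = np.empty((classes.size, Wj.shape[1]))
        for k, cl in enumerate(classes):
            members = Wj[labels == cl]
            if members.shape[0] == 0:
                raise ValueError(f"class {cl!r} has no training samples")
            M[k] = members.mean(axis=0)
        means.append(M)
    return KMeansModel(
        class_labels=classes, class_mean_weights=means, components=list(components)
    )


def kmeans_predict(
    model: KMeansModel,
    features,
    metric: str = "d_l2",
    grams: Optional[Sequence[np.ndarray]] = None,
) -> np.ndarray:
    """Assign each sample to the class with the nearest mean distribution.

    Exact ties go to the lowest class index (stable, documented rule).
    """
    if grams is None:
        grams = metric_grams(model.components, metric)
    D = total_pairwise_distances(features, model.class_mean_weights, grams)
    return model.class_labels[np.argmin(D, axis=1)]


def knn_predict(
    model: KNNModel,
    features,
    metric: str = "d_l2",
    grams: Optional[Sequence[np.ndarray]] = None,
) -> np.ndarray:
    """Modal label of the k nearest training samples by total distance.

    A tie in the label mode resolves to the label of the nearest neighbour
    among the tied classes.
    """
    if grams is None:
        grams = metric_grams(model.components, metric)
    D = total_pairwise_distances(features, model.train_weights, grams)
    return _knn_from_distances(D, model.train_labels, model.k)


def _knn_from_distances(D: np.ndarray, train_labels: np.ndarray, k: int) -> np.ndarray:
    train_labels = np.asarray(train_labels)
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    out = np.empty(D.shape[0], dtype=train_labels.dtype)
    for i in range(D.shape[0]):
        neigh = train_labels[order[i]]
        classes, counts = np.unique(neigh, return_counts=True)
        best = counts == counts.max()
        if best.sum() == 1:
            out[i] = classes[np.argmax(counts)]
        else:
            tied = set(classes[best])
            for lab in neigh:  # neighbours already ordered by distance
                if lab in tied:
                    out[i] = lab
                    break
    return out


def choose_k_cv(
    features,
    labels,
    metric: str = "d_l2",
    grams: Optional[Sequence[np.ndarray]] = None,
    components: Optional[Sequence[ComponentSet]] = None,
    grid: Sequence[int] = (1, 3, 5, 7, 9, 11, 13, 15),
    folds: int = 5,
    seed: int = 0,
) -> int:
    """Pick k maximizing stratified-CV accuracy; ties go to the smallest k."""
    W = as_weight_matrices(features)
    labels = np.asarray(labels)
    if grams is None:
        if components is None:
            raise ValueError("need grams or components to evaluate distances")
        grams = metric_grams(components, metric)
    grid = sorted(grid)
    n = labels.size
    folds = min(folds, int(np.min(np.unique(labels, return_counts=True)[1])))
    folds = max(folds, 2)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = np.zeros(len(grid))
    for train_idx, val_idx in skf.split(np.zeros(n), labels):
        D = np.zeros((val_idx.size, train_idx.size))
        for Wj, G in zip(W, grams):
            D += pairwise_quadratic(Wj[val_idx], Wj[train_idx], G)
        for g, k in enumerate(grid):
            kk = min(k, train_idx.size)
            pred = _knn_from_distances(D, labels[train_idx], kk)
            correct[g] += np.sum(pred == labels[val_idx])
    return grid[int(np.argmax(correct))]


def evaluate(y_true, y_pred, positive_label=None) -> PredictionReport:
    """Accuracy for any task; precision, recall, F1 for binary labels.

    The positive class defaults to the lexicographically second label.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction and truth lengths differ")
    classes = np.unique(y_true)
    unseen = np.setdiff1d(np.unique(y_pred), classes)
    if unseen.size:
        raise ValueError(f"predictions contain unseen labels: {unseen.tolist()}")
    acc = float(np.mean(y_true == y_pred))
    if classes.size != 2:
        return PredictionReport(y_pred=y_pred, accuracy=acc)
    pos = classes[1] if positive_label is None else positive_label
    tp = int(np.sum((y_pred == pos) & (y_true == pos)))
    fp = int(np.sum((y_pred == pos) & (y_true != pos)))
    fn = int(np.sum((y_pred != pos) & (y_true == pos)))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return PredictionReport(
        y_pred=y_pred,
        accuracy=acc,
        precision=precision,
        recall=recall,
        f1=f1,
        tp=tp,
        fp=fp,
        fn=fn,
    )
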