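"""End-to-end DCMD classifier over an OTU table.

Fits one bootstrap-averaged mixture per OTU on the training samples,
represents every sample as per-OTU posterior weight vectors, and classifies
with supervised k-means or k-NN under the D-L2 or CC-L2 metric.  All
estimation (component specification, weight fitting, bootstrap averaging,
class means, k selection) uses training data only; test samples enter only
through their counts and depths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import classifiers as clf
from .mixture import FittedMixture, fit_mixture
from .otu_table import OTUTable, compute_resolutions, Resolutions
from .sample_dist import component_pmf_matrix, posterior_weights

logger = logging.getLogger(__name__)


@dataclass
class DCMDClassifier:
    """Distance-based classification using mixture distributions.

    Parameters
    ----------
    B : bootstrap iterations for model averaging per OTU.
    metric : ``'d_l2'`` or ``'cc_l2'``.
    algorithm : ``'kmeans'`` or ``'knn'``.
    k : neighbour count for k-NN; ``None`` selects k by CV on the training set.
    seed : governs the bootstrap; per-OTU streams are derived as seed + OTU index.
    """

    B: int = 100
    metric: str = "d_l2"
    algorithm: str = "kmeans"
    k: Optional[int] = None
    n_models: int = 5
    seed: int = 0
    component_config: dict = field(default_factory=dict)

    def fit(self, train: OTUTable) -> "DCMDClassifier":
        if train.labels is None:
            raise ValueError("training table needs labels")
        self.resolutions_: Resolutions = compute_resolutions(train)
        self.mixtures_: list[FittedMixture] = []
        self.otu_ids_: list[str] = []
        self.skipped_otus_: list[str] = []
        for j in range(train.n_otus):
            counts = train.counts[:, j]
            if not np.any(counts > 0):
                logger.warning("skipping all-zero OTU %s", train.otu_ids[j])
                self.skipped_otus_.append(train.otu_ids[j])
                continue
            rng = np.random.default_rng(self.seed + j)
            self.mixtures_.append(
                fit_mixture(
                    counts,
                    self.resolutions_,
                    B=self.B,
                    rng=rng,
                    n_models=self.n_models,
                    **self.component_config,
                )
            )
            self.otu_ids_.append(train.otu_ids[j])
        if not self.mixtures_:
            raise ValueError("no fittable OTUs in the training table")
        self.components_ = [m.components for m in self.mixtures_]
        self.pmats_ = [component_pmf_matrix(m) for m in self.mixtures_]
        self._grams: dict[str, list[np.ndarray]] = {}
        self.train_labels_ = np.asarray(train.labels)
        self.train_weights_ = self.transform(train)
        self.kmeans_ = clf.kmeans_fit(
            self.train_weights_, self.train_labels_, self.components_
        )
        return self

    def grams(self, metric: Optional[str] = None) -> list[np.ndarray]:
        metric = metric or self.metric
        if metric not in self._grams:
            self._grams[metric] = clf.metric_grams(self.components_, metric)
        return self._grams[metric]

    def transform(self, table: OTUTable) -> list[np.ndarray]:
        """Per-OTU posterior weight matrices for the table's samples.

        Resolutions are measured against the training cohort's mean depth
        so train and test counts share one rate scale.
        """
        t = np.asarray(table.totals, dtype=float) / self.resolutions_.nbar
        if np.any(t <= 0):
            raise ValueError("every sample needs positive total reads")
        keep = [table.otu_ids.index(o) for o in self.otu_ids_]
        return [
            posterior_weights(table.counts[:, j], t, m)
            for j, m in zip(keep, self.mixtures_)
        ]

    def choose_k(self, grid=(1, 3, 5, 7, 9, 11, 13, 15), folds: int = 5) -> int:
        return clf.choose_k_cv(
            self.train_weights_,
            self.train_labels_,
            metric=self.metric,
            grams=self.grams(),
            grid=grid,
            folds=folds,
            seed=self.seed,
        )

    def predict(
        self,
        table: OTUTable,
        algorithm: Optional[str] = None,
        metric: Optional[str] = None,
    ) -> np.ndarray:
        algorithm = algorithm or self.algorithm
        metric = metric or self.metric
        feats = self.transform(table)
        return self.predict_from_features(feats, algorithm, metric)

    def predict_from_features(
        self,
        feats: Sequence[np.ndarray],
        algorithm: Optional[str] = None,
        metric: Optional[str] = None,
    ) -> np.ndarray:
        algorithm = algorithm or self.algorithm
        metric = metric or self.metric
        grams = self.grams(metric)
        if algorithm == "kmeans":
            return clf.kmeans_predict(self.kmeans_, feats, metric, grams=grams)
        if algorithm == "knn":
            k = self.k if self.k is not None else self.choose_k()
            model = clf.KNNModel(
                train_weights=self.train_weights_,
                train_labels=self.train_labels_,
                k=k,
                components=self.components_,
            )
            return clf.knn_predict(model, feats, metric, grams=grams)
        raise ValueError(f"unknown algorithm {algorithm!r}")

    def score(
        self,
        table: OTUTable,
        algorithm: Optional[str] = None,
        metric: Optional[str] = None,
        positive_label=None,
    ) -> clf.PredictionReport:
        if table.labels is None:
            raise ValueError("scoring needs a labelled table")
        y_pred = self.predict(table, algorithm, metric)
        return clf.evaluate(table.labels, y_pred, positive_label=positive_label)


def train_test_split_table(
    table: OTUTable, test_fraction: float = 0.4, seed: int = 0, stratify: bool = True
):
    """Split a labelled table into train/test sample subsets.

    ``|test| = round(test_fraction * I)``; stratified by class by default.
    """
    if table.labels is None:
        raise ValueError("split needs labels")
    rng = np.random.default_rng(seed)
    I = table.n_samples
    n_test = int(round(test_fraction * I))
    if stratify:
        test_idx: list[int] = []
        classes = np.unique(table.labels)
        # largest-remainder apportionment of the test quota across classes
        sizes = np.array([np.sum(table.labels == c) for c in classes])
        quota = sizes * n_test / I
        base = np.floor(quota).astype(int)
        rem = n_test - base.sum()
        order = np.argsort(-(quota - base))
        base[order[:rem]] += 1
        for c, nc in zip(classes, base):
            members = np.flatnonzero(table.labels == c)
            test_idx.extend(rng.choice(members, size=nc, replace=False))
        test_idx = np.sort(np.asarray(test_idx))
    else:
        test_idx = np.sort(rng.choice(I, size=n_test, replace=False))
    train_idx = np.setdiff1d(np.arange(I), test_idx)
    return table.select_samples(train_idx), table.select_samples(test_idx)
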