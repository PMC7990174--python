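"""Comparison classifiers on relative-abundance features.

Distance-based baselines (supervised k-means and k-NN with Euclidean or
Manhattan distance, nearest shrunken centroid) and standard machine
learning classifiers (random forest, gradient boosting, LASSO, ridge
regression, SVM) all operate on the relative abundances q_ij = n_ij / N_i,
so every method sees the same train/test split objects as DCMD and
comparisons are paired within a replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .otu_table import OTUTable

DISTANCE_METHODS = (
    "kmeans-euclidean",
    "kmeans-manhattan",
    "knn-euclidean",
    "knn-manhattan",
    "nsc",
)
ML_METHODS = ("rf", "gb", "lasso", "rr", "svm")


@dataclass
class BaselineSpec:
    """A named baseline with optional hyperparameter overrides."""

    method: str
    hyperparameters: dict = field(default_factory=dict)
    tuning_folds: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.method not in DISTANCE_METHODS + ML_METHODS:
            raise ValueError(f"unsupported method {self.method!r}")


def relative_abundance_features(table: OTUTable) -> np.ndarray:
    """Feature matrix q_ij = n_ij / N_i (rows sum to at most 1)."""
    return table.relative_abundances()


# ---------------------------------------------------------------------------
# distance-based baselines


def _centroid_predict(X_test, centroids, classes, metric):
    D = cdist(X_test, centroids, metric=metric)
    return classes[np.argmin(D, axis=1)]


def kmeans_baseline_fit_predict(
    X_train, y_train, X_test, metric: str = "euclidean"
) -> np.ndarray:
    """Supervised k-means on raw relative abundances: class centroids are
    per-class feature means; assign to the nearest centroid."""
    y_train = np.asarray(y_train)
    classes = np.unique(y_train)
    centroids = np.vstack([X_train[y_train == c].mean(axis=0) for c in classes])
    metric = "cityblock" if metric == "manhattan" else metric
    return _centroid_predict(np.asarray(X_test), centroids, classes, metric)


def knn_baseline_fit_predict(
    X_train,
    y_train,
    X_test,
    metric: str = "euclidean",
    k: Optional[int] = None,
    grid=(1, 3, 5, 7, 9, 11, 13, 15),
    folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """k-NN on relative abundances; k chosen by CV on the training set."""
    from .classifiers import _knn_from_distances  # same neighbour/tie rules as DCMD

    X_train = np.asarray(X_train)
    X_test = np.asarray(X_test)
    y_train = np.asarray(y_train)
    metric = "cityblock" if metric == "manhattan" else metric
    if k is None:
        folds_eff = max(2, min(folds, int(np.min(np.unique(y_train, return_counts=True)[1]))))
        skf = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=seed)
        grid = sorted(grid)
        correct = np.zeros(len(grid))
        for tr, va in skf.split(X_train, y_train):
            D = cdist(X_train[va], X_train[tr], metric=metric)
            for g, kk in enumerate(grid):
                pred = _knn_from_distances(D, y_train[tr], min(kk, tr.size))
                correct[g] += np.sum(pred == y_train[va])
        k = grid[int(np.argmax(correct))]
    D = cdist(X_test, X_train, metric=metric)
    return _knn_from_distances(D, y_train, k)


def nsc_fit_predict(
    X_train,
    y_train,
    X_test,
    shrinkage: Optional[float] = None,
    s0_quantile: float = 0.5,
) -> np.ndarray:
    """Nearest (shrunken) centroid on relative abundances.

    Class centroids are per-class feature means; test samples minimize the
    standardized squared distance sum_j (x_j - centroid_kj)^2 / s_j^2 with
    s_j the pooled within-class standard deviation (floored to keep
    constant features harmless).  ``shrinkage`` soft-thresholds the
    standardized centroid offsets toward the overall centroid (0 or None
    means plain nearest centroid).
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train)
    classes = np.unique(y_train)
    if classes.size < 2:
        raise ValueError("NSC needs at least two classes")
    n, p = X_train.shape
    overall = X_train.mean(axis=0)
    centroids = np.vstack([X_train[y_train == c].mean(axis=0) for c in classes])
    # pooled within-class SD per feature
    ss = np.zeros(p)
    for k, c in enumerate(classes):
        block = X_train[y_train == c]
        ss += ((block - centroids[k]) ** 2).sum(axis=0)
    dof = max(n - classes.size, 1)
    s = np.sqrt(ss / dof)
    floor = np.quantile(s[s > 0], s0_quantile) if np.any(s > 0) else 1.0
    s = np.maximum(s, max(floor, 1e-12))
    if shrinkage:
        sizes = np.array([np.sum(y_train == c) for c in classes], dtype=float)
        mk = np.sqrt(1.0 / sizes - 1.0 / n)
        d = (centroids - overall) / (mk[:, None] * s[None, :])
        d = np.sign(d) * np.clip(np.abs(d) - shrinkage, 0.0, None)
        centroids = overall + mk[:, None] * s[None, :] * d
    D = ((X_test[:, None, :] - centroids[None, :, :]) ** 2 / s[None, None, :] ** 2).sum(
        axis=2
    )
    return classes[np.argmin(D, axis=1)]


# ---------------------------------------------------------------------------
# machine learning baselines


def _build_estimator(spec: BaselineSpec, n_features: int):
    hp = spec.hyperparameters
    seed = spec.seed
    cv = spec.tuning_folds
    if spec.method == "rf":
        mtry = sorted(
            {
                max(1, int(round(np.sqrt(n_features)))),
                max(1, n_features // 3),
                n_features,
            }
        )
        est = RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 500), random_state=seed, n_jobs=1
        )
        return GridSearchCV(
            est, {"max_features": hp.get("max_features_grid", mtry)}, cv=cv, n_jobs=1
        )
    if spec.method == "gb":
        est = GradientBoostingClassifier(
            n_estimators=hp.get("n_estimators", 300),
            n_iter_no_change=hp.get("n_iter_no_change", 5),
            validation_fraction=0.2,
            random_state=seed,
        )
        grid = {
            "max_depth": hp.get("max_depth_grid", [1, 2, 3]),
            "learning_rate": hp.get("learning_rate_grid", [0.01, 0.1]),
        }
        return GridSearchCV(est, grid, cv=cv, n_jobs=1)
    if spec.method in ("lasso", "rr"):
        # penalized logistic regression; features standardized so the
        # penalty path is meaningful on small relative abundances
        est = make_pipeline(
            StandardScaler(),
            LogisticRegression(
                l1_ratio=1.0 if spec.method == "lasso" else 0.0,
                solver="saga",  # handles l1/l2 and multiclass alike
                max_iter=5000,
                random_state=seed,
            ),
        )
        grid = {"logisticregression__C": hp.get("C_grid", list(np.logspace(-3, 3, 13)))}
        return GridSearchCV(est, grid, cv=hp.get("cv", 10), n_jobs=1)
    if spec.method == "svm":
        est = make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed))
        grid = {
            "svc__C": hp.get("C_grid", list(np.logspace(-2, 3, 6))),
            "svc__gamma": hp.get("gamma_grid", list(np.logspace(-3, 1, 5)) + ["scale"]),
        }
        return GridSearchCV(est, grid, cv=cv, n_jobs=1)
    raise ValueError(f"no estimator for {spec.method!r}")


def ml_fit_predict(spec: BaselineSpec, X_train, y_train, X_test) -> np.ndarray:
    """Fit a named ML baseline (CV-tuned where appropriate) and predict."""
    est = _build_estimator(spec, np.asarray(X_train).shape[1])
    est.fit(np.asarray(X_train), np.asarray(y_train))
    return est.predict(np.asarray(X_test))


def baseline_fit_predict(
    spec: BaselineSpec, train: OTUTable, test: OTUTable
) -> np.ndarray:
    """Run any baseline on the relative abundances of a train/test pair."""
    X_train = relative_abundance_features(train)
    # test features on the test samples' own depths
    X_test = relative_abundance_features(test)
    y_train = train.labels
    if y_train is None:
        raise ValueError("training table needs labels")
    if spec.method.startswith("kmeans-"):
        return kmeans_baseline_fit_predict(
            X_train, y_train, X_test, metric=spec.method.split("-", 1)[1]
        )
    if spec.method.startswith("knn-"):
        return knn_baseline_fit_predict(
            X_train,
            y_train,
            X_test,
            metric=spec.method.split("-", 1)[1],
            seed=spec.seed,
            **spec.hyperparameters,
        )
    if spec.method == "nsc":
        return nsc_fit_predict(X_train, y_train, X_test, **spec.hyperparameters)
    return ml_fit_predict(spec, X_train, y_train, X_test)
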