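import numpy as np
import pytest

from conftest import make_mixture
from dcmd.classifiers import (
    KNNModel,
    choose_k_cv,
    evaluate,
    kmeans_fit,
    kmeans_predict,
    knn_predict,
    metric_grams,
    total_pairwise_distances,
)
from dcmd.sample_dist import component_pmf_matrix, SampleDistribution


@pytest.fixture
def mix():
    return make_mixture([0.3, 0.2, 0.3, 0.2], [(1.0, 1.0), (5.0, 1.0)], C=8)


def _weights(rng, n, k=4):
    return rng.dirichlet(np.ones(k), size=n)


def _toy_training(mix, rng, n_per_class=10):
    """Two classes concentrated on different components."""
    a = rng.dirichlet([8, 1, 1, 1], size=n_per_class)
    b = rng.dirichlet([1, 1, 1, 8], size=n_per_class)
    W = np.vstack([a, b])
    labels = np.array(["a"] * n_per_class + ["b"] * n_per_class)
    return [W], labels


class TestKMeans:
    def test_single_sample_class_mean_is_that_sample(self, mix):
        rng = np.random.default_rng(0)
        W = _weights(rng, 2)
        model = kmeans_fit([W], ["x", "y"], [mix.components])
        assert np.allclose(model.class_mean_weights[0][0], W[0])

    def test_means_lie_on_simplex(self, mix):
        rng = np.random.default_rng(1)
        feats, labels = _toy_training(mix, rng)
        model = kmeans_fit(feats, labels, [mix.components])
        sums = model.class_mean_weights[0].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_mean_minimizes_within_class_distance(self, mix):
        # the arithmetic mean minimizes summed quadratic-form distances;
        # compare against random simplex perturbations
        rng = np.random.default_rng(2)
        W = _weights(rng, 15)
        mu = W.mean(axis=0)
        for metric in ("d_l2", "cc_l2"):
            G = metric_grams([mix.components], metric)[0]
            base = sum((w - mu) @ G @ (w - mu) for w in W)
            for _ in range(1000):
                cand = rng.dirichlet(np.ones(4))
                val = sum((w - cand) @ G @ (w - cand) for w in W)
                assert val >= base - 1e-10

    def test_sample_equal_to_mean_classified_to_it(self, mix):
        rng = np.random.default_rng(3)
        feats, labels = _toy_training(mix, rng)
        model = kmeans_fit(feats, labels, [mix.components])
        query = [model.class_mean_weights[0][1][None, :]]
        assert kmeans_predict(model, query, "d_l2")[0] == "b"

    def test_equidistant_tie_goes_to_lowest_class_index(self, mix):
        W = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 1.0]])
        model = kmeans_fit([W], ["a", "b"], [mix.components])
        midpoint = [np.array([[0.5, 0.0, 0.0, 0.5]])]
        assert kmeans_predict(model, midpoint, "d_l2")[0] == "a"

    def test_agreement_with_bruteforce_distances(self, mix):
        rng = np.random.default_rng(4)
        feats, labels = _toy_training(mix, rng)
        model = kmeans_fit(feats, labels, [mix.components])
        queries = _weights(rng, 20)
        for metric in ("d_l2", "cc_l2"):
            G = metric_grams([mix.components], metric)[0]
            pred = kmeans_predict(model, [queries], metric)
            for i in range(20):
                d = [
                    (queries[i] - model.class_mean_weights[0][k])
                    @ G
                    @ (queries[i] - model.class_mean_weights[0][k])
                    for k in range(2)
                ]
                assert pred[i] == model.class_labels[int(np.argmin(d))]

    def test_invariant_to_duplicating_training_samples(self, mix):
        rng = np.random.default_rng(5)
        feats, labels = _toy_training(mix, rng)
        doubled = [np.vstack([feats[0], feats[0]])]
        m1 = kmeans_fit(feats, labels, [mix.components])
        m2 = kmeans_fit(doubled, np.concatenate([labels, labels]), [mix.components])
        queries = [_weights(rng, 10)]
        assert np.array_equal(
            kmeans_predict(m1, queries, "d_l2"), kmeans_predict(m2, queries, "d_l2")
        )

    def test_label_permutation_equivariance(self, mix):
        rng = np.random.default_rng(6)
        feats, labels = _toy_training(mix, rng)
        swapped = np.where(labels == "a", "b", "a")
        queries = [_weights(rng, 12)]
        p1 = kmeans_predict(kmeans_fit(feats, labels, [mix.components]), queries, "d_l2")
        p2 = kmeans_predict(kmeans_fit(feats, swapped, [mix.components]), queries, "d_l2")
        assert np.array_equal(p1, np.where(p2 == "a", "b", "a"))


class TestKNN:
    def test_k1_on_training_point_returns_its_label(self, mix):
        rng = np.random.default_rng(0)
        feats, labels = _toy_training(mix, rng)
        model = KNNModel(feats, labels, k=1, components=[mix.components])
        pred = knn_predict(model, [feats[0][3][None, :]], "d_l2")
        assert pred[0] == labels[3]

    def test_k_equals_training_size_gives_majority(self, mix):
        rng = np.random.default_rng(1)
        W = _weights(rng, 9)
        labels = np.array(["a"] * 6 + ["b"] * 3)
        model = KNNModel([W], labels, k=9, components=[mix.components])
        assert np.all(knn_predict(model, [_weights(rng, 5)], "d_l2") == "a")

    def test_training_accuracy_one_at_k1(self, mix):
        rng = np.random.default_rng(2)
        feats, labels = _toy_training(mix, rng)
        model = KNNModel(feats, labels, k=1, components=[mix.components])
        assert np.array_equal(knn_predict(model, feats, "d_l2"), labels)

    def test_agreement_with_bruteforce_sort(self, mix):
        rng = np.random.default_rng(3)
        feats, labels = _toy_training(mix, rng, n_per_class=12)
        G = metric_grams([mix.components], "d_l2")
        queries = [_weights(rng, 15)]
        model = KNNModel(feats, labels, k=5, components=[mix.components])
        pred = knn_predict(model, queries, "d_l2", grams=G)
        D = total_pairwise_distances(queries, feats, G)
        for i in range(15):
            near = labels[np.argsort(D[i], kind="stable")[:5]]
            vals, counts = np.unique(near, return_counts=True)
            assert pred[i] == vals[np.argmax(counts)] or counts.max() == counts.min()

    def test_invalid_k_rejected(self, mix):
        rng = np.random.default_rng(4)
        feats, labels = _toy_training(mix, rng)
        with pytest.raises(ValueError):
            KNNModel(feats, labels, k=0, components=[mix.components])


class TestChooseK:
    def test_singleton_grid(self, mix):
        rng = np.random.default_rng(0)
        feats, labels = _toy_training(mix, rng)
        assert choose_k_cv(feats, labels, components=[mix.components], grid=[7]) == 7

    def test_perfect_separation_ties_resolve_to_smallest(self, mix):
        W = np.vstack([
            np.tile([0.97, 0.01, 0.01, 0.01], (8, 1)),
            np.tile([0.01, 0.01, 0.01, 0.97], (8, 1)),
        ])
        labels = np.array(["a"] * 8 + ["b"] * 8)
        k = choose_k_cv([W], labels, components=[mix.components], grid=[1, 3, 5])
        assert k == 1

    def test_deterministic_given_seed(self, mix):
        rng = np.random.default_rng(1)
        W = _weights(rng, 30)
        labels = np.array(["a", "b"] * 15)
        k1 = choose_k_cv([W], labels, components=[mix.components], seed=5)
        k2 = choose_k_cv([W], labels, components=[mix.components], seed=5)
        assert k1 == k2


class TestEvaluate:
    def test_formula_case(self):
        y_true = np.array(["pos", "pos", "pos", "neg", "neg", "neg"])
        y_pred = np.array(["pos", "pos", "neg", "pos", "neg", "neg"])
        rep = evaluate(y_true, y_pred, positive_label="pos")
        assert (rep.tp, rep.fp, rep.fn) == (2, 1, 1)
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.recall == pytest.approx(2 / 3)
        assert rep.f1 == pytest.approx(2 / 3)

    def test_perfect_prediction(self):
        y = np.array(["a", "b", "a", "b"])
        rep = evaluate(y, y)
        assert rep.accuracy == 1.0 and rep.f1 == 1.0

    def test_single_class_predictions_on_balanced_truth(self):
        y_true = np.array(["a", "b"] * 10)
        rep = evaluate(y_true, np.full(20, "b"))
        assert rep.accuracy == 0.5
        assert rep.recall == 1.0  # positive class defaults to "b"

    def test_multiclass_reports_accuracy_only(self):
        y = np.array(["a", "b", "c", "a"])
        rep = evaluate(y, y)
        assert rep.accuracy == 1.0 and rep.precision is None

    def test_unseen_labels_rejected(self):
        with pytest.raises(ValueError, match="unseen"):
            evaluate(np.array(["a", "b"]), np.array(["a", "c"]))
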