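import numpy as np
import pytest

from dcmd.mixture import (
    AggregateCounts,
    CandidateModel,
    ComponentSet,
    FittedMixture,
    GammaComponent,
    aggregate_counts,
    bootstrap_model_average,
    build_nested_models,
    expected_aggregate,
    fit_mixture,
    fit_weights,
    nb_count_prob,
    nb_pmf_grid,
    specify_components,
)
from dcmd.otu_table import Resolutions


def _res(n, t=None):
    return Resolutions(t=np.ones(n) if t is None else np.asarray(t), nbar=1000.0)


class TestNBProb:
    def test_geometric_closed_form(self):
        g = GammaComponent(1.0, 1.0)
        for x in range(6):
            assert nb_count_prob(x, g, 1.0) == pytest.approx(0.5 ** (x + 1))

    def test_p0_is_success_prob_to_alpha(self):
        assert nb_count_prob(0, GammaComponent(2.0, 1.0), 1.0) == pytest.approx(0.25)

    @pytest.mark.parametrize("alpha,beta,t", [(1, 1, 1), (3.5, 2.0, 0.7), (8, 1, 1.25)])
    def test_pmf_normalizes(self, alpha, beta, t):
        g = GammaComponent(alpha, beta)
        total = sum(nb_count_prob(x, g, t) for x in range(3000))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_grid_matches_scalar(self):
        alphas, betas = np.array([1.0, 4.5]), np.array([1.0, 2.0])
        t = np.array([0.8, 1.3])
        grid = nb_pmf_grid(alphas, betas, t, 10)
        for m in range(2):
            for x in range(11):
                for i in range(2):
                    assert grid[m, x, i] == pytest.approx(
                        nb_count_prob(x, GammaComponent(alphas[m], betas[m]), t[i]),
                        rel=1e-12,
                    )


class TestSpecifyComponents:
    def test_low_count_otu_collapses_high_grid(self):
        counts = np.array([0, 1, 2, 7, 3, 0])
        comp = specify_components(counts)
        assert comp.C == 8
        highs = [g.alpha for g in comp.gammas if g.alpha >= 8]
        assert highs == [8.0]

    def test_grid_endpoints_log_uniform(self):
        counts = np.concatenate([np.zeros(10, dtype=int), np.full(40, 100)])
        comp = specify_components(counts, n_high=12)
        highs = np.array([g.alpha for g in comp.gammas if g.alpha >= 8])
        assert highs.size == 12
        assert highs[0] == pytest.approx(8.0) and highs[-1] == pytest.approx(100.0)
        assert np.allclose(np.diff(np.log(highs)), np.diff(np.log(highs))[0])

    def test_zero_mass_only_when_zeros_observed(self):
        assert not specify_components(np.array([1, 2, 3, 9])).has_zero_mass
        assert specify_components(np.array([0, 2, 3, 9])).has_zero_mass

    def test_all_zero_otu_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            specify_components(np.zeros(5, dtype=int))

    def test_component_order_ascending_mean(self):
        comp = specify_components(np.array([0, 1, 5, 40, 2, 0, 7]))
        means = [g.mean for g in comp.gammas]
        assert means == sorted(means)
        assert means[0] == pytest.approx(0.5)  # Gamma(1,2) leads


class TestNestedModels:
    def test_progressive_exclusion(self):
        full = specify_components(np.array([0, 1, 2, 3, 10, 30]))
        models = build_nested_models(full, n_models=2)
        assert models[0].components == full
        dropped = set(full.gammas) - set(models[1].components.gammas)
        assert dropped == {GammaComponent(1.0, 2.0)}

    def test_single_model_is_full(self):
        full = specify_components(np.array([0, 1, 5]))
        assert build_nested_models(full, 1)[0].components == full

    def test_candidates_keep_masses_and_high_components(self):
        full = specify_components(np.array([0, 1, 2, 3, 10, 30]))
        for cand in build_nested_models(full, 5):
            assert cand.components.has_zero_mass and cand.components.has_high_mass
            kept_means = [g.mean for g in cand.components.gammas]
            assert all(m in kept_means for m in [4, 5, 6, 7, 8])

    def test_too_many_models_rejected(self):
        full = specify_components(np.array([0, 1, 2, 3, 10]))
        with pytest.raises(ValueError):
            build_nested_models(full, 6)


class TestExpectedAggregate:
    def test_pure_zero_mass(self):
        full = specify_components(np.array([0, 0, 1, 3]))
        model = CandidateModel(full, index=1)
        w = np.zeros(full.n_components)
        w[full.zero_index] = 1.0
        yE = expected_aggregate(model, w, _res(4))
        assert yE[0] == pytest.approx(4.0)
        assert np.allclose(yE[1:], 0.0)

    def test_conservation_for_random_simplex_weights(self):
        full = specify_components(np.array([0, 1, 2, 9, 30, 2]))
        model = CandidateModel(full, index=1)
        rng = np.random.default_rng(0)
        for _ in range(5):
            w = rng.dirichlet(np.ones(full.n_components))
            yE = expected_aggregate(model, w, _res(6))
            assert yE.sum() == pytest.approx(6.0, abs=1e-9)

    def test_single_geometric_component(self):
        comp = ComponentSet(
            gammas=(GammaComponent(1.0, 1.0),), C=8,
            has_zero_mass=False, has_high_mass=False,
        )
        model = CandidateModel(comp, index=1)
        yE = expected_aggregate(model, np.array([1.0]), _res(100))
        assert yE[0] == pytest.approx(50.0)


class TestFitWeights:
    def test_perfect_fit_recovers_single_component(self):
        # aggregate generated exactly as I * pmf of Gamma(5,1)
        comp = specify_components(np.array([0, 1, 2, 3, 5, 9]))
        model = CandidateModel(comp, index=1)
        I = 1000
        target = GammaComponent(5.0, 1.0)
        idx = comp.gamma_slice.start + [g.alpha for g in comp.gammas].index(5.0)
        pmf = nb_pmf_grid(np.array([5.0]), np.array([1.0]), np.ones(1), comp.C)[0, :, 0]
        y = np.concatenate([pmf, [1 - pmf.sum()]]) * I
        agg = AggregateCounts(y=y, I=I, C=comp.C)
        agg.y = y  # exact expected frequencies (not integers by design)
        w, obj = fit_weights(model, agg, _res(I))
        assert w[idx] == pytest.approx(1.0, abs=1e-6)
        assert obj == pytest.approx(0.0, abs=1e-8)

    def test_matches_dense_grid_search_on_two_components(self):
        # brute-force oracle: simplex grid at step 0.001
        comp = ComponentSet(
            gammas=(GammaComponent(1.0, 1.0), GammaComponent(6.0, 1.0)),
            C=10, has_zero_mass=False, has_high_mass=True,
        )
        model = CandidateModel(comp, index=1)
        rng = np.random.default_rng(1)
        counts = np.concatenate([rng.poisson(1.0, 300), rng.poisson(6.0, 700)])
        agg = aggregate_counts(counts, comp.C)
        w, obj = fit_weights(model, agg, _res(1000))
        pmf = nb_pmf_grid(comp.alphas(), comp.betas(), np.ones(1), comp.C)[:, :, 0]
        A = np.zeros((comp.C + 2, 3))
        A[:-1, :2] = pmf.T
        A[-1, :2] = 1 - pmf.sum(axis=1)
        A[-1, 2] = 1.0
        best = np.inf
        for a in np.arange(0, 1.0005, 0.001):
            for b in np.arange(0, 1 - a + 0.0005, 0.05):
                r = 1000 * (A @ np.array([a, b, 1 - a - b])) - agg.y
                best = min(best, r @ r)
        assert obj <= best + 1e-6

    def test_recovers_zero_inflation_weight(self):
        # counts from 0.3 structural zero + 0.7 Gamma(5,1), I = 2000
        rng = np.random.default_rng(7)
        I = 2000
        is_zero = rng.random(I) < 0.3
        rates = rng.gamma(5.0, 1.0, size=I)
        counts = np.where(is_zero, 0, rng.poisson(rates))
        comp = specify_components(counts)
        model = CandidateModel(comp, index=1)
        w, _ = fit_weights(model, aggregate_counts(counts, comp.C), _res(I))
        assert abs(w[comp.zero_index] - 0.3) < 0.05

    def test_objective_not_worse_than_uniform_start(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(2.0, 400)
        comp = specify_components(counts)
        model = CandidateModel(comp, index=1)
        agg = aggregate_counts(counts, comp.C)
        w, obj = fit_weights(model, agg, _res(400))
        uniform = np.full(comp.n_components, 1.0 / comp.n_components)
        yE = expected_aggregate(model, uniform, _res(400))
        assert obj <= (agg.y - yE) @ (agg.y - yE) + 1e-9


class TestBootstrapAverage:
    def test_single_candidate_trivial(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3.0, 200)
        comp = specify_components(counts)
        fm = bootstrap_model_average(
            counts, _res(200), [CandidateModel(comp, 1)], B=10, seed=0
        )
        assert fm.model_probs.tolist() == [1.0]
        assert np.allclose(fm.w, fm.per_model_w[0])

    def test_joint_weights_are_convex_combination(self):
        rng = np.random.default_rng(1)
        counts = np.concatenate([np.zeros(150, dtype=int), rng.poisson(4.0, 250)])
        fm = fit_mixture(counts, _res(400), B=25, seed=5)
        assert fm.model_probs.sum() == pytest.approx(1.0)
        assert fm.w.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(fm.w >= -1e-12)
        assert np.allclose(fm.w, fm.model_probs @ fm.per_model_w, atol=1e-10)

    def test_scale_consistency_in_totals(self):
        # multiplying all N_i by a constant leaves t, hence the fit, unchanged
        rng = np.random.default_rng(2)
        counts = rng.poisson(2.0, 300)
        totals = rng.integers(500, 2000, 300).astype(float)
        r1 = Resolutions(t=totals / totals.mean(), nbar=totals.mean())
        r2 = Resolutions(t=(totals * 9) / (totals * 9).mean(), nbar=(totals * 9).mean())
        f1 = fit_mixture(counts, r1, B=20, seed=3)
        f2 = fit_mixture(counts, r2, B=20, seed=3)
        assert np.allclose(f1.w, f2.w)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(1.5, 250)
        f1 = fit_mixture(counts, _res(250), B=15, seed=11)
        f2 = fit_mixture(counts, _res(250), B=15, seed=11)
        assert np.array_equal(f1.w, f2.w)
        assert np.array_equal(f1.model_probs, f2.model_probs)

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        counts = rng.poisson(2.5, 150)
        fm = fit_mixture(counts, _res(150), B=10, seed=1)
        p = tmp_path / "fit.json"
        fm.to_json(p)
        back = FittedMixture.from_json(p)
        assert back.components == fm.components
        assert np.array_equal(back.w, fm.w)
        assert np.array_equal(back.per_model_w, fm.per_model_w)
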