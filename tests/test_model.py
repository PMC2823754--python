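"""The supervised mixture-of-experts model: E-step, EM fit, prediction, reports."""

import numpy as np
import pytest

import hme3m
from hme3m import (
    HME3MModel,
    MarkovMixtureParams,
    PLRExpert,
    SimulationConfig,
    component_scores,
    dominant_path_report,
    e_step,
    fit_hme3m,
    fit_plr,
    predict,
    predict_proba,
    predict_proba_plr,
    roc_auc,
    simulate_pathways,
)
from hme3m.markov import component_path_probability
from hme3m.network import ConfigurationError

from test_markov import random_params


def build_model(network, m, rng, betas=None):
    mix = random_params(network, m, rng)
    P = network.n_edges
    if betas is None:
        betas = [rng.normal(scale=0.5, size=P + 1) for _ in range(m)]
    experts = [PLRExpert(beta=b) for b in betas]
    return HME3MModel(mixture=mix, experts=experts, config={"M": m})


@pytest.fixture(scope="module")
def clean_sim():
    """Small benchmark network with no noise paths."""
    return simulate_pathways(SimulationConfig(network_size="small",
                                              noise_fraction=0.0, seed=3))


class TestEStep:
    def test_single_component_gives_all_ones(self, example_network):
        model = build_model(example_network, 1, np.random.default_rng(0))
        X = np.array(hme3m.enumerate_paths(example_network))
        y = np.array([0, 1, 1, 0])
        H = e_step(model, X, y)
        np.testing.assert_allclose(H, 1.0)

    def test_identical_components_yield_rows_proportional_to_pi(self, example_network):
        rng = np.random.default_rng(1)
        base = random_params(example_network, 1, rng)
        beta = rng.normal(size=example_network.n_edges + 1)
        mix = MarkovMixtureParams(pi=np.array([0.2, 0.8]),
                                  theta=np.vstack([base.theta, base.theta]),
                                  network=example_network)
        model = HME3MModel(mixture=mix,
                           experts=[PLRExpert(beta=beta), PLRExpert(beta=beta)],
                           config={})
        X = np.array(hme3m.enumerate_paths(example_network))
        H = e_step(model, X, np.array([0, 1, 0, 1]))
        np.testing.assert_allclose(H, np.tile([0.2, 0.8], (4, 1)), atol=1e-12)

    def test_matches_direct_bayes_rule_hand_computation(self, example_network):
        rng = np.random.default_rng(2)
        model = build_model(example_network, 2, rng)
        X = np.array(hme3m.enumerate_paths(example_network))[:3]
        y = np.array([1, 0, 1])
        H = e_step(model, X, y)
        for i in range(3):
            w = []
            for m in range(2):
                px = component_path_probability(model.mixture.theta[m], X[i])
                py1 = predict_proba_plr(model.experts[m], X[i : i + 1])[0]
                py = py1 if y[i] == 1 else 1 - py1
                w.append(model.mixture.pi[m] * px * py)
            w = np.array(w)
            np.testing.assert_allclose(H[i], w / w.sum(), atol=1e-12)
        np.testing.assert_allclose(H.sum(axis=1), 1.0, atol=1e-10)


class TestFit:
    def test_perfectly_aligned_dominant_paths_are_learned(self, clean_sim):
        X, y = clean_sim.dataset.X, clean_sim.dataset.y
        model = fit_hme3m(X, y, clean_sim.network, 2, seed=0)
        assert hme3m.ccr(y, predict(model, X)) == 100.0
        # the component claiming each class puts nearly all its path
        # probability on that class's two dominant paths
        H = e_step(model, X, y)
        for cls in (0, 1):
            m = int(np.argmax(H[y == cls].sum(axis=0)))
            mass = sum(component_path_probability(model.mixture.theta[m], p)
                       for p in clean_sim.dominant_paths[cls])
            assert mass > 0.8

    def test_single_component_equals_standalone_plr(self, small_sim):
        X, y = small_sim.dataset.X, small_sim.dataset.y
        model = fit_hme3m(X, y, small_sim.network, 1, seed=0, n_restarts=1,
                          max_em_iter=200)
        standalone = fit_plr(X, y, lam=1.0, alpha=0.5, max_iter=5000, tol=1e-10)
        np.testing.assert_allclose(predict_proba(model, X),
                                   predict_proba_plr(standalone, X), atol=1e-6)

    def test_objective_trace_is_monotone_over_random_datasets(self):
        for seed in range(5):
            sim = simulate_pathways(SimulationConfig(
                network_size="small", noise_fraction=0.3, seed=seed))
            model = fit_hme3m(sim.dataset.X[:120], sim.dataset.y[:120],
                              sim.network, 2, seed=seed, n_restarts=1)
            diffs = np.diff(model.history)
            assert np.all(diffs >= -1e-8), f"seed {seed}: min diff {diffs.min()}"

    def test_seeded_fit_is_fully_reproducible(self, small_sim):
        X, y = small_sim.dataset.X, small_sim.dataset.y
        a = fit_hme3m(X, y, small_sim.network, 2, seed=42, n_restarts=2)
        b = fit_hme3m(X, y, small_sim.network, 2, seed=42, n_restarts=2)
        np.testing.assert_array_equal(a.mixture.theta, b.mixture.theta)
        for ea, eb in zip(a.experts, b.experts):
            np.testing.assert_array_equal(ea.beta, eb.beta)
        assert a.history == b.history

    def test_component_count_validation(self, small_sim):
        X, y = small_sim.dataset.X, small_sim.dataset.y
        with pytest.raises(ConfigurationError):
            fit_hme3m(X, y, small_sim.network, 0)
        with pytest.raises(ConfigurationError):
            fit_hme3m(X[:3], y[:3], small_sim.network, 5)

    def test_mixture_invariants_hold_after_fit(self, small_sim):
        model = fit_hme3m(small_sim.dataset.X, small_sim.dataset.y,
                          small_sim.network, 3, seed=1, n_restarts=1)
        model.mixture.validate(atol=1e-10)


class TestPredict:
    def test_zero_experts_predict_half(self, example_network):
        rng = np.random.default_rng(3)
        model = build_model(example_network, 2, rng,
                            betas=[np.zeros(6), np.zeros(6)])
        X = np.array(hme3m.enumerate_paths(example_network))
        np.testing.assert_allclose(predict_proba(model, X), 0.5)

    def test_single_component_reduces_to_expert(self, example_network):
        rng = np.random.default_rng(4)
        model = build_model(example_network, 1, rng)
        X = np.array(hme3m.enumerate_paths(example_network))
        np.testing.assert_allclose(predict_proba(model, X),
                                   predict_proba_plr(model.experts[0], X),
                                   atol=1e-12)

    def test_matches_hand_computed_gated_sum(self, example_network):
        rng = np.random.default_rng(5)
        model = build_model(example_network, 2, rng)
        X = np.array(hme3m.enumerate_paths(example_network))
        got = predict_proba(model, X)
        for i, x in enumerate(X):
            gate = np.array([model.mixture.pi[m]
                             * component_path_probability(model.mixture.theta[m], x)
                             for m in range(2)])
            gate = gate / gate.sum()
            expert = np.array([predict_proba_plr(model.experts[m], x[None, :])[0]
                               for m in range(2)])
            assert got[i] == pytest.approx(float(gate @ expert), abs=1e-12)

    def test_label_swap_flips_predictions(self, small_sim):
        X, y = small_sim.dataset.X, small_sim.dataset.y
        a = fit_hme3m(X, y, small_sim.network, 2, seed=7, n_restarts=1)
        b = fit_hme3m(X, 1 - y, small_sim.network, 2, seed=7, n_restarts=1)
        np.testing.assert_allclose(predict_proba(a, X), 1 - predict_proba(b, X),
                                   atol=1e-8)

    def test_probabilities_strictly_inside_unit_interval(self, small_sim):
        model = fit_hme3m(small_sim.dataset.X, small_sim.dataset.y,
                          small_sim.network, 2, seed=8, n_restarts=1)
        p = predict_proba(model, small_sim.dataset.X)
        assert np.all(p > 0) and np.all(p < 1)


class TestComponentScores:
    def test_zero_expert_gives_constant_scores_and_auc_half(self, example_network):
        model = build_model(example_network, 2, np.random.default_rng(6),
                            betas=[np.zeros(6), np.zeros(6)])
        X = np.array(hme3m.enumerate_paths(example_network))
        s = component_scores(model, X, 0)
        assert np.ptp(s) == 0.0
        auc, _, _ = roc_auc(np.array([0, 1, 0, 1]), s)
        assert auc == pytest.approx(0.5)

    def test_perfectly_separating_edge_gives_auc_one(self, example_network):
        beta = np.zeros(6)
        beta[1] = 10.0  # edge 1 determines the class
        model = build_model(example_network, 1, np.random.default_rng(7),
                            betas=[beta])
        X = np.array(hme3m.enumerate_paths(example_network))
        y = X[:, 0]
        auc, _, _ = roc_auc(y, component_scores(model, X, 0))
        assert auc == 1.0

    def test_scores_equal_direct_expert_probability(self, example_network):
        model = build_model(example_network, 2, np.random.default_rng(8))
        X = np.array(hme3m.enumerate_paths(example_network))
        np.testing.assert_array_equal(component_scores(model, X, 1),
                                      predict_proba_plr(model.experts[1], X))

    def test_out_of_range_component_raises(self, example_network):
        model = build_model(example_network, 2, np.random.default_rng(9))
        X = np.array(hme3m.enumerate_paths(example_network))
        with pytest.raises(IndexError):
            component_scores(model, X, 2)


class TestDominantPathReport:
    def test_one_hot_theta_reports_one_edge_per_source_node(self, example_network):
        theta = np.array([[1.0, 0.0, 1.0, 1.0, 0.0]])
        mix = MarkovMixtureParams(pi=np.array([1.0]), theta=theta,
                                  network=example_network)
        model = HME3MModel(mixture=mix, experts=[PLRExpert(beta=np.zeros(6))],
                           config={})
        rep = dominant_path_report(model, 0, threshold=0.5)
        assert rep["source"].tolist() == ["A", "B", "C"]
        assert rep["edge"].tolist() == [1, 3, 4]  # 1-based coordinates

    def test_threshold_zero_reports_every_edge(self, example_network):
        model = build_model(example_network, 1, np.random.default_rng(10))
        rep = dominant_path_report(model, 0, threshold=0.0)
        assert len(rep) == example_network.n_edges

    def test_fitted_report_recovers_generating_edges(self, clean_sim):
        X, y = clean_sim.dataset.X, clean_sim.dataset.y
        model = fit_hme3m(X, y, clean_sim.network, 2, seed=0)
        H = e_step(model, X, y)
        for cls in (0, 1):
            m = int(np.argmax(H[y == cls].sum(axis=0)))
            reported = set(dominant_path_report(model, m, 0.4)["edge"] - 1)
            generating = set(
                np.flatnonzero(np.max(clean_sim.dominant_paths[cls], axis=0)))
            assert generating <= reported


class TestSerializationAndExport:
    def test_json_round_trip_reproduces_predictions_exactly(self, tmp_path, small_sim):
        X, y = small_sim.dataset.X, small_sim.dataset.y
        model = fit_hme3m(X, y, small_sim.network, 2, seed=3, n_restarts=1)
        f = tmp_path / "model.json"
        model.to_json(f)
        back = HME3MModel.from_json(f)
        np.testing.assert_array_equal(predict_proba(model, X),
                                      predict_proba(back, X))
        assert back.config == model.config

    def test_graphml_theta_sums_to_one_per_source_node(self, tmp_path, small_sim):
        import networkx as nx

        model = fit_hme3m(small_sim.dataset.X, small_sim.dataset.y,
                          small_sim.network, 2, seed=4, n_restarts=1)
        f = tmp_path / "model.graphml"
        hme3m.export_graphml(model, f)
        g = nx.read_graphml(f)
        for m in (1, 2):
            sums: dict[str, float] = {}
            for u, _v, data in g.edges(data=True):
                sums[u] = sums.get(u, 0.0) + data[f"theta_{m}"]
            for node, total in sums.items():
                assert total == pytest.approx(1.0, abs=1e-9), node

    def test_dot_export_contains_gene_labels(self, tmp_path, example_network):
        model = build_model(example_network, 1, np.random.default_rng(11))
        f = tmp_path / "m.dot"
        hme3m.export_dot(model, f, m=0)
        text = f.read_text()
        assert text.startswith("digraph")
        for gene in example_network.genes:
            assert gene in text
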