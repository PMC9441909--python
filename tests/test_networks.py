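"""Residual and Ising symptom networks, structure search, centrality."""

import itertools

import numpy as np
import pytest

from smdsnet.cfa import fit_factor_model
from smdsnet.networks import (
    IsingFamily,
    IsingModel,
    RnmFamily,
    SeparationError,
    bootstrap_centrality,
    centrality,
    fit_ising,
    fit_rnm,
    ising_loglik,
    sample_ising,
    stepwise_search,
)
from smdsnet.polychoric import estimate_summary
from smdsnet.simulate import (
    SMDS_LOADINGS,
    SMDS_THRESHOLDS,
    simulate_residual_dependence,
)


def _edge_matrix(entries, J=9):
    W = np.zeros((J, J))
    for j, k, v in entries:
        W[j, k] = W[k, j] = v
    return W


class TestRnm:
    def test_empty_structure_equals_one_factor(self, onefactor_summary):
        rnm = fit_rnm(onefactor_summary, [])
        params, _, fit = fit_factor_model(onefactor_summary)
        np.testing.assert_allclose(rnm.loadings, params.loadings, atol=1e-8)
        assert abs(rnm.dwls.t0 - fit.t0) < 1e-8

    def test_single_edge_recovery(self, table_params):
        lam, tau = table_params
        om = _edge_matrix([(5, 8, 0.10)])
        ests = []
        for seed in (40, 41, 42):
            m = simulate_residual_dependence(lam, tau, om, 50_000, seed=seed)
            s = estimate_summary(m.values, [2] * 9)
            rnm = fit_rnm(s, [(5, 8)])
            ests.append(rnm.omega[5, 8])
        assert np.all(np.asarray(ests) > 0)
        assert abs(np.mean(ests) - 0.10) < 0.03

    def test_full_structure_saturates_correlations(self, onefactor_summary):
        rnm = fit_rnm(onefactor_summary, itertools.combinations(range(9), 2))
        assert rnm.dwls.t0 < 1e-6


class TestIsingModel:
    def test_uniform_at_zero_parameters(self):
        m = IsingModel(thresholds=np.zeros(9), weights=np.zeros((9, 9)))
        np.testing.assert_allclose(m.state_probs(), 1 / 512)

    def test_three_node_pairwise_marginal(self):
        m = IsingModel(thresholds=np.zeros(3),
                       weights=_edge_matrix([(0, 1, 1.0)], 3))
        p = m.state_probs()
        states = np.indices((2, 2, 2)).reshape(3, -1).T[:, ::-1]
        p11 = p[(states[:, 0] == 1) & (states[:, 1] == 1)].sum()
        assert p11 == pytest.approx(np.e / (3 + np.e), abs=1e-12)

    def test_all_zero_state_loglik_closed_form(self):
        ll = ising_loglik(np.zeros(9), np.zeros((9, 9)), np.zeros((1, 9)))
        assert ll == pytest.approx(-9 * np.log(2), abs=1e-12)

    def test_probabilities_renormalize_under_threshold_shift(self):
        rng = np.random.default_rng(0)
        W = _edge_matrix([(0, 1, 0.5), (2, 3, -0.4)], 5)
        t = rng.normal(size=5)
        m1 = IsingModel(thresholds=t, weights=W)
        m2 = IsingModel(thresholds=t + 0.7, weights=W)
        assert m1.state_probs().sum() == pytest.approx(1.0, abs=1e-12)
        assert m2.state_probs().sum() == pytest.approx(1.0, abs=1e-12)

    def test_loglik_matches_bruteforce_on_fitted_model(self):
        truth = IsingModel(thresholds=np.full(5, -0.8),
                           weights=_edge_matrix([(0, 1, 0.9)], 5))
        X = sample_ising(truth, 3000, seed=1)
        fit = fit_ising(X)
        # brute force: sum of log state probabilities
        p = fit.state_probs()
        states = np.indices((2,) * 5).reshape(5, -1).T[:, ::-1]
        lut = {tuple(s): np.log(pi) for s, pi in zip(states, p)}
        brute = sum(lut[tuple(row)] for row in X)
        assert fit.loglik == pytest.approx(brute, rel=1e-10)

    def test_separation_detected(self):
        X = np.zeros((100, 4), int)
        X[:, 1] = 1
        with pytest.raises(SeparationError):
            fit_ising(X)


class TestIsingFit:
    def test_parameter_recovery_within_ci(self):
        truth = IsingModel(
            thresholds=np.full(9, -1.2),
            weights=_edge_matrix([(0, 1, 0.9), (5, 8, 1.1), (3, 7, 0.8)]))
        X = sample_ising(truth, 13377, seed=2)
        fit = fit_ising(X)
        z = 2.807  # 99.5% normal quantile
        cover_t = np.abs(fit.thresholds - truth.thresholds) <= z * fit.thresholds_se
        assert cover_t.mean() >= 8 / 9
        for (j, k) in [(0, 1), (5, 8), (3, 7)]:
            assert (abs(fit.weights[j, k] - truth.weights[j, k])
                    <= z * fit.weights_se[j, k])

    def test_matches_pseudolikelihood_on_large_sample(self):
        """Cross-method check: exact ML vs independent node-wise logistic fits."""
        truth = IsingModel(
            thresholds=np.full(6, -0.9),
            weights=_edge_matrix([(0, 1, 0.8), (2, 4, 0.6)], 6))
        X = sample_ising(truth, 40_000, seed=3).astype(float)
        fit = fit_ising(X.astype(int))
        # pseudo-likelihood: logistic regression of each node on the others
        from smdsnet.impute import _logistic_irls

        W_pl = np.zeros((6, 6))
        for j in range(6):
            others = [k for k in range(6) if k != j]
            D = np.column_stack([np.ones(X.shape[0]), X[:, others]])
            beta, _ = _logistic_irls(D, X[:, j], ridge=1e-8)
            for i, k in enumerate(others):
                W_pl[j, k] = beta[1 + i]
        W_pl = (W_pl + W_pl.T) / 2
        np.testing.assert_allclose(fit.weights, W_pl, atol=0.08)


class TestStepwiseSearch:
    def test_recovers_true_ising_structure(self):
        truth = IsingModel(
            thresholds=np.full(9, -1.2),
            weights=_edge_matrix([(0, 1, 0.9), (5, 8, 1.1), (3, 7, 0.8)]))
        X = sample_ising(truth, 13377, seed=4)
        edges, trace, final = stepwise_search(IsingFamily(X), [], alpha=0.005)
        assert edges == [(0, 1), (3, 7), (5, 8)]
        for s in trace.steps:
            assert s.bic_after < s.bic_before

    def test_search_from_full_prunes_null_edges(self):
        truth = IsingModel(thresholds=np.full(5, -1.0),
                           weights=_edge_matrix([(0, 1, 1.0)], 5))
        X = sample_ising(truth, 10_000, seed=5)
        full = list(itertools.combinations(range(5), 2))
        edges, _, _ = stepwise_search(IsingFamily(X), full, alpha=0.005)
        assert (0, 1) in edges
        assert len(edges) <= 3

    def test_rnm_branch_recovers_injected_edges(self, table_params):
        lam, tau = table_params
        om = _edge_matrix([(3, 7, 0.15), (5, 8, 0.15), (6, 8, -0.15)])
        m = simulate_residual_dependence(lam, tau, om, 13377, seed=6)
        s = estimate_summary(m.values, [2] * 9)
        edges, trace, _ = stepwise_search(RnmFamily(s), [], alpha=0.005)
        assert set(edges) >= {(3, 7), (5, 8), (6, 8)}
        bics = [st.bic_after for st in trace.steps]
        assert all(b2 < b1 for b1, b2 in zip([st.bic_before for st in trace.steps], bics))

    def test_deterministic_given_data(self, onefactor_summary):
        e1, t1, _ = stepwise_search(RnmFamily(onefactor_summary), [], 0.005)
        e2, t2, _ = stepwise_search(RnmFamily(onefactor_summary), [], 0.005)
        assert e1 == e2
        assert [s.edge for s in t1.steps] == [s.edge for s in t2.steps]


class TestCentrality:
    def test_strength_absolute_sum(self):
        W = _edge_matrix([(0, 1, 0.3), (0, 2, -0.2)], 3)
        c = centrality(W)
        assert c.loc["node1", "strength"] == pytest.approx(0.5)

    def test_path_graph_hand_computation(self):
        W = _edge_matrix([(0, 1, 0.5), (1, 2, 0.5)], 3)
        c = centrality(W)
        assert c.loc["node1", "closeness"] == pytest.approx(1 / 6)
        assert c.loc["node2", "betweenness"] == pytest.approx(1.0)

    def test_symmetric_graph_equal_indices(self):
        W = np.full((4, 4), 0.4)
        np.fill_diagonal(W, 0.0)
        c = centrality(W)
        for col in ("strength", "closeness", "betweenness"):
            assert c[col].nunique() == 1

    def test_node_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        W = rng.uniform(0.1, 1.0, (6, 6))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        perm = rng.permutation(6)
        c1 = centrality(W)
        c2 = centrality(W[np.ix_(perm, perm)])
        for col in ("strength", "closeness", "betweenness"):
            np.testing.assert_allclose(c2[col].to_numpy(),
                                       c1[col].to_numpy()[perm], atol=1e-12)

    def test_disconnected_node_flagged(self):
        W = _edge_matrix([(0, 1, 0.5)], 3)
        c = centrality(W)
        assert c["disconnected"].any()
        assert c.loc["node3", "harmonic_closeness"] == 0.0


class TestBootstrapCentrality:
    def test_single_replicate_degenerate_interval(self):
        truth = IsingModel(thresholds=np.full(5, -0.5),
                           weights=_edge_matrix([(0, 1, 1.0), (1, 2, 0.5)], 5))
        X = sample_ising(truth, 2000, seed=7)
        ranks, dropped = bootstrap_centrality(X, truth.edges, B=1, seed=0)
        # distinct strengths: the interval collapses to the replicate's rank;
        # tied indices (isolated nodes) may span the tie by one unit
        st = ranks["strength"]
        assert (st["rank_lo"] == st["rank_hi"]).sum() >= 2
        for df in ranks.values():
            assert (df["rank_hi"] - df["rank_lo"] <= 1).all()

    def test_dominant_node_rank_pinned(self):
        entries = [(0, 1, 1.6), (0, 2, 1.6), (0, 3, 1.6), (1, 2, 0.2),
                   (2, 3, 0.2)]
        truth = IsingModel(thresholds=np.full(4, -1.0),
                           weights=_edge_matrix(entries, 4))
        X = sample_ising(truth, 8000, seed=8)
        ranks, _ = bootstrap_centrality(X, truth.edges, B=300, seed=1)
        st = ranks["strength"]
        assert st.loc["node1", "rank_lo"] == 1 and st.loc["node1", "rank_hi"] == 1

    def test_exchangeable_nodes_overlapping_intervals(self):
        truth = IsingModel(thresholds=np.full(4, -0.8),
                           weights=_edge_matrix([(0, 1, 0.6), (2, 3, 0.6)], 4))
        X = sample_ising(truth, 3000, seed=9)
        ranks, _ = bootstrap_centrality(X, truth.edges, B=300, seed=2)
        st = ranks["strength"]
        # nodes 1 and 3 play symmetric roles: intervals must overlap
        assert (st.loc["node1", "rank_lo"] <= st.loc["node3", "rank_hi"]
                and st.loc["node3", "rank_lo"] <= st.loc["node1", "rank_hi"])
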