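import numpy as np
import pytest

from sczag.adaptive_augmentation import (
    AugmentationConfig,
    CentralityScores,
    edge_centrality,
    edge_drop_probabilities,
    feature_dim_weights,
    feature_mask_probabilities,
    make_views,
    pagerank_centrality,
    sample_edge_view,
    sample_feature_mask,
)

from conftest import graph_from_edges, random_graph


def pagerank_dense_solve(G, damping):
    """Oracle: direct linear solve of (I - a A D^-1) sigma = 1."""
    deg = G.adjacency.sum(axis=1).astype(float)
    M = G.adjacency / deg[None, :]
    return np.linalg.solve(np.eye(G.n_nodes) - damping * M, np.ones(G.n_nodes))


class TestPagerank:
    def test_cycle_all_equal(self):
        G = graph_from_edges(5, [(i, (i + 1) % 5) for i in range(5)])
        sigma = pagerank_centrality(G).sigma
        np.testing.assert_allclose(sigma, sigma[0])

    def test_path_graph_worked_values(self):
        G = graph_from_edges(3, [(0, 1), (1, 2)])
        sigma = pagerank_centrality(G, damping=0.85).sigma
        np.testing.assert_allclose(sigma, [5.135, 9.730, 5.135], atol=1.5e-3)

    @pytest.mark.parametrize("seed,n", [(0, 20), (1, 50), (2, 200)])
    def test_matches_dense_solve(self, seed, n):
        G = random_graph(n, 3.0 / n, seed)
        sigma = pagerank_centrality(G, damping=0.85).sigma
        np.testing.assert_allclose(sigma, pagerank_dense_solve(G, 0.85), atol=1e-8)

    def test_scores_at_least_one(self):
        G = random_graph(30, 0.1, 3)
        assert pagerank_centrality(G).sigma.min() >= 1.0

    def test_invalid_damping(self):
        G = graph_from_edges(2, [(0, 1)])
        with pytest.raises(ValueError):
            pagerank_centrality(G, damping=1.0)


class TestEdgeCentrality:
    def test_equal_scores_give_score(self):
        G = graph_from_edges(2, [(0, 1)])
        s = edge_centrality(CentralityScores(np.array([3.0, 3.0]), 0.85), G)
        np.testing.assert_allclose(s["w"], [3.0])

    def test_hand_value(self):
        G = graph_from_edges(2, [(0, 1)])
        s = edge_centrality(CentralityScores(np.array([2.0, 4.0]), 0.85), G)
        np.testing.assert_allclose(s["w"], [3.0])
        np.testing.assert_allclose(s["s"], [np.log(3.0)])

    def test_symmetric_in_endpoints(self):
        G = graph_from_edges(3, [(0, 1), (1, 2)])
        sig = CentralityScores(np.array([1.0, 5.0, 9.0]), 0.85)
        s = edge_centrality(sig, G)
        # edge (1,2) mean = (5+9)/2 regardless of orientation
        np.testing.assert_allclose(sorted(s["w"]), [3.0, 7.0])


class TestDropProbabilities:
    def _probs(self, s, p_e=0.3, p_tau=0.7):
        edges = np.array([[0, i + 1] for i in range(len(s))])
        return edge_drop_probabilities(
            {"edges": edges, "s": np.asarray(s, dtype=float)}, p_e, p_tau
        ).p_edge

    def test_max_score_gets_zero(self):
        p = self._probs([np.log(1), np.log(2), np.log(3)])
        assert p[2] == 0.0

    def test_mean_score_gets_pe(self):
        s = [1.0, 2.0, 3.0]  # mean 2
        p = self._probs(s, p_e=0.3)
        np.testing.assert_allclose(p[1], 0.3)

    def test_three_value_hand_example(self):
        s = np.log([1.0, 2.0, 3.0])
        mu = s.mean()
        expected = np.minimum(0.3 * (s[-1] - s) / (s[-1] - mu), 0.7)
        np.testing.assert_allclose(self._probs(s), expected)

    def test_degenerate_all_equal(self):
        np.testing.assert_allclose(self._probs([1.0, 1.0]), 0.3)

    def test_truncation_at_p_tau(self):
        p = self._probs([0.0, 10.0, 10.0, 10.0], p_e=0.9, p_tau=0.5)
        assert p.max() <= 0.5

    def test_monotone_in_centrality(self, rng):
        s = np.sort(rng.normal(size=30))
        p = self._probs(s)
        assert np.all(np.diff(p) <= 1e-12)  # higher centrality => lower drop prob

    def test_empty_edges_error(self):
        with pytest.raises(ValueError, match="empty edge set"):
            edge_drop_probabilities({"edges": np.zeros((0, 2)), "s": np.array([])}, 0.3, 0.7)


class TestSampling:
    def test_zero_probability_keeps_graph(self):
        G = random_graph(15, 0.3, 0)
        pe = edge_drop_probabilities(
            {"edges": G.edge_list(), "s": np.zeros(len(G.edge_list()))}, 0.3, 0.7
        )
        pe.p_edge[:] = 0.0
        A = sample_edge_view(G, pe, seed=1)
        np.testing.assert_array_equal(A, G.adjacency)

    def test_keep_rate_matches_bernoulli(self):
        """Monte Carlo vs Bernoulli oracle: keep-rate within 3 SE of 1 - p."""
        G = graph_from_edges(2, [(0, 1)])
        p_tau = 0.7
        pe = edge_drop_probabilities(
            {"edges": G.edge_list(), "s": np.array([0.0])}, 0.5, p_tau
        )
        # single edge at mean score -> p = 0.5 (but s_max == mu: degenerate = 0.5)
        n_draws = 10_000
        kept = sum(
            int(sample_edge_view(G, pe, seed=s)[0, 1]) for s in range(n_draws)
        )
        p = pe.p_edge[0]
        se = np.sqrt(p * (1 - p) / n_draws)
        assert abs(kept / n_draws - (1 - p)) < 3 * se

    def test_seeded_reproducible(self):
        G = random_graph(20, 0.2, 2)
        pe = edge_drop_probabilities(
            {"edges": G.edge_list(), "s": np.arange(len(G.edge_list()), dtype=float)},
            0.4, 0.7,
        )
        np.testing.assert_array_equal(
            sample_edge_view(G, pe, 7), sample_edge_view(G, pe, 7)
        )

    def test_view_is_symmetric_subset(self):
        G = random_graph(20, 0.25, 3)
        pe = edge_drop_probabilities(
            {"edges": G.edge_list(), "s": np.arange(len(G.edge_list()), dtype=float)},
            0.4, 0.7,
        )
        A = sample_edge_view(G, pe, 11)
        np.testing.assert_array_equal(A, A.T)
        assert np.all(A <= G.adjacency)


class TestFeatureWeights:
    def test_equal_columns_equal_weights(self):
        sigma = CentralityScores(np.array([1.0, 2.0]), 0.85)
        s = feature_dim_weights(np.ones((2, 3)), sigma)
        np.testing.assert_allclose(s, s[0])

    def test_hand_value(self):
        sigma = CentralityScores(np.array([1.0, 3.0]), 0.85)
        s = feature_dim_weights(np.array([[1.0], [2.0]]), sigma)
        np.testing.assert_allclose(np.exp(s), [7.0])

    def test_negation_invariant_dense(self):
        sigma = CentralityScores(np.array([1.0, 3.0]), 0.85)
        X = np.array([[1.0, -1.0], [2.0, -2.0]])
        s = feature_dim_weights(X, sigma, dense=True)
        np.testing.assert_allclose(s[0], s[1])

    def test_all_zero_weights_error(self):
        sigma = CentralityScores(np.array([1.0, 1.0]), 0.85)
        with pytest.raises(ValueError, match="zero weight"):
            feature_dim_weights(np.zeros((2, 3)), sigma)

    def test_zero_column_gets_max_mask_probability(self):
        sigma = CentralityScores(np.array([1.0, 1.0]), 0.85)
        X = np.array([[1.0, 0.0], [2.0, 0.0]])
        s = feature_dim_weights(X, sigma)
        p = feature_mask_probabilities(s, 0.3, 0.7).p_dim
        assert p[1] == p.max()


class TestFeatureMask:
    def test_zero_probability_identity(self, rng):
        X = rng.normal(size=(5, 4))
        pf = feature_mask_probabilities(np.zeros(4), 0.3, 0.7)
        pf.p_dim[:] = 0.0
        Xm, mask = sample_feature_mask(X, pf, 1)
        np.testing.assert_array_equal(Xm, X)
        np.testing.assert_array_equal(mask, 1.0)

    def test_masked_columns_exactly_zero(self, rng):
        X = rng.normal(size=(10, 6))
        pf = feature_mask_probabilities(np.arange(6.0), 0.5, 0.7)
        Xm, mask = sample_feature_mask(X, pf, 3)
        for j in np.flatnonzero(mask == 0):
            assert np.all(Xm[:, j] == 0.0)

    def test_mask_rate_matches_bernoulli(self):
        """Monte Carlo vs Bernoulli oracle at p_i = 0.3 over 10,000 draws."""
        pf = feature_mask_probabilities(np.array([0.0]), 0.3, 0.7)
        assert pf.p_dim[0] == pytest.approx(0.3)
        X = np.ones((1, 1))
        n_draws = 10_000
        masked = sum(
            1 - sample_feature_mask(X, pf, seed=s)[1][0] for s in range(n_draws)
        )
        se = np.sqrt(0.3 * 0.7 / n_draws)
        assert abs(masked / n_draws - 0.3) < 3 * se


class TestMakeViews:
    def test_same_seed_identical(self, rng):
        G = random_graph(20, 0.25, 4)
        X = np.abs(rng.normal(size=(20, 8))) + 0.1
        cfg = AugmentationConfig()
        v1a, v2a = make_views(G, X, cfg, seed=5)
        v1b, v2b = make_views(G, X, cfg, seed=5)
        np.testing.assert_array_equal(v1a.adjacency, v1b.adjacency)
        np.testing.assert_array_equal(v2a.features, v2b.features)

    def test_views_differ_between_each_other(self, rng):
        G = random_graph(40, 0.15, 6)
        assert len(G.edges) >= 50
        X = np.abs(rng.normal(size=(40, 30))) + 0.1
        v1, v2 = make_views(G, X, AugmentationConfig(), seed=9)
        assert not np.array_equal(v1.adjacency, v2.adjacency)

    def test_view_edges_subset_of_original(self, rng):
        G = random_graph(25, 0.2, 8)
        X = np.abs(rng.normal(size=(25, 10))) + 0.1
        v1, v2 = make_views(G, X, AugmentationConfig(), seed=2)
        assert np.all(v1.adjacency <= G.adjacency)
        assert np.all(v2.adjacency <= G.adjacency)
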