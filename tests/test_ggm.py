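import numpy as np
import pandas as pd
import pytest

from omibone.ggm import (
    GaussianGraphicalModel,
    ebic,
    glasso_path,
    network_stats,
    refit_unregularized,
)


def _sample_cov(rng, p=4, n=500):
    X = rng.standard_normal((n, p))
    return np.cov(X, rowvar=False), n


class TestGlassoPath:
    def test_large_lambda_gives_empty_graph(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, 5))
        structures, _, _ = glasso_path(X, n_lambdas=5, lambda_ratio=0.9)
        assert structures[0] == frozenset()

    def test_small_lambda_reaches_dense_supports(self):
        rng = np.random.default_rng(1)
        Ktrue = np.eye(4) + 0.4 * (np.ones((4, 4)) - np.eye(4))
        X = rng.multivariate_normal(np.zeros(4), np.linalg.inv(Ktrue), 2000)
        structures, _, _ = glasso_path(X, n_lambdas=50, lambda_ratio=1e-3)
        assert max(len(s) for s in structures) == 6  # complete graph on 4

    def test_supports_deduplicated_and_sparsifying_order(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((300, 6))
        structures, _, _ = glasso_path(X, n_lambdas=40)
        assert len(structures) == len(set(structures))
        sizes = [len(s) for s in structures]
        assert sizes[0] == 0 and sizes == sorted(sizes)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            glasso_path(np.ones((3, 4)))


class TestRefit:
    def test_full_graph_equals_inverse_sample_covariance(self):
        rng = np.random.default_rng(3)
        S, n = _sample_cov(rng)
        full = frozenset((i, j) for i in range(4) for j in range(i + 1, 4))
        res = refit_unregularized(S, full, n)
        np.testing.assert_allclose(
            res.precision.to_numpy(), np.linalg.inv(S), atol=1e-10
        )

    def test_empty_graph_diagonal_mle(self):
        rng = np.random.default_rng(4)
        S, n = _sample_cov(rng)
        res = refit_unregularized(S, frozenset(), n)
        np.testing.assert_allclose(
            res.precision.to_numpy(), np.diag(1.0 / np.diag(S)), atol=1e-12
        )

    def test_chain_refit_matches_independent_ipf_run(self):
        # A-B-C chain: r_AC = 0 after refit, and the constrained MLE
        # matches an edge-wise IPF written independently here
        rng = np.random.default_rng(5)
        Ktrue = np.array([[2.0, 0.8, 0.0], [0.8, 2.0, 0.7], [0.0, 0.7, 2.0]])
        X = rng.multivariate_normal(np.zeros(3), np.linalg.inv(Ktrue), 2000)
        S = np.cov(X, rowvar=False)
        edges = {(0, 1), (1, 2)}
        res = refit_unregularized(S, edges, 2000)
        pc = res.partial_correlations.to_numpy()
        assert pc[0, 2] == pytest.approx(0.0, abs=1e-10)

        K = np.diag(1.0 / np.diag(S))  # independent oracle: edge-wise IPF
        for _ in range(500):
            for block in ([0, 1], [1, 2]):
                idx = np.ix_(block, block)
                sigma = np.linalg.inv(K)
                K[idx] += np.linalg.inv(S[idx]) - np.linalg.inv(sigma[idx])
        np.testing.assert_allclose(res.precision.to_numpy(), K, atol=1e-8)

    def test_fitted_covariance_matches_s_on_structure(self):
        rng = np.random.default_rng(6)
        S, n = _sample_cov(rng, p=5)
        edges = {(0, 1), (1, 2), (2, 3), (0, 4), (1, 4)}
        res = refit_unregularized(S, edges, n)
        sigma = np.linalg.inv(res.precision.to_numpy())
        np.testing.assert_allclose(np.diag(sigma), np.diag(S), atol=1e-8)
        for i, j in edges:
            assert sigma[i, j] == pytest.approx(S[i, j], abs=1e-8)
        for i in range(5):
            for j in range(i + 1, 5):
                if (i, j) not in edges:
                    assert res.precision.to_numpy()[i, j] == 0.0


class TestEbic:
    def test_gamma_zero_reduces_to_bic(self):
        rng = np.random.default_rng(7)
        S, n = _sample_cov(rng)
        res = refit_unregularized(S, {(0, 1), (2, 3)}, n)
        assert ebic(res, 0.0) == pytest.approx(
            -2 * res.loglik + 2 * np.log(n)
        )

    def test_empty_graph_ebic_is_minus_two_loglik(self):
        rng = np.random.default_rng(8)
        S, n = _sample_cov(rng)
        res = refit_unregularized(S, frozenset(), n)
        assert ebic(res, 0.5) == pytest.approx(-2 * res.loglik)

    def test_uninformative_edge_strictly_increases_ebic(self):
        # independent variables: any edge buys ~no likelihood, penalty wins
        rng = np.random.default_rng(9)
        S, n = _sample_cov(rng, p=4, n=5000)
        empty = refit_unregularized(S, frozenset(), n)
        one = refit_unregularized(S, {(0, 1)}, n)
        assert one.ebic_value > empty.ebic_value


class TestSelection:
    def test_independent_data_selects_near_empty_graph(self):
        count = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            X = rng.standard_normal((1000, 8))
            model = GaussianGraphicalModel(pd.DataFrame(X)).fit()
            count += len(model.edges) <= 1
        assert count >= 18

    def test_recovers_known_sparse_precision(self):
        f1s = []
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            p = 10
            pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
            chosen = rng.choice(len(pairs), 10, replace=False)
            K = np.eye(p)
            for t in chosen:
                i, j = pairs[t]
                K[i, j] = K[j, i] = 0.3 * rng.choice([-1.0, 1.0])
            K += np.eye(p) * max(0.0, 0.1 - np.linalg.eigvalsh(K).min())
            truth = {pairs[t] for t in chosen}
            X = rng.multivariate_normal(np.zeros(p), np.linalg.inv(K), 2000)
            model = GaussianGraphicalModel(pd.DataFrame(X)).fit()
            tp = len(model.edges & truth)
            fp = len(model.edges - truth)
            fn = len(truth - model.edges)
            f1s.append(2 * tp / (2 * tp + fp + fn) if tp else 0.0)
        assert np.mean(f1s) >= 0.8

    def test_selection_deterministic(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.standard_normal((400, 6)))
        a = GaussianGraphicalModel(X).fit()
        b = GaussianGraphicalModel(X).fit()
        assert a.edges == b.edges
        assert a.ebic_value == b.ebic_value

    def test_selection_invariant_to_column_scaling(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.standard_normal((400, 6)))
        scales = np.array([1.0, 10.0, 0.1, 5.0, 2.0, 100.0])
        a = GaussianGraphicalModel(X).fit()
        b = GaussianGraphicalModel(X * scales).fit()
        assert a.edges == b.edges

    def test_partial_correlation_signs_oppose_precision(self):
        rng = np.random.default_rng(12)
        Ktrue = np.array([[2.0, 0.9, 0.0], [0.9, 2.0, -0.8], [0.0, -0.8, 2.0]])
        X = rng.multivariate_normal(np.zeros(3), np.linalg.inv(Ktrue), 3000)
        S = np.cov(X, rowvar=False)
        res = refit_unregularized(S, {(0, 1), (1, 2)}, 3000)
        K = res.precision.to_numpy()
        r = res.partial_correlations.to_numpy()
        for i, j in res.edges:
            assert np.sign(r[i, j]) == np.sign(-K[i, j])


class TestNetworkStats:
    def test_triangle(self):
        rng = np.random.default_rng(13)
        S, n = _sample_cov(rng, p=3)
        res = refit_unregularized(S, {(0, 1), (1, 2), (0, 2)}, n)
        s = network_stats(res)
        assert s.density == pytest.approx(1.0)
        assert s.transitivity == pytest.approx(1.0)

    def test_path_counted_by_hand(self):
        # path A-B-C: 2 of 3 possible edges, one open triple, no triangles
        rng = np.random.default_rng(14)
        S, n = _sample_cov(rng, p=3)
        res = refit_unregularized(S, {(0, 1), (1, 2)}, n)
        s = network_stats(res)
        assert s.density == pytest.approx(2.0 / 3.0)
        assert s.transitivity == pytest.approx(0.0)

    def test_empty_graph_zero_density(self):
        rng = np.random.default_rng(15)
        S, n = _sample_cov(rng, p=4)
        s = network_stats(refit_unregularized(S, frozenset(), n))
        assert s.density == 0.0

    def test_edge_list_and_summary(self):
        rng = np.random.default_rng(16)
        S, n = _sample_cov(rng, p=4)
        res = refit_unregularized(S, {(0, 1)}, n)
        edges = res.edge_list()
        assert list(edges.columns) == ["node1", "node2", "partial_r", "sign"]
        assert "density" in res.summary()
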