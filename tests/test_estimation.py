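import warnings

import numpy as np
import pytest

import symptomnet as sn
from symptomnet.correlation import pearson_matrix
from symptomnet.estimation import GlassoFit, lambda_max

from _oracles import random_pd_correlation


class TestGraphicalLasso:
    def test_penalty_above_lambda_max_gives_diagonal_precision(self):
        rng = np.random.default_rng(0)
        R = random_pd_correlation(rng, 5)
        fit = sn.graphical_lasso(R, lambda_=lambda_max(R) + 0.01)
        off = fit.precision - np.diag(np.diag(fit.precision))
        assert np.allclose(off, 0.0)
        assert fit.edge_count == 0

    def test_unpenalized_two_variable_partial_equals_r(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        fit = sn.graphical_lasso(R, lambda_=0.0)
        assert fit.partial_corr[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_singular_matrix_at_zero_penalty_fails(self):
        R = np.ones((3, 3))
        with pytest.raises(np.linalg.LinAlgError):
            sn.graphical_lasso(R, lambda_=0.0)

    def test_agrees_with_sklearn_reference(self):
        """Independent solver cross-check: sklearn's graphical lasso on the
        same objective, at its achievable tolerance."""
        from sklearn.covariance import graphical_lasso as sk_glasso
        rng = np.random.default_rng(1)
        for _ in range(5):
            R = random_pd_correlation(rng, 6)
            lam = 0.3 * lambda_max(R)
            fit = sn.graphical_lasso(R, lam, tol=1e-8, max_iter=2000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, prec = sk_glasso(R, alpha=lam, max_iter=2000, tol=1e-9)
            assert np.max(np.abs(fit.precision - prec)) < 5e-3

    def test_unpenalized_partials_match_residual_correlation_oracle(self):
        """Partial correlations from the precision matrix must equal the
        correlations of least-squares residuals after regressing out all
        other variables."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(400, 5))
        X[:, 1] += 0.6 * X[:, 0]
        X[:, 3] += 0.4 * X[:, 2] - 0.3 * X[:, 0]
        R = np.corrcoef(X, rowvar=False)
        fit = sn.graphical_lasso(R, lambda_=0.0)
        Z = (X - X.mean(0)) / X.std(0)
        for i in range(5):
            for j in range(i + 1, 5):
                others = [k for k in range(5) if k not in (i, j)]
                A = Z[:, others]
                ri = Z[:, i] - A @ np.linalg.lstsq(A, Z[:, i], rcond=None)[0]
                rj = Z[:, j] - A @ np.linalg.lstsq(A, Z[:, j], rcond=None)[0]
                expected = np.corrcoef(ri, rj)[0, 1]
                assert fit.partial_corr[i, j] == pytest.approx(expected,
                                                               abs=1e-6)


class TestEBIC:
    def test_gamma_zero_reduces_to_bic(self):
        rng = np.random.default_rng(3)
        R = random_pd_correlation(rng, 4)
        fit = sn.graphical_lasso(R, 0.1)
        n = 200
        bic = -2 * sn.log_likelihood(fit, n) + fit.edge_count * np.log(n)
        assert sn.ebic(fit, n, gamma=0.0) == pytest.approx(bic, abs=1e-10)

    def test_empty_model_arithmetic(self):
        # K = R = I, p = 2, n = 100: l = 50 * (0 - 2), EBIC = 200
        fit = GlassoFit(1.0, np.eye(2), np.eye(2), True, 0)
        assert sn.ebic(fit, 100, gamma=0.5) == pytest.approx(200.0)

    def test_penalty_term_arithmetic(self):
        """For E=5 edges, p=16, n=343, gamma=0.5 the model-complexity part
        is 5 log 343 + 10 log 16, computed independently."""
        K = np.eye(16)
        for a, b in [(0, 1), (2, 3), (4, 5), (6, 7), (8, 9)]:
            K[a, b] = K[b, a] = 0.2
        fit = GlassoFit(0.1, K, np.eye(16), True, 0)
        assert fit.edge_count == 5
        penalty = sn.ebic(fit, 343, 0.5) + 2 * sn.log_likelihood(fit, 343)
        assert penalty == pytest.approx(5 * np.log(343) + 10 * np.log(16))


class TestEbicGlasso:
    def test_identity_input_gives_empty_network(self):
        R = pearson_matrix(np.random.default_rng(5).normal(size=(50, 4)),
                           labels=None)
        R.values[:] = np.eye(4)
        net = sn.ebic_glasso(R, n=50)
        assert net.edge_count == 0

    def test_selected_lambda_is_grid_argmin_of_ebic(self):
        rng = np.random.default_rng(6)
        m = sn.generate_true_network(p=8, density=0.3, seed=rng)
        X = sn.sample_wave(m, 300, "T1", rng)
        R = pearson_matrix(X, labels=None)
        net, fits, scores, grid = sn.ebic_glasso(R, return_path=True)
        recomputed = [sn.ebic(f, R.n, 0.5) for f in fits]
        assert np.allclose(scores, recomputed)
        assert net.lambda_selected == grid[int(np.argmin(scores))]

    def test_edge_count_nonincreasing_in_gamma(self):
        rng = np.random.default_rng(7)
        m = sn.generate_true_network(p=16, density=0.2, seed=rng)
        X = sn.sample_wave(m, 500, "T1", rng)
        R = pearson_matrix(X, labels=None)
        edges = [sn.ebic_glasso(R, gamma=g).edge_count
                 for g in (0.0, 0.25, 0.5, 1.0)]
        assert edges == sorted(edges, reverse=True)

    def test_strength_sums_to_twice_global_strength(self):
        rng = np.random.default_rng(8)
        for s in range(3):
            m = sn.generate_true_network(p=16, density=0.2, seed=rng)
            X = sn.sample_wave(m, 400, "T1", rng)
            net = sn.estimate_network(X)
            total = sn.strength_centrality(net).sum()
            assert total == pytest.approx(2 * sn.global_strength(net),
                                          rel=1e-12, abs=1e-12)


class TestGlobalStrength:
    def test_empty_network_zero(self):
        net = sn.SymptomNetwork(("a", "b", "c"), np.zeros((3, 3)), None,
                                n=10, lambda_selected=0.1)
        assert sn.global_strength(net) == 0.0

    def test_signed_edges_sum_absolutely(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.3
        W[1, 2] = W[2, 1] = -0.2
        net = sn.SymptomNetwork(("a", "b", "c"), W, None, n=10,
                                lambda_selected=0.1)
        assert sn.global_strength(net) == pytest.approx(0.5)


class TestLayout:
    @staticmethod
    def toy(nodes, edges):
        p = len(nodes)
        W = np.zeros((p, p))
        for i, j, w in edges:
            W[i, j] = W[j, i] = w
        return sn.SymptomNetwork(tuple(nodes), W, None, n=10,
                                 lambda_selected=0.1)

    def test_connected_nodes_closer_than_isolated(self):
        net = self.toy(["A", "B", "C"], [(0, 1, 0.9)])
        pos = sn.fr_layout(net, seed=0)
        ab = np.hypot(pos["A"][0] - pos["B"][0], pos["A"][1] - pos["B"][1])
        ac = np.hypot(pos["A"][0] - pos["C"][0], pos["A"][1] - pos["C"][1])
        bc = np.hypot(pos["B"][0] - pos["C"][0], pos["B"][1] - pos["C"][1])
        assert ab < min(ac, bc)

    def test_deterministic_given_seed(self):
        net = self.toy(["A", "B", "C", "D"], [(0, 1, 0.5), (2, 3, 0.4)])
        assert sn.fr_layout(net, seed=3) == sn.fr_layout(net, seed=3)

    def test_permutation_equivariance(self):
        edges = [(0, 1, 0.5), (1, 2, 0.4), (0, 3, 0.2)]
        net = self.toy(["A", "B", "C", "D"], edges)
        perm_edges = [(3, 2, 0.5), (2, 1, 0.4), (3, 0, 0.2)]
        net_perm = self.toy(["D", "C", "B", "A"], perm_edges)
        pos = sn.fr_layout(net, seed=5)
        pos_perm = sn.fr_layout(net_perm, seed=5)
        for lab in "ABCD":
            assert pos[lab] == pytest.approx(pos_perm[lab], abs=1e-9)

    def test_coordinates_in_unit_square(self):
        net = self.toy(["A", "B", "C"], [(0, 1, 0.5), (1, 2, 0.3)])
        pos = sn.fr_layout(net, seed=1)
        xy = np.array(list(pos.values()))
        assert xy.min() >= 0 and xy.max() <= 1
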