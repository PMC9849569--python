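import numpy as np
import pytest

import symptomnet as sn
from symptomnet.correlation import polychoric_pair
from symptomnet.synthetic import sample_latent


class TestPearson:
    def test_duplicated_column_correlates_perfectly(self):
        x = np.array([0, 1, 2, 3, 1.0])
        R = sn.pearson_matrix(np.column_stack([x, x]), labels=("a", "b"))
        assert R.values[0, 1] == pytest.approx(1.0)

    def test_negated_column(self):
        x = np.array([0, 1, 2, 3.0])
        R = sn.pearson_matrix(np.column_stack([x, -x]), labels=("a", "b"))
        assert R.values[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # r = 2 / sqrt(5) = 0.8944 to 4 d.p.
        x = np.array([0, 1, 2, 3.0])
        y = np.array([0, 0, 3, 3.0])
        R = sn.pearson_matrix(np.column_stack([x, y]), labels=("a", "b"))
        assert R.values[0, 1] == pytest.approx(0.8944, abs=5e-5)

    def test_constant_column_error_names_item(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="itemA"):
            sn.pearson_matrix(X, labels=("itemA", "itemB"))


class TestPolychoric:
    @staticmethod
    def ordinal_pair(rho, n, seed, cuts=(-0.5, 0.5, 1.2)):
        rng = np.random.default_rng(seed)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        return (np.digitize(z[:, 0], cuts), np.digitize(z[:, 1], cuts))

    def test_recovers_latent_correlation(self):
        x, y = self.ordinal_pair(0.5, 5000, seed=0)
        rho, clamped = polychoric_pair(x, y)
        assert not clamped
        assert rho == pytest.approx(0.5, abs=0.05)

    def test_independent_items_near_zero(self):
        x, y = self.ordinal_pair(0.0, 5000, seed=1)
        rho, _ = polychoric_pair(x, y)
        assert abs(rho) < 3.0 / np.sqrt(5000) + 0.02

    def test_identical_items_clamped_and_flagged(self):
        x, _ = self.ordinal_pair(0.3, 400, seed=2)
        R = sn.polychoric_matrix(np.column_stack([x, x, 3 - x]),
                                 labels=("a", "b", "c"))
        assert R.values[0, 1] == pytest.approx(0.999)
        assert any(f.startswith("clamped") for f in R.flags)

    def test_sign_agreement_with_pearson_on_latent_gaussian_fixture(self):
        m = sn.generate_true_network(p=4, density=0.5, seed=5)
        X = sn.sample_wave(m, 4000, "T1", seed=6)
        Rp = sn.pearson_matrix(X, labels=None)
        Rc = sn.polychoric_matrix(X, labels=None)
        iu = np.triu_indices(4, 1)
        big = np.abs(Rp.values[iu]) > 0.05
        assert np.all(np.sign(Rp.values[iu][big]) == np.sign(Rc.values[iu][big]))


class TestNearestPSD:
    def test_idempotent_on_psd_input(self):
        R = np.array([[1.0, 0.3], [0.3, 1.0]])
        out = sn.nearest_psd(R, epsilon=1e-8)
        assert np.allclose(out.values, R, atol=1e-12)

    def test_repair_reaches_epsilon_floor(self):
        R = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(R).min() < 0
        out = sn.nearest_psd(R, epsilon=1e-6)
        assert np.linalg.eigvalsh(out.values).min() >= 1e-6 - 1e-12
        assert np.allclose(np.diag(out.values), 1.0)

    def test_close_to_alternating_projection_oracle(self):
        """Clipping + rescaling should land near the Higham alternating
        projection onto {PSD} intersect {unit diagonal} on a 4x4 case."""
        R = np.array([
            [1.0, 0.95, -0.4, 0.2],
            [0.95, 1.0, 0.9, -0.3],
            [-0.4, 0.9, 1.0, 0.6],
            [0.2, -0.3, 0.6, 1.0],
        ])

        def higham(A, iters=500):
            Y, dS = A.copy(), np.zeros_like(A)
            for _ in range(iters):
                Rk = Y - dS
                w, V = np.linalg.eigh(Rk)
                X = (V * np.clip(w, 0, None)) @ V.T
                dS = X - Rk
                Y = X.copy()
                np.fill_diagonal(Y, 1.0)
            return Y

        oracle = higham(R)
        ours = sn.nearest_psd(R, epsilon=1e-10).values
        d_ours = np.linalg.norm(ours - R)
        d_oracle = np.linalg.norm(oracle - R)
        assert d_ours <= 1.5 * d_oracle
        assert np.max(np.abs(ours - oracle)) < 0.1

    def test_invariants_on_random_indefinite_matrices(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.integers(3, 8)
            A = rng.uniform(-1, 1, (p, p))
            A = 0.5 * (A + A.T)
            np.fill_diagonal(A, 1.0)
            out = sn.nearest_psd(A, epsilon=1e-8)
            assert np.allclose(out.values, out.values.T)
            assert np.allclose(np.diag(out.values), 1.0)
            assert np.all(np.abs(out.values) <= 1.0 + 1e-9)
            assert np.linalg.eigvalsh(out.values).min() >= 1e-8 - 1e-12
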