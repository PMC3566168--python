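"""Gaussian RBF network: kernel, training, prediction, persistence."""

import math

import numpy as np
import pytest

from metalsite import rbfn


class TestKernel:
    def test_zero_distance(self):
        assert rbfn.kernel([1.0, 2.0], [1.0, 2.0], 5.0) == 1.0

    def test_distance_sigma_sqrt2(self):
        # ||x - mu|| = sigma * sqrt(2)  =>  exp(-1)
        sigma = 5.0
        x = np.zeros(4)
        mu = np.full(4, sigma * math.sqrt(2) / 2.0)
        assert rbfn.kernel(x, mu, sigma) == pytest.approx(math.exp(-1), abs=1e-12)

    def test_flat_limit(self):
        assert rbfn.kernel([0.0], [3.0], 1e6) == pytest.approx(1.0, abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            rbfn.kernel([0.0, 1.0], [0.0], 5.0)

    def test_nonpositive_bandwidth(self):
        with pytest.raises(ValueError):
            rbfn.kernel([0.0], [1.0], 0.0)


class TestTrain:
    def test_two_point_interpolation(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([1, 0])
        model = rbfn.train(X, y, sigma=5.0, ridge=0.0)
        G = rbfn.decision_values(model, X)
        np.testing.assert_allclose(G, [[1.0, 0.0], [0.0, 1.0]], atol=1e-10)

    def test_hand_solved_two_point_system(self):
        # 1-D points {0, 10}, sigma=5: Phi = [[1, e^-2], [e^-2, 1]].
        # Solving Phi W = T column-wise gives W[:,0] = (1, -e^-2)/(1 - e^-4).
        X = np.array([[0.0], [10.0]])
        model = rbfn.train(X, np.array([1, 0]), sigma=5.0, ridge=0.0)
        e2 = math.exp(-2.0)
        d = 1.0 - e2**2
        np.testing.assert_allclose(
            model.weights,
            [[1.0 / d, -e2 / d], [-e2 / d, 1.0 / d]],
            atol=1e-10,
        )
        assert rbfn.predict(model, np.array([0.0])) == 1
        assert rbfn.predict(model, np.array([10.0])) == 0

    def test_duplicate_conflicting_points_with_ridge(self):
        X = np.array([[0.0], [0.0]])
        y = np.array([1, 0])
        model = rbfn.train(X, y, sigma=5.0, ridge=1e-6)
        # tied outputs at the duplicated point resolve to non-binding
        g = rbfn.decision_values(model, np.array([0.0]))
        assert g[0] == pytest.approx(g[1], abs=1e-6)
        assert rbfn.predict(model, np.array([0.0])) == 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            rbfn.train(np.array([[0.0], [1.0]]), np.array([1, 1]))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            rbfn.train(np.array([[np.nan], [1.0]]), np.array([1, 0]))

    def test_training_is_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 4))
        y = (rng.random(15) < 0.5).astype(int)
        y[:2] = [0, 1]
        a = rbfn.train(X, y)
        b = rbfn.train(X, y)
        np.testing.assert_array_equal(a.weights, b.weights)


class TestDecisionValues:
    def test_zero_weights_give_zero(self):
        model = rbfn.RbfnModel(
            centers=np.zeros((3, 2)), weights=np.zeros((3, 2)), sigma=5.0
        )
        np.testing.assert_array_equal(
            rbfn.decision_values(model, np.ones(2)), [0.0, 0.0]
        )

    def test_interpolation_corollary(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 3))
        y = np.array([1, 0, 1, 0, 1, 0, 1, 0])
        model = rbfn.train(X, y, sigma=2.0, ridge=0.0)
        G = rbfn.decision_values(model, X)
        np.testing.assert_allclose(G, rbfn.one_hot_targets(y), atol=1e-8)

    def test_naive_double_loop_oracle(self):
        """Matrix evaluation equals the definition g_j(x) = sum_i w_ij phi_i(x)."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            n, d, m = rng.integers(2, 9), rng.integers(1, 6), rng.integers(1, 5)
            centers = rng.normal(size=(n, d))
            weights = rng.normal(size=(n, 2))
            sigma = float(rng.uniform(0.5, 6.0))
            model = rbfn.RbfnModel(centers=centers, weights=weights, sigma=sigma)
            Xq = rng.normal(size=(m, d))
            G = rbfn.decision_values(model, Xq)
            for a in range(m):
                for j in range(2):
                    ref = sum(
                        weights[i, j] * rbfn.kernel(Xq[a], centers[i], sigma)
                        for i in range(n)
                    )
                    assert abs(G[a, j] - ref) < 1e-10

    def test_lipschitz_continuity(self):
        """Perturbing x by delta moves each output by at most L * delta with
        L = sum_i |w_ij| / (sigma * sqrt(e)), the Gaussian kernel's gradient bound."""
        rng = np.random.default_rng(7)
        centers = rng.normal(size=(6, 3))
        weights = rng.normal(size=(6, 2))
        sigma = 2.0
        model = rbfn.RbfnModel(centers=centers, weights=weights, sigma=sigma)
        L = np.abs(weights).sum(axis=0) / (sigma * math.sqrt(math.e))
        x = rng.normal(size=3)
        for _ in range(20):
            delta = rng.normal(size=3) * 0.05
            diff = np.abs(
                rbfn.decision_values(model, x + delta)
                - rbfn.decision_values(model, x)
            )
            assert np.all(diff <= L * np.linalg.norm(delta) + 1e-12)

    def test_length_mismatch(self):
        model = rbfn.RbfnModel(centers=np.zeros((2, 3)), weights=np.zeros((2, 2)))
        with pytest.raises(ValueError, match="length"):
            rbfn.decision_values(model, np.zeros(4))


class TestPredict:
    def test_argmax_and_tie_rule(self):
        model = rbfn.RbfnModel(
            centers=np.array([[0.0]]), weights=np.array([[0.9, 0.1]]), sigma=5.0
        )
        assert rbfn.predict(model, np.array([0.0])) == 1
        tied = rbfn.RbfnModel(
            centers=np.array([[0.0]]), weights=np.array([[0.5, 0.5]]), sigma=5.0
        )
        assert rbfn.predict(tied, np.array([0.0])) == 0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(12, 3))
        y = (np.arange(12) % 2).astype(int)
        perm = rng.permutation(12)
        a = rbfn.train(X, y, sigma=3.0)
        b = rbfn.train(X[perm], y[perm], sigma=3.0)
        Xq = rng.normal(size=(20, 3))
        np.testing.assert_allclose(
            rbfn.decision_values(a, Xq), rbfn.decision_values(b, Xq), atol=1e-5
        )
        np.testing.assert_array_equal(rbfn.predict(a, Xq), rbfn.predict(b, Xq))


class TestPersistence:
    def test_bit_exact_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 4))
        y = (np.arange(10) % 2).astype(int)
        model = rbfn.train(
            X, y, sigma=5.0, feature_spec={"encoding": "AA", "w": 6}
        )
        path = tmp_path / "model.json"
        rbfn.save_model(model, path)
        back = rbfn.load_model(path)
        np.testing.assert_array_equal(back.centers, model.centers)
        np.testing.assert_array_equal(back.weights, model.weights)
        assert back.sigma == model.sigma and back.ridge == model.ridge
        assert back.feature_spec == model.feature_spec

    def test_version_check(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text('{"format_version": 99}')
        with pytest.raises(ValueError, match="version"):
            rbfn.load_model(path)
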