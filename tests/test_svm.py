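import numpy as np
import pytest
from hypothesis import given, strategies as st

import blockdecode as bd
from blockdecode.svm import primal_objective, reference_dual_solve


def random_instance(rng):
    n = int(rng.integers(2, 7))
    d = int(rng.integers(1, 4))
    X = rng.normal(0, 2, (n, d))
    y = np.ones(n)
    y[: n // 2] = -1
    rng.shuffle(y)
    if len(np.unique(y)) < 2:
        y[0], y[-1] = 1, -1
    return X, y


class TestTrainSVM:
    def test_symmetric_two_point_problem(self):
        m = bd.train_svm(np.array([[1.0], [-1.0]]), np.array([1, -1]), C=1.0)
        assert abs(m.w[0] - 1.0) < 1e-8
        assert abs(m.b) < 1e-8
        np.testing.assert_allclose(m.slacks, 0.0, atol=1e-8)
        np.testing.assert_array_equal(m.support_indices, [0, 1])

    def test_two_dimensional_hard_margin(self):
        X = np.array([[2, 0], [3, 1], [-2, 0], [-3, -1]], float)
        y = np.array([1, 1, -1, -1])
        m = bd.train_svm(X, y, C=1.0)
        wr, br, _ = reference_dual_solve(X, y, C=1.0)
        assert (
            abs(primal_objective(X, y, m.w, m.b, 1.0) - primal_objective(X, y, wr, br, 1.0))
            < 1e-6
        )
        np.testing.assert_allclose(m.w, [0.5, 0.0], atol=1e-6)
        assert abs(m.b) < 1e-6

    def test_separated_clusters_perfect_training_accuracy(self, rng):
        X = np.vstack(
            [rng.normal(5, 0.2, (20, 3)), rng.normal(-5, 0.2, (20, 3))]
        )
        y = np.repeat([1, -1], 20)
        m = bd.train_svm(X, y)
        assert bd.accuracy(m, X, y) == 1.0
        np.testing.assert_allclose(m.slacks, 0.0, atol=1e-6)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            bd.train_svm(np.ones((3, 2)), np.ones(3))

    def test_nonpositive_c_raises(self):
        with pytest.raises(ValueError):
            bd.train_svm(np.array([[1.0], [-1.0]]), np.array([1, -1]), C=0)

    def test_slack_postcondition(self, rng):
        X, y = rng.standard_normal((10, 3)), np.repeat([1, -1], 5)
        m = bd.train_svm(X, y)
        np.testing.assert_allclose(
            m.slacks, np.maximum(0, 1 - y * (X @ m.w + m.b)), atol=1e-12
        )

    def test_example_order_invariance(self, rng):
        X, y = rng.standard_normal((12, 4)), np.repeat([1, -1], 6)
        m1 = bd.train_svm(X, y)
        perm = rng.permutation(12)
        m2 = bd.train_svm(X[perm], y[perm])
        np.testing.assert_allclose(m1.w, m2.w, atol=1e-7)
        assert abs(m1.b - m2.b) < 1e-7

    def test_scale_covariance_hard_margin(self, rng):
        """Scaling separable features by c scales w by 1/c."""
        X = np.vstack([rng.normal(4, 0.3, (10, 2)), rng.normal(-4, 0.3, (10, 2))])
        y = np.repeat([1, -1], 10)
        w1 = bd.train_svm(X, y).w
        w3 = bd.train_svm(3 * X, y).w
        np.testing.assert_allclose(w3, w1 / 3, atol=1e-6)

    def test_no_bias_mode(self):
        X = np.array([[2.0], [0.5], [-2.0], [-0.5]])
        y = np.array([1, 1, -1, -1])
        m = bd.train_svm(X, y, fit_bias=False)
        assert m.b == 0.0
        wr, _, _ = reference_dual_solve(X, y, fit_bias=False)
        assert (
            abs(primal_objective(X, y, m.w, 0, 1.0) - primal_objective(X, y, wr, 0, 1.0))
            < 1e-6
        )


class TestOracleEquivalence:
    @pytest.mark.parametrize("fit_bias", [True, False])
    def test_objective_matches_brute_force_dual(self, fit_bias):
        """On ~40 random small instances the trained objective agrees with
        the brute-force QP reference to 1e-6 and KKT conditions hold."""
        rng = np.random.default_rng(202)
        for _ in range(40):
            X, y = random_instance(rng)
            C = float(rng.choice([0.5, 1.0, 2.0]))
            m = bd.train_svm(X, y, C=C, fit_bias=fit_bias)
            wr, br, _ = reference_dual_solve(X, y, C=C, fit_bias=fit_bias)
            obj_m = primal_objective(X, y, m.w, m.b, C)
            obj_r = primal_objective(X, y, wr, br, C)
            assert abs(obj_m - obj_r) < 1e-6
            # complementary slackness: strictly positive slack only on
            # margin-violating examples (decision inside the margin)
            margins = y * (X @ m.w + m.b)
            assert np.all(margins[m.slacks > 1e-6] < 1 + 1e-6)

    def test_support_vectors_at_margin(self, rng):
        X = np.vstack([rng.normal(3, 0.5, (8, 2)), rng.normal(-3, 0.5, (8, 2))])
        y = np.repeat([1, -1], 8)
        m = bd.train_svm(X, y)
        sv_zero_slack = [
            i for i in m.support_indices if m.slacks[i] < 1e-8
        ]
        dec = bd.decision_values(m, X[sv_zero_slack])
        np.testing.assert_allclose(np.abs(dec), 1.0, atol=1e-5)


class TestDecisionAndPredict:
    def test_zero_vector_zero_bias(self):
        m = bd.SVMModel(
            w=np.zeros(3), b=0.0, C=1.0, support_indices=np.array([]), slacks=np.array([])
        )
        assert bd.decision_values(m, np.zeros((1, 3)))[0] == 0.0
        assert bd.predict(m, np.zeros((1, 3)))[0] == 1  # tie-break to +1

    def test_unit_model(self):
        m = bd.SVMModel(
            w=np.array([1.0]), b=0.0, C=1.0, support_indices=np.array([]), slacks=np.array([])
        )
        assert bd.decision_values(m, np.array([[2.0]]))[0] == 2.0
        np.testing.assert_array_equal(
            bd.predict(m, np.array([[-0.5], [0.2]])), [-1, 1]
        )

    def test_dimension_mismatch_raises(self):
        m = bd.SVMModel(
            w=np.ones(2), b=0.0, C=1.0, support_indices=np.array([]), slacks=np.array([])
        )
        with pytest.raises(ValueError):
            bd.decision_values(m, np.ones((1, 3)))


class TestCrossRunAccuracy:
    def _example_set(self, X, y):
        return bd.ExampleSet(
            features=X,
            labels=y,
            frame_times=np.arange(len(y), dtype=float),
            voxel_index=np.stack([np.arange(X.shape[1])] * 3, axis=1),
        )

    def test_train_equals_test_separable(self, rng):
        X = np.vstack([rng.normal(4, 0.3, (10, 2)), rng.normal(-4, 0.3, (10, 2))])
        y = np.repeat([1, -1], 10)
        es = self._example_set(X, y)
        assert bd.cross_run_accuracy(es, es) == 1.0

    def test_pure_noise_accuracy_near_chance(self):
        """Random labels on noise features: mean accuracy ~ 0.5 over seeds."""
        accs = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            X1, X2 = rng.standard_normal((2, 40, 10))
            y1 = np.repeat([1, -1], 20)
            y2 = y1.copy()
            rng.shuffle(y1)
            rng.shuffle(y2)
            accs.append(
                bd.cross_run_accuracy(self._example_set(X1, y1), self._example_set(X2, y2))
            )
        accs = np.array(accs)
        se = accs.std(ddof=1) / np.sqrt(len(accs))
        assert abs(accs.mean() - 0.5) < 3 * se

    def test_feature_space_mismatch_raises(self, rng):
        a = self._example_set(rng.standard_normal((4, 3)), np.array([1, 1, -1, -1]))
        b = self._example_set(rng.standard_normal((4, 2)), np.array([1, 1, -1, -1]))
        with pytest.raises(ValueError):
            bd.cross_run_accuracy(a, b)

    def test_paired_direction_mean(self, rng):
        X1 = np.vstack([rng.normal(2, 1, (10, 2)), rng.normal(-2, 1, (10, 2))])
        X2 = np.vstack([rng.normal(2, 1, (10, 2)), rng.normal(-2, 1, (10, 2))])
        y = np.repeat([1, -1], 10)
        s1, s2 = self._example_set(X1, y), self._example_set(X2, y)
        paired = bd.paired_cross_run_accuracy(s1, s2)
        assert paired == 0.5 * (
            bd.cross_run_accuracy(s1, s2) + bd.cross_run_accuracy(s2, s1)
        )

    def test_degenerate_all_positive_model_on_balanced_set(self):
        m = bd.SVMModel(
            w=np.zeros(2), b=5.0, C=1.0, support_indices=np.array([]), slacks=np.array([])
        )
        X = np.zeros((10, 2))
        y = np.repeat([1, -1], 5)
        assert bd.accuracy(m, X, y) == 0.5
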