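"""PLS-DA fitting, prediction, cross-validation and permutation test."""

import numpy as np
import pytest
from scipy import stats

from uromet.plsda import (
    fit_plsda,
    loo_cv,
    permutation_test,
    predict,
    separation_distance,
)


def separated_clusters(n_per=20, p=5, delta=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.standard_normal((n_per, p)) + delta, rng.standard_normal((n_per, p))]
    )
    y = np.array([1] * n_per + [0] * n_per)
    return X, y


class TestFit:
    def test_rank_one_data_recovers_direction(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 10)
        u = (y - y.mean()) + 0.01 * rng.standard_normal(20)
        u -= u.mean()
        v = rng.standard_normal(6)
        X = np.outer(u, v)
        model = fit_plsda(X, y, n_components=1, scale=False)
        cos = abs(u @ model.x_scores[:, 0]) / (
            np.linalg.norm(u) * np.linalg.norm(model.x_scores[:, 0])
        )
        assert cos > 0.999

    @pytest.mark.parametrize("seed", range(5))
    def test_first_weights_match_cross_covariance_singular_vector(self, seed):
        # for a single response the dominant left singular vector of
        # X_c^T y_c is X_c^T y_c normalized; sign-fix both before comparing
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((20, 10))
        y = np.array([0, 1] * 10)
        model = fit_plsda(X, y, n_components=2, scale=False)
        Xc = X - X.mean(0)
        yc = y - y.mean()
        u, *_ = np.linalg.svd((Xc.T @ yc).reshape(-1, 1), full_matrices=False)
        w_svd = u[:, 0] * np.sign(u[0, 0])
        w = model.x_weights[:, 0] * np.sign(model.x_weights[0, 0])
        assert np.allclose(w, w_svd, atol=1e-10)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(3)
        model = fit_plsda(rng.standard_normal((30, 8)), np.array([0, 1] * 15), 3)
        G = model.x_scores.T @ model.x_scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() / np.abs(np.diag(G)).max() < 1e-8

    def test_matches_reference_nipals_implementation(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(4)
        X = rng.standard_normal((25, 7))
        y = np.array([0, 1, 1, 0, 1] * 5)
        model = fit_plsda(X, y, n_components=3, scale=True)
        ref = PLSRegression(n_components=3, scale=True).fit(X, y.astype(float))
        for a in range(3):
            cos = abs(model.x_scores[:, a] @ ref.x_scores_[:, a]) / (
                np.linalg.norm(model.x_scores[:, a])
                * np.linalg.norm(ref.x_scores_[:, a])
            )
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((16, 6))
        y = np.array([0, 1] * 8)
        perm = rng.permutation(16)
        m1 = fit_plsda(X, y, 2)
        m2 = fit_plsda(X[perm], y[perm], 2)
        assert np.allclose(m1.x_scores[perm], m2.x_scores, atol=1e-10)

    def test_constant_feature_shift_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((20, 5))
        y = np.array([0, 1] * 10)
        m1 = fit_plsda(X, y, 2)
        m2 = fit_plsda(X + np.array([5, -3, 0, 1, 2]), y, 2)
        assert np.allclose(m1.x_scores, m2.x_scores, atol=1e-10)

    def test_bad_inputs(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((10, 4))
        with pytest.raises(ValueError, match="both classes"):
            fit_plsda(X, np.zeros(10, dtype=int), 2)
        with pytest.raises(ValueError, match="n_components"):
            fit_plsda(X, np.array([0, 1] * 5), 5)


class TestPredict:
    def test_separated_clusters_training_accuracy(self):
        X, y = separated_clusters()
        model = fit_plsda(X, y, 2)
        assert (predict(model, X) == y).all()

    def test_training_sample_reproduces_fitted_label(self):
        X, y = separated_clusters(seed=2)
        model = fit_plsda(X, y, 2)
        assert predict(model, X[:1])[0] == predict(model, X)[0]

    def test_degenerate_input_at_centered_midpoint(self):
        # all-zero scaled features give a centered-label prediction of
        # exactly 0, which is not > 0: label 0 regardless of imbalance
        X, y = separated_clusters(seed=3)
        model = fit_plsda(X, y, 2)
        assert predict(model, model.x_mean.reshape(1, -1))[0] == 0

    def test_feature_mismatch_rejected(self):
        X, y = separated_clusters(seed=4)
        model = fit_plsda(X, y, 2)
        with pytest.raises(ValueError, match="feature mismatch"):
            predict(model, X[:, :3])


class TestLooCv:
    def test_separated_clusters_perfect(self):
        X, y = separated_clusters()
        _, acc = loo_cv(X, y, 2)
        assert acc == 1.0

    def test_null_accuracy_near_chance(self):
        # pure noise, balanced labels: mean LOO accuracy within binomial
        # bounds of the 0.5 majority rate, pooled over 20 seeds
        total = hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((40, 5))
            y = np.array([0, 1] * 20)
            preds, _ = loo_cv(X, y, 2)
            hits += int((preds == y).sum())
            total += 40
        lo, hi = stats.binom.ppf([0.025, 0.975], total, 0.5)
        assert lo <= hits <= hi

    def test_minimal_legal_input(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((4, 3))
        y = np.array([0, 0, 1, 1])
        preds, acc = loo_cv(X, y, 1)
        assert len(preds) == 4

    def test_singleton_class_rejected(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError, match="class empty"):
            loo_cv(rng.standard_normal((5, 3)), np.array([0, 0, 0, 0, 1]), 1)


class TestSeparationDistance:
    def test_identical_class_means_zero(self):
        T = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        assert separation_distance(T, np.array([0, 0, 1, 1])) == 0.0

    def test_zero_within_scatter_is_infinite(self):
        T = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        assert separation_distance(T, np.array([1, 1, 0, 0])) == np.inf

    def test_hand_computed_configuration(self):
        # class 0 scores {-2, 0}, class 1 {1, 3}: B = 9, W = 4
        T = np.array([[-2.0], [0.0], [1.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        assert separation_distance(T, y) == pytest.approx(9.0 / 4.0)


class TestPermutationTest:
    def test_constant_statistic_gives_p_one(self):
        res = permutation_test(
            np.zeros((12, 4)), np.array([0, 1] * 6), 2, B=99, seed=0
        )
        assert res.p_value == 1.0

    def test_separated_clusters_minimum_p(self):
        X, y = separated_clusters()
        res = permutation_test(X, y, 2, B=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.observed_stat > res.permuted_stats.max()

    def test_seed_reproducibility(self):
        X, y = separated_clusters(seed=5, delta=1.0)
        r1 = permutation_test(X, y, 2, B=50, seed=42)
        r2 = permutation_test(X, y, 2, B=50, seed=42)
        assert np.array_equal(r1.permuted_stats, r2.permuted_stats)

    def test_p_value_definition(self):
        X, y = separated_clusters(seed=6, delta=0.5)
        res = permutation_test(X, y, 2, B=199, seed=7)
        n_ge = int((res.permuted_stats >= res.observed_stat).sum())
        assert res.p_value == (1 + n_ge) / 200
        assert 0 < res.p_value <= 1
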