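"""GMM family, DFA, naive Bayes, SVM-RBF and the class-target contract."""

import math

import numpy as np
import pytest

from swarmexpr.core_data import CANCER, NORMAL, SyntheticSpec, ValidationError, generate_synthetic_dataset
from swarmexpr.feature_extraction import FeatureMatrix
from swarmexpr.metaheuristics import FireflyParams, FPOParams, PSOParams
from swarmexpr.classifiers import (
    ConfigurationError,
    DFAConfig,
    GMMClassModel,
    NumericalError,
    TargetScheme,
    check_targets,
    dfa_classify,
    dfa_exponent,
    gmm_fit,
    gmm_predict,
    hybrid_gmm_fit,
    mse,
    nbc_fit_predict,
    svm_fit_predict,
    svm_rbf_kernel,
)


def make_features(X, labels):
    return FeatureMatrix(
        values=np.asarray(X, dtype=float),
        feature_names=[f"f{i}" for i in range(np.asarray(X).shape[1])],
        method="test", params={}, labels=list(labels),
    )


def two_blob_features(n_per_class=100, delta=10.0, d=1, seed=4):
    rng = np.random.default_rng(seed)
    Xc = rng.standard_normal((n_per_class, d))
    Xn = rng.standard_normal((n_per_class, d)) + delta
    X = np.vstack([Xc, Xn])
    labels = [CANCER] * n_per_class + [NORMAL] * n_per_class
    return make_features(X, labels)


class TestTargetsAndMSE:
    def test_study_targets_are_valid(self):
        scheme = check_targets(TargetScheme(0.85, 0.1))
        assert abs(scheme.t_normal - scheme.t_cancer) == pytest.approx(0.75)

    def test_insufficient_separation_rejected(self):
        with pytest.raises(ConfigurationError, match="separation"):
            check_targets(TargetScheme(0.6, 0.4))

    def test_out_of_range_target_rejected(self):
        with pytest.raises(ConfigurationError):
            check_targets(TargetScheme(1.2, 0.1))

    def test_mse_values(self):
        assert mse([1, 2, 3], [1, 2, 3]) == 0.0
        assert mse([1, 0], [0, 1]) == 1.0
        assert mse([0.85], [0.95]) == pytest.approx(0.01)
        with pytest.raises(ValidationError):
            mse([1, 2], [1])


class TestGMM:
    def test_priors_equal_class_frequencies(self):
        rng = np.random.default_rng(0)
        feats = make_features(
            rng.standard_normal((62, 3)), [CANCER] * 40 + [NORMAL] * 22
        )
        model = gmm_fit(feats, n_components=1)
        assert model.priors[CANCER] == pytest.approx(40 / 62)
        assert model.priors[NORMAL] == pytest.approx(22 / 62)

    def test_single_component_recovers_separated_means(self):
        feats = two_blob_features(n_per_class=100, delta=10.0, seed=4)
        model = gmm_fit(feats, n_components=1, seed=4)
        assert abs(model.means[CANCER][0, 0] - 0.0) < 0.5
        assert abs(model.means[NORMAL][0, 0] - 10.0) < 0.5

    def test_em_loglik_nondecreasing(self):
        rng = np.random.default_rng(6)
        X = np.vstack(
            [rng.standard_normal((30, 2)), rng.standard_normal((30, 2)) + 3]
        )
        feats = make_features(
            np.vstack([X, X + 0.5]), [CANCER] * 60 + [NORMAL] * 60
        )
        model = gmm_fit(feats, n_components=2, seed=1)
        for trace in model.loglik_trace.values():
            assert np.all(np.diff(trace) >= -1e-8)

    def test_posteriors_normalize(self):
        feats = two_blob_features()
        model = gmm_fit(feats, n_components=1)
        _, post, _ = gmm_predict(model, feats.values)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((post >= 0) & (post <= 1))

    def test_symmetric_model_boundary_is_perpendicular_bisector(self):
        mu_c, mu_n = np.array([0.0, 0.0]), np.array([4.0, 0.0])
        model = GMMClassModel(
            classes=(CANCER, NORMAL),
            weights={CANCER: np.ones(1), NORMAL: np.ones(1)},
            means={CANCER: mu_c[None, :], NORMAL: mu_n[None, :]},
            covariances={CANCER: np.eye(2)[None], NORMAL: np.eye(2)[None]},
            priors={CANCER: 0.5, NORMAL: 0.5},
            n_components=1, n_features=2,
        )
        labels, _, _ = gmm_predict(
            model, np.array([[1.9, 3.0], [2.1, -3.0], [2.0, 0.0]])
        )
        assert list(labels) == [CANCER, NORMAL, CANCER]  # midpoint → cancer

    def test_sample_at_mean_of_well_separated_class(self):
        feats = two_blob_features(delta=10.0)
        model = gmm_fit(feats, n_components=1)
        _, post, _ = gmm_predict(model, np.array([[0.0]]))
        # closed-form check: posterior ratio at the cancer mean is
        # exp(−0) / exp(−(10²)/2) — overwhelmingly cancer
        assert post[0, 0] > 0.999

    def test_dimension_mismatch_rejected(self):
        feats = two_blob_features(d=2)
        model = gmm_fit(feats, n_components=1)
        with pytest.raises(ValidationError):
            gmm_predict(model, np.ones((1, 3)))

    def test_too_few_samples_for_components(self):
        feats = make_features(np.ones((3, 1)), [CANCER, CANCER, NORMAL])
        with pytest.raises(ValidationError):
            gmm_fit(feats, n_components=2)

    def test_continuous_score_lives_on_target_axis(self):
        feats = two_blob_features(delta=8.0)
        model = gmm_fit(feats, n_components=1)
        _, _, scores = gmm_predict(model, feats.values)
        assert np.all(scores >= 0.1 - 1e-9) and np.all(scores <= 0.85 + 1e-9)


def overlap_features(seed, effect=0.7):
    ds = generate_synthetic_dataset(
        SyntheticSpec(
            n_genes=60, n_informative=10, effect_size=effect, seed=seed
        )
    )
    X = ds.values[:10].T
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    return make_features(X, ds.labels)


class TestHybridGMM:
    @pytest.mark.parametrize("optimizer,params", [
        ("pso", PSOParams(population=15, max_iter=15)),
        ("firefly", FireflyParams(population=10, max_iter=8)),
        ("fpo", FPOParams(population=15, max_iter=15)),
    ])
    def test_never_worse_than_em_and_trace_monotone(self, optimizer, params):
        feats = overlap_features(seed=21)
        h = hybrid_gmm_fit(feats, optimizer, params, seed=3)
        assert h.train_mse <= h.em_mse + 1e-15
        assert np.all(np.diff(h.trace) <= 0)

    def test_zero_iteration_budget_returns_em_model(self):
        feats = overlap_features(seed=22)
        h = hybrid_gmm_fit(
            feats, "fpo", FPOParams(population=10, max_iter=0), seed=0
        )
        for label in (CANCER, NORMAL):
            np.testing.assert_array_equal(
                h.model.means[label], h.base.means[label]
            )
            np.testing.assert_array_equal(
                h.model.weights[label], h.base.weights[label]
            )

    def test_optimizer_improves_on_overlapping_classes(self):
        """Where EM leaves a nonzero class-target MSE, the swarm search
        strictly improves it in at least 8 of 10 seeds."""
        wins = 0
        for s in range(10):
            feats = overlap_features(seed=100 + s)
            h = hybrid_gmm_fit(
                feats, "fpo", FPOParams(population=20, max_iter=40), seed=s
            )
            wins += (h.em_mse > 0) and (h.train_mse < h.em_mse)
        assert wins >= 8

    def test_unknown_optimizer_rejected(self):
        with pytest.raises(ConfigurationError):
            hybrid_gmm_fit(overlap_features(seed=23), "annealing")


class TestDFA:
    def test_constant_series_is_degenerate(self):
        res = dfa_exponent(np.full(256, 3.14))
        assert res.degenerate and res.exponent == 0.0

    def test_white_noise_exponent_near_half(self):
        rng = np.random.default_rng(9)
        res = dfa_exponent(rng.standard_normal(4096))
        assert abs(res.exponent - 0.5) <= 0.1

    def test_random_walk_exponent_near_three_halves(self):
        rng = np.random.default_rng(9)
        res = dfa_exponent(np.cumsum(rng.standard_normal(4096)))
        assert abs(res.exponent - 1.5) <= 0.1

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError):
            dfa_exponent(np.arange(10))

    def test_classify_separates_noise_from_walks(self):
        """Cancer rows built as integrated noise (exponent ≈ 1.5), normal
        rows as plain noise (≈ 0.5): held-out accuracy ≥ 0.9."""
        rng = np.random.default_rng(12)
        n_len = 512
        walks = [np.cumsum(rng.standard_normal(n_len)) for _ in range(25)]
        noise = [rng.standard_normal(n_len) for _ in range(25)]
        train_X = np.vstack(walks[:20] + noise[:20])
        train_y = np.array([CANCER] * 20 + [NORMAL] * 20, dtype=object)
        test_X = np.vstack(walks[20:] + noise[20:])
        test_y = np.array([CANCER] * 5 + [NORMAL] * 5, dtype=object)
        pred = dfa_classify(train_X, train_y, test_X)
        assert np.mean(pred == test_y) >= 0.9

    def test_equal_class_means_tie_toward_cancer(self):
        X = np.tile(np.sin(np.arange(64)), (4, 1))
        y = np.array([CANCER, CANCER, NORMAL, NORMAL], dtype=object)
        with pytest.warns(UserWarning):
            pred = dfa_classify(X, y, X[:2])
        assert np.all(pred == CANCER)


class TestNBC:
    def test_midpoint_boundary_one_feature(self):
        # equal priors, exactly equal variances, class means 0 and 2:
        # the decision boundary is the midpoint 1.0
        train = np.array([-1.0, 0.0, 1.0, 1.0, 2.0, 3.0])[:, None]
        y = np.array([CANCER] * 3 + [NORMAL] * 3, dtype=object)
        pred, _ = nbc_fit_predict(train, y, np.array([[0.99], [1.01]]), alpha=0.0)
        assert list(pred) == [CANCER, NORMAL]

    def test_posteriors_sum_to_one(self):
        feats = two_blob_features(d=3)
        _, post = nbc_fit_predict(feats.values, feats.label_array(), feats.values)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_brute_force_bayes_oracle(self):
        train = np.array(
            [[0.0, 1.0], [0.2, 0.8], [-0.2, 1.2], [3.0, -1.0], [2.8, -0.8],
             [3.2, -1.2]]
        )
        y = np.array([CANCER] * 3 + [NORMAL] * 3, dtype=object)
        test = np.array([[1.5, 0.0], [0.1, 0.9]])
        _, post = nbc_fit_predict(train, y, test, alpha=0.0)

        # independent dense Bayes computation on the same numbers
        def gauss(v, mu, var):
            return np.exp(-((v - mu) ** 2) / (2 * var)) / math.sqrt(
                2 * math.pi * var
            )

        oracle = np.zeros((2, 2))
        for c, cls in enumerate((CANCER, NORMAL)):
            Xc = train[y == cls]
            mu, var = Xc.mean(axis=0), Xc.var(axis=0)
            for t in range(2):
                lik = np.prod([gauss(test[t, j], mu[j], var[j]) for j in range(2)])
                oracle[t, c] = 0.5 * lik
        oracle /= oracle.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(post, oracle, atol=1e-12)

    def test_zero_variance_with_zero_alpha_errors(self):
        train = np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0], [1.0, 5.0]])
        y = np.array([CANCER, CANCER, NORMAL, NORMAL], dtype=object)
        with pytest.raises(NumericalError, match="alpha"):
            nbc_fit_predict(train, y, train, alpha=0.0)


class TestSVM:
    def test_kernel_identity_and_known_value(self):
        x = np.array([1.3, -2.0, 0.5])
        assert svm_rbf_kernel(x, x, sigma=0.1) == 1.0
        val = svm_rbf_kernel(np.array([0.0, 0.0]), np.array([1.0, 0.0]), 0.1)
        assert val == pytest.approx(math.exp(-50), rel=1e-10)

    def test_gram_matrix_is_psd(self):
        rng = np.random.default_rng(7)
        pts = rng.standard_normal((10, 3))
        K = np.array(
            [[svm_rbf_kernel(a, b, 1.0) for b in pts] for a in pts]
        )
        np.testing.assert_allclose(K, K.T, atol=1e-15)
        assert np.linalg.eigvalsh(K).min() >= -1e-10

    def test_xor_training_accuracy(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([CANCER, CANCER, NORMAL, NORMAL], dtype=object)
        pred, _, _ = svm_fit_predict(X, y, X, sigma=0.5, C=10.0)
        assert np.all(pred == y)

    def test_dual_feasibility(self):
        feats = two_blob_features(n_per_class=20, delta=3.0, d=2, seed=8)
        _, _, model = svm_fit_predict(
            feats.values, feats.label_array(), feats.values, sigma=2.0, C=1.0
        )
        assert np.all(model.alphas >= -1e-12)
        assert np.all(model.alphas <= model.C + 1e-12)
        assert abs(np.sum(model.alphas * model.y)) < 1e-5

    def test_duplicated_training_set_leaves_predictions_unchanged(self):
        feats = two_blob_features(n_per_class=15, delta=6.0, d=2, seed=9)
        test = np.array([[0.0, 0.0], [6.0, 6.0], [3.5, 3.5], [2.5, 2.5]])
        base, _, _ = svm_fit_predict(
            feats.values, feats.label_array(), test, sigma=2.0, C=5.0
        )
        dup_X = np.vstack([feats.values, feats.values])
        dup_y = np.concatenate([feats.label_array(), feats.label_array()])
        dup, _, _ = svm_fit_predict(dup_X, dup_y, test, sigma=2.0, C=5.0)
        assert list(base) == list(dup)

    def test_matches_sklearn_svc_predictions(self):
        """Independent library cross-check on a non-trivially separable set."""
        from sklearn.svm import SVC

        rng = np.random.default_rng(13)
        X = np.vstack(
            [rng.standard_normal((30, 2)), rng.standard_normal((30, 2)) + 1.5]
        )
        y = np.array([CANCER] * 30 + [NORMAL] * 30, dtype=object)
        test = rng.standard_normal((20, 2)) + 0.75
        sigma, C = 1.0, 1.0
        ours, _, _ = svm_fit_predict(X, y, test, sigma=sigma, C=C)
        ref = SVC(kernel="rbf", gamma=1.0 / (2 * sigma**2), C=C)
        ref.fit(X, np.where(y == CANCER, 1, -1))
        ref_labels = np.where(ref.predict(test) == 1, CANCER, NORMAL)
        assert np.mean(ours == ref_labels) >= 0.95

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValidationError):
            svm_rbf_kernel(np.zeros(2), np.ones(2), 0.0)

    def test_predictions_are_pure(self):
        feats = two_blob_features(n_per_class=10, delta=5.0, seed=10)
        a, dec_a, _ = svm_fit_predict(
            feats.values, feats.label_array(), feats.values, sigma=1.0, seed=3
        )
        b, dec_b, _ = svm_fit_predict(
            feats.values, feats.label_array(), feats.values, sigma=1.0, seed=3
        )
        np.testing.assert_array_equal(dec_a, dec_b)
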