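"""Elastic-net logistic regression: solver correctness, calibration, CV."""

import warnings

import numpy as np
import pytest
import scipy.optimize
import scipy.special
from hypothesis import given, strategies as st

from falldetect.elasticnet_classifier import (
    ElasticNetModel,
    TrainingSet,
    auroc,
    calibrate_threshold,
    fit,
    grid_search,
    loso_cv,
    objective,
    predict_posterior,
    standardize_fit,
)


def toy_problem(n=50, d=8, seed=3):
    """A small logistic problem with planted weights and a pure-noise feature."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    w_true = np.zeros(d)
    w_true[:3] = [2.0, -1.5, 1.0]  # features 3.. are noise
    p = 1 / (1 + np.exp(-(X @ w_true - 0.3)))
    y = (rng.random(n) < p).astype(float)
    groups = np.array([f"P{i % 4}" for i in range(n)])
    return TrainingSet(X, y, groups)


def lbfgs_oracle(X_std, y, alpha, lam):
    """Independent minimiser: split w = w+ - w- so the L1 term is smooth-linear."""
    n, d = X_std.shape

    def f(u):
        wp, wn, b = u[:d], u[d:2 * d], u[-1]
        w = wp - wn
        z = X_std @ w + b
        p = np.clip(1 / (1 + np.exp(-z)), 1e-15, 1 - 1e-15)
        nll = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        return nll + lam * (alpha * np.sum(wp + wn) + 0.5 * (1 - alpha) * np.sum(w**2))

    bounds = [(0, None)] * (2 * d) + [(None, None)]
    res = scipy.optimize.minimize(
        f, np.zeros(2 * d + 1), method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12},
    )
    return res.fun


class TestStandardize:
    def test_zero_variance_column_gets_unit_std(self):
        means, stds = standardize_fit(np.array([[2.0, 0.0], [2.0, 2.0]]))
        assert means[0] == 2.0 and stds[0] == 1.0
        assert means[1] == 1.0 and stds[1] == pytest.approx(np.sqrt(2.0))

    def test_standardized_columns_have_zero_mean_unit_std(self):
        X = np.random.default_rng(0).normal(2, 3, (40, 5))
        means, stds = standardize_fit(X)
        Z = (X - means) / stds
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1, rtol=1e-12)


class TestObjective:
    def test_null_model_on_balanced_labels_is_log2(self):
        X = np.zeros((4, 2))
        y = np.array([0.0, 0.0, 1.0, 1.0])
        assert objective(np.zeros(2), 0.0, X, y, 0.6, 0.015) == pytest.approx(np.log(2))

    def test_lam_zero_is_pure_log_loss(self):
        rng = np.random.default_rng(1)
        X, w, b = rng.normal(size=(10, 3)), rng.normal(size=3), 0.2
        y = (rng.random(10) < 0.5).astype(float)
        p = 1 / (1 + np.exp(-(X @ w + b)))
        nll = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert objective(w, b, X, y, 0.6, 0.0) == pytest.approx(nll)

    def test_alpha_one_penalty_is_pure_l1(self):
        w = np.array([1.0, -2.0])
        base = objective(w, 0.0, np.zeros((2, 2)), np.array([0.0, 1.0]), 1.0, 0.0)
        with_pen = objective(w, 0.0, np.zeros((2, 2)), np.array([0.0, 1.0]), 1.0, 0.5)
        assert with_pen - base == pytest.approx(0.5 * 3.0)


class TestFit:
    def test_matches_independent_convex_optimizer(self):
        train = toy_problem()
        alpha, lam = 0.6, 0.015
        model = fit(train, alpha=alpha, lam=lam)
        means, stds = standardize_fit(train.X)
        Xs = (train.X - means) / stds
        ours = objective(model.weights, model.intercept, Xs, train.y, alpha, lam)
        oracle = lbfgs_oracle(Xs, train.y, alpha, lam)
        assert ours <= oracle + 1e-6

    def test_matches_sklearn_saga_objective(self):
        # sklearn's elastic-net logistic objective is C * sum-logloss +
        # l1_ratio*||w||_1 + (1-l1_ratio)/2*||w||_2^2; dividing ours by
        # lam maps onto it with C = 1/(n*lam)
        from sklearn.linear_model import LogisticRegression

        train = toy_problem(n=80, seed=9)
        alpha, lam = 0.6, 0.02
        means, stds = standardize_fit(train.X)
        Xs = (train.X - means) / stds
        n = len(Xs)
        sk = LogisticRegression(
            penalty="elasticnet", solver="saga", l1_ratio=alpha,
            C=1.0 / (n * lam), max_iter=100_000, tol=1e-10,
        ).fit(Xs, train.y)
        sk_obj = objective(sk.coef_[0], float(sk.intercept_[0]), Xs, train.y,
                           alpha, lam)
        model = fit(train, alpha=alpha, lam=lam)
        ours = objective(model.weights, model.intercept, Xs, train.y, alpha, lam)
        assert ours <= sk_obj + 1e-5

    def test_penalty_dominated_limit(self):
        train = toy_problem()
        model = fit(train, alpha=0.6, lam=1e3)
        np.testing.assert_allclose(model.weights, 0.0, atol=1e-10)
        odds = train.y.mean() / (1 - train.y.mean())
        assert model.intercept == pytest.approx(np.log(odds), rel=1e-3)

    def test_lasso_zeroes_noise_feature_exactly(self):
        train = toy_problem(n=200, seed=5)
        model = fit(train, alpha=1.0, lam=0.05)
        assert model.weights[5] == 0.0  # pure-noise coordinate
        assert np.any(model.weights[:3] != 0)

    def test_zero_variance_feature_masked(self):
        train = toy_problem()
        X = train.X.copy()
        X[:, 4] = 3.14
        model = fit(TrainingSet(X, train.y, train.groups))
        assert model.weights[4] == 0.0 and model.feature_stds[4] == 1.0

    def test_single_class_rejected(self):
        train = toy_problem()
        with pytest.raises(ValueError):
            fit(TrainingSet(train.X, np.zeros(len(train.y)), train.groups))

    def test_fitted_objective_beats_null_model(self):
        train = toy_problem()
        model = fit(train)
        means, stds = standardize_fit(train.X)
        Xs = (train.X - means) / stds
        fitted = objective(model.weights, model.intercept, Xs, train.y, 0.6, 0.015)
        null = objective(np.zeros(train.X.shape[1]), 0.0, Xs, train.y, 0.6, 0.015)
        assert fitted <= null

    def test_l1_norm_shrinks_with_lam(self):
        train = toy_problem(n=200, seed=5)
        norms = [np.abs(fit(train, lam=lam).weights).sum()
                 for lam in (0.001, 0.01, 0.1, 1.0)]
        assert all(b <= a + 1e-8 for a, b in zip(norms, norms[1:]))

    def test_posterior_invariant_to_feature_rescaling(self):
        train = toy_problem()
        model_a = fit(train)
        X2 = train.X.copy()
        X2[:, 1] *= 1000.0
        model_b = fit(TrainingSet(X2, train.y, train.groups))
        pa = predict_posterior(model_a, train.X)
        pb = predict_posterior(model_b, X2)
        np.testing.assert_allclose(pa, pb, atol=1e-8)


class TestPredict:
    def _null_model(self, d=3):
        return ElasticNetModel(np.zeros(d), np.ones(d), np.zeros(d), 0.0)

    def test_zero_weights_give_half(self):
        assert predict_posterior(self._null_model(), np.ones(3)) == 0.5

    def test_monotone_in_linear_score(self):
        model = ElasticNetModel(np.zeros(1), np.ones(1), np.ones(1), 0.0)
        xs = np.linspace(-5, 5, 11).reshape(-1, 1)
        p = predict_posterior(model, xs)
        assert np.all(np.diff(p) > 0)
        assert np.all((p > 0) & (p < 1))

    def test_batch_equals_per_sample(self):
        train = toy_problem()
        model = fit(train)
        batch = predict_posterior(model, train.X[:5])
        singles = [predict_posterior(model, x) for x in train.X[:5]]
        np.testing.assert_allclose(batch, singles)


class TestCalibrateThreshold:
    def _identity_model(self):
        # posterior == feature via logit trick is overkill; use a 1-feature model
        return ElasticNetModel(np.zeros(1), np.ones(1), np.ones(1), 0.0)

    def test_twenty_equally_spaced_posteriors(self):
        # posteriors 0.905, 0.910, ..., 1.000 -> 5th pct under linear
        # interpolation is 0.905 + 0.95 * 0.005 = 0.90975 (hand-computed)
        posteriors = np.linspace(0.905, 1.0, 20)
        X = scipy.special.logit(np.clip(posteriors, 0, 1 - 1e-12)).reshape(-1, 1)
        thr = calibrate_threshold(self._identity_model(), X)
        assert thr == pytest.approx(0.90975, abs=1e-6)

    def test_constant_posteriors_return_that_constant(self):
        X = np.zeros((25, 1))  # posterior 0.5 for all
        assert calibrate_threshold(self._identity_model(), X) == pytest.approx(0.5)

    def test_at_least_95_percent_of_falls_above_threshold(self):
        rng = np.random.default_rng(2)
        X = rng.normal(2, 3, (200, 1))
        model = self._identity_model()
        thr = calibrate_threshold(model, X)
        post = predict_posterior(model, X)
        assert np.mean(post >= thr) >= 0.95
        assert post.min() <= thr <= post.max()

    def test_too_few_falls_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold(self._identity_model(), np.zeros((19, 1)))


def brute_force_auroc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_known_values(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert auroc([0.5, 0.5, 0.5, 0.5], [0, 0, 1, 1]) == 0.5
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_pairwise_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        scores = np.round(rng.random(n), 2)  # coarse grid forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert auroc(scores, labels) == pytest.approx(
            brute_force_auroc(scores, labels), abs=1e-12
        )


class TestCrossValidation:
    def _two_participant_set(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 3))
        y = (X[:, 0] + 0.3 * rng.normal(size=80) > 0).astype(float)
        groups = np.array(["A"] * 40 + ["B"] * 40)
        return TrainingSet(X, y, groups)

    def test_one_fold_per_participant(self):
        folds, mean = loso_cv(self._two_participant_set())
        assert set(folds) == {"A", "B"}
        assert mean == pytest.approx(np.mean(list(folds.values())))

    def test_no_leakage_into_folds(self):
        train = self._two_participant_set()
        model_without_b = fit(train.subset(train.groups == "A"))
        refit = fit(train.subset(train.groups == "A"))
        np.testing.assert_array_equal(model_without_b.weights, refit.weights)

    def test_grid_search_shape_and_tie_break(self):
        train = self._two_participant_set()
        a, l, table = grid_search(train, alpha_grid=[0.6], lam_grid=[0.01])
        assert (a, l) == (0.6, 0.01) and len(table) == 1
        # a perfectly separable set gives AUROC 1 everywhere -> larger lam wins
        X = np.vstack([np.full((20, 2), -1.0), np.full((20, 2), 1.0)])
        X += np.random.default_rng(0).normal(0, 0.01, X.shape)
        y = np.array([0.0] * 20 + [1.0] * 20)
        groups = np.array((["A", "B"] * 20))
        sep = TrainingSet(X, y, groups)
        a, l, table = grid_search(sep, alpha_grid=[0.4, 0.6], lam_grid=[0.001, 0.01])
        assert len(table) == 4
        assert l == 0.01 and a == 0.6

    def test_single_class_fold_skipped_with_warning(self):
        train = self._two_participant_set()
        y = train.y.copy()
        y[train.groups == "B"] = 1.0
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            folds, _ = loso_cv(TrainingSet(train.X, y, train.groups))
        assert "B" not in folds
        assert any("single class" in str(w.message) for w in caught)


class TestPersistence:
    def test_json_roundtrip(self, tmp_path):
        model = fit(toy_problem())
        model.threshold = 0.87
        path = tmp_path / "m.json"
        model.save(path)
        back = ElasticNetModel.load(path)
        np.testing.assert_array_equal(back.weights, model.weights)
        assert back.threshold == model.threshold
        assert back.alpha == model.alpha and back.lam == model.lam
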