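import numpy as np
import pytest
from scipy.optimize import minimize

from fragminer.models import (
    ModelError,
    RLRModel,
    SVRModel,
    cv_kfold_regression,
    cv_random_subsampling,
    default_kernel_sigma,
    evaluate_classification,
    fit_rlr,
    fit_svr,
    grid_search_svr,
    rbf_kernel,
    rlr_objective,
    rlr_probability,
)


def toy_classification(n=80, p=4, seed=0, sep=2.0):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.5).astype(int)
    X = rng.normal(size=(n, p))
    X[:, 0] += sep * (y - 0.5)
    return X, y


class TestRLRProbability:
    def test_half_at_zero(self):
        assert rlr_probability(np.zeros(3), np.ones(3)) == pytest.approx(0.5)

    def test_complement_sums_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            W, x = rng.normal(size=4), rng.normal(size=4)
            p = rlr_probability(W, x)
            q = rlr_probability(-W, x)  # P(y=0 | x) under the symmetric form
            assert p + q == pytest.approx(1.0)

    def test_no_overflow_at_extremes(self):
        assert rlr_probability(np.array([1000.0]), np.array([1.0])) == pytest.approx(1.0)
        assert rlr_probability(np.array([-1000.0]), np.array([1.0])) == pytest.approx(0.0)


class TestFitRLR:
    def test_symmetric_data_gives_zero_weights(self):
        # each feature vector appears with both labels: W = 0 maximizes
        X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        y = np.array([1, 0, 1, 0])
        model = fit_rlr(X, y, sigma=1.0)
        assert np.allclose(model.W, 0.0, atol=1e-6)

    def test_separable_data_finite_weights(self):
        X = np.array([[1.0], [1.0], [-1.0], [-1.0]] * 3)
        y = np.array([1, 1, 0, 0] * 3)
        model = fit_rlr(X, y, sigma=2.0)
        assert np.isfinite(model.W).all()
        assert model.converged
        preds = model.predict(X)
        assert (preds == y).all()

    def test_matches_independent_optimizer(self):
        X, y = toy_classification(seed=3)
        sigma = 1.5
        model = fit_rlr(X, y, sigma=sigma)
        res = minimize(
            lambda w: -rlr_objective(w, X, y.astype(float), sigma),
            np.zeros(X.shape[1]),
            method="BFGS",
            options={"gtol": 1e-10, "maxiter": 500},
        )
        assert np.allclose(model.W, res.x, atol=1e-4)

    def test_objective_not_decreased_by_fit(self):
        X, y = toy_classification(seed=4)
        model = fit_rlr(X, y, sigma=1.0)
        assert rlr_objective(model.W, X, y.astype(float), 1.0) >= rlr_objective(
            np.zeros(X.shape[1]), X, y.astype(float), 1.0
        )

    def test_stronger_prior_shrinks_weights(self):
        X, y = toy_classification(seed=5)
        w_tight = fit_rlr(X, y, sigma=0.1).W
        w_loose = fit_rlr(X, y, sigma=10.0).W
        assert np.linalg.norm(w_tight) < np.linalg.norm(w_loose)

    def test_error_contracts(self):
        X = np.ones((4, 2))
        with pytest.raises(ModelError):
            fit_rlr(X, np.array([1, 1, 1, 1]))  # single class
        with pytest.raises(ModelError):
            fit_rlr(X, np.array([0, 1, 2, 1]))  # non-binary
        with pytest.raises(ModelError):
            fit_rlr(X, np.array([0, 1, 1, 1]))  # < 2 per class
        with pytest.raises(ModelError):
            fit_rlr(X, np.array([0, 0, 1, 1]), sigma=0.0)

    def test_json_round_trip(self):
        X, y = toy_classification(seed=6)
        model = fit_rlr(X, y, feature_keys=[f"f{i}" for i in range(X.shape[1])])
        back = RLRModel.from_json(model.to_json())
        assert np.allclose(back.W, model.W)
        assert back.feature_keys == model.feature_keys
        assert np.allclose(back.predict_proba(X), model.predict_proba(X))


class TestClassificationMetrics:
    def test_worked_confusion(self):
        # 10 positives: 9 scored above threshold; 10 negatives: 7 below
        scores = [0.9] * 9 + [0.1] + [0.2] * 7 + [0.8] * 3
        labels = [1] * 10 + [0] * 10
        m = evaluate_classification(scores, labels)
        assert m.sensitivity == pytest.approx(0.9)
        assert m.specificity == pytest.approx(0.7)
        assert m.accuracy == pytest.approx(0.8)

    def test_perfect_and_tied_auc(self):
        m = evaluate_classification([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert m.roc_auc == pytest.approx(1.0)
        m = evaluate_classification([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0])
        assert m.roc_auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ModelError):
            evaluate_classification([0.1, 0.9], [1, 1])


class TestRandomSubsamplingCV:
    def test_deterministic_under_seed(self):
        X, y = toy_classification(n=60, seed=7)
        a = cv_random_subsampling(X, y, repeats=3, seed=42)
        b = cv_random_subsampling(X, y, repeats=3, seed=42)
        assert a.as_dict() == b.as_dict()

    def test_seed_changes_result(self):
        X, y = toy_classification(n=60, seed=7, sep=0.5)
        a = cv_random_subsampling(X, y, repeats=3, seed=1)
        b = cv_random_subsampling(X, y, repeats=3, seed=2)
        assert a.as_dict() != b.as_dict()

    def test_recovers_separable_signal(self):
        X, y = toy_classification(n=120, seed=8, sep=3.0)
        m = cv_random_subsampling(X, y, repeats=5, seed=0)
        assert m.roc_auc > 0.95

    def test_too_few_samples_rejected(self):
        X, y = np.ones((2, 1)), np.array([0, 1])
        with pytest.raises(ModelError):
            cv_random_subsampling(X, y, n_subsets=3)


class TestRBFKernel:
    def test_unit_at_zero_distance(self):
        x = np.array([1.0, 2.0])
        assert rbf_kernel(x, x, sigma=1.0) == pytest.approx(1.0)

    def test_known_value(self):
        a, b = np.array([0.0]), np.array([1.0])
        assert rbf_kernel(a, b, sigma=1.0) == pytest.approx(np.exp(-0.5))

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a, b = rng.normal(size=3), rng.normal(size=3)
            k = rbf_kernel(a, b, 1.3)
            assert k == pytest.approx(rbf_kernel(b, a, 1.3))
            assert 0.0 < k <= 1.0

    def test_gram_matrix_psd(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 3))
        K = np.array([[rbf_kernel(a, b, 1.0) for b in pts] for a in pts])
        eig = np.linalg.eigvalsh(K)
        assert eig.min() > -1e-10

    def test_invalid_sigma(self):
        with pytest.raises(ModelError):
            rbf_kernel(np.zeros(2), np.zeros(2), 0.0)


class TestSVR:
    def toy_regression(self, n=60, p=5, seed=0, noise=0.0):
        rng = np.random.default_rng(seed)
        X = (rng.random((n, p)) < 0.4).astype(float)
        w = np.arange(1, p + 1, dtype=float) / p
        y = 5.0 + X @ w + rng.normal(0.0, noise, size=n)
        return X, y

    def test_training_interpolation(self):
        X, y = self.toy_regression(seed=1)
        model = fit_svr(X, y, box_constraint=100.0, epsilon=0.05)
        mse = float(np.mean((model.predict(X) - y) ** 2))
        assert mse < 0.05**2

    def test_default_sigma(self):
        assert default_kernel_sigma(30) == pytest.approx(np.sqrt(15.0))
        X, y = self.toy_regression()
        model = fit_svr(X, y)
        assert model.sigma == pytest.approx(default_kernel_sigma(X.shape[1]))

    def test_constant_target_fallback(self, caplog):
        X, _ = self.toy_regression(n=10)
        model = fit_svr(X, np.full(10, 6.5))
        assert model.constant_fallback == 6.5
        assert np.allclose(model.predict(X), 6.5)

    def test_error_contracts(self):
        X, y = self.toy_regression(n=10)
        with pytest.raises(ModelError):
            fit_svr(X[:3], y[:3])
        with pytest.raises(ModelError):
            fit_svr(X, y, box_constraint=-1.0)
        with pytest.raises(ModelError):
            fit_svr(X, y, sigma=-2.0)

    def test_json_round_trip(self):
        X, y = self.toy_regression(seed=2)
        model = fit_svr(X, y)
        back = SVRModel.from_json(model.to_json())
        assert np.allclose(back.predict(X), model.predict(X))


class TestKFoldCV:
    def test_deterministic(self):
        X, y = TestSVR().toy_regression(n=50, seed=3, noise=0.1)
        a = cv_kfold_regression(X, y, k=5, seed=9)
        b = cv_kfold_regression(X, y, k=5, seed=9)
        assert a.as_dict() == b.as_dict()

    def test_recovers_linear_target(self):
        X, y = TestSVR().toy_regression(n=150, seed=4, noise=0.05)
        m = cv_kfold_regression(X, y, k=5, seed=0, box_constraint=50.0)
        assert m.pearson_r > 0.9

    def test_k_exceeding_n_rejected(self):
        X, y = TestSVR().toy_regression(n=10)
        with pytest.raises(ModelError):
            cv_kfold_regression(X, y, k=11)

    def test_grid_search_picks_lowest_mse(self):
        X, y = TestSVR().toy_regression(n=60, seed=5, noise=0.05)
        params, metrics = grid_search_svr(
            X, y, sigmas=[0.5, 2.0], boxes=[1.0, 50.0], k=3, seed=0
        )
        for s in (0.5, 2.0):
            for c in (1.0, 50.0):
                other = cv_kfold_regression(X, y, k=3, seed=0, sigma=s, box_constraint=c)
                assert metrics.mse <= other.mse + 1e-12
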