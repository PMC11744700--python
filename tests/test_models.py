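"""Model zoo: fitting, metrics, cross-validation, gradient contract."""

import numpy as np
import pytest

from pofp.models import (
    ModelSpec,
    UnsupportedGradientError,
    build_fcnn,
    cross_validate,
    evaluate_classification,
    evaluate_regression,
    fit,
)

from _oracles import manual_r2, manual_weighted_f1


def _linear_problem(n=200, dim=46, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.poisson(1.0, size=(n, dim)).astype(float)
    w = rng.normal(0, 0.1, dim)
    y = X @ w + 2.5 + noise * rng.standard_normal(n)
    return X, y, w


class TestFitting:
    def test_linear_recovers_exact_coefficients(self):
        X, y, w = _linear_problem()
        model = fit(ModelSpec("linear", "regression"), X, y)
        grad = model.input_gradient(np.zeros(46))
        assert np.max(np.abs(grad - w)) < 1e-8
        metrics = evaluate_regression(y, model.predict(X))
        assert metrics.r2 == pytest.approx(1.0)

    def test_knn_k1_memorizes_training_set(self):
        X, y, _ = _linear_problem(n=80)
        model = fit(ModelSpec("knn", "regression", {"n_neighbors": 1}), X, y)
        assert evaluate_regression(y, model.predict(X)).mae == pytest.approx(0.0)

    def test_fcnn_scaffold_shape_and_seeding(self):
        X, y, _ = _linear_problem(n=60)
        m1 = fit(build_fcnn(task="regression", seed=9, hidden_sizes=(16, 8, 4)),
                 X, y)
        assert m1.predict(np.zeros((1, 46))).shape == (1,)
        assert [W.shape for W in m1.estimator.coefs_] == [
            (46, 16), (16, 8), (8, 4), (4, 1)]
        with pytest.raises(ValueError):
            build_fcnn(hidden_sizes=(16, 8))

    def test_fcnn_same_seed_identical_weights(self):
        X, y, _ = _linear_problem(n=60)
        hp = {"max_iter": 5, "early_stopping": False}
        coefs = []
        for _ in range(2):
            m = fit(ModelSpec("fcnn", "regression", hp, seed=3), X, y)
            coefs.append([W.copy() for W in m.estimator.coefs_])
        for a, b in zip(*coefs):
            assert (a == b).all()

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            fit(ModelSpec("linear", "regression"), np.zeros((1, 46)), [1.0])


class TestGradientContract:
    def test_fcnn_gradient_matches_central_differences(self, fcnn_reg):
        rng = np.random.default_rng(0)
        h = 1e-4
        for _ in range(10):
            x = rng.uniform(0.0, 3.0, 46)
            grad = fcnn_reg.input_gradient(x)
            fd = np.empty(46)
            for i in range(46):
                xp, xm = x.copy(), x.copy()
                xp[i] += h
                xm[i] -= h
                fd[i] = (fcnn_reg.predict(xp[None])[0]
                         - fcnn_reg.predict(xm[None])[0]) / (2 * h)
            scale = max(np.max(np.abs(fd)), 1e-9)
            assert np.max(np.abs(grad - fd)) / scale < 1e-4

    def test_classifier_probability_gradient(self, fcnn_clf):
        rng = np.random.default_rng(1)
        h = 1e-4
        k = list(fcnn_clf.classes_).index("AIE")
        x = rng.uniform(0.5, 2.5, 46)
        grad = fcnn_clf.input_gradient(x, target="AIE")
        fd = np.empty(46)
        for i in range(46):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            fd[i] = (fcnn_clf.predict_scores(xp[None])[0, k]
                     - fcnn_clf.predict_scores(xm[None])[0, k]) / (2 * h)
        scale = max(np.max(np.abs(fd)), np.max(np.abs(grad)), 1e-9)
        assert np.max(np.abs(grad - fd)) / scale < 1e-4

    def test_tree_models_have_no_gradient(self):
        X, y, _ = _linear_problem(n=60)
        model = fit(ModelSpec("decision_tree", "regression"), X, y)
        with pytest.raises(UnsupportedGradientError):
            model.input_gradient(np.zeros(46))


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        m = evaluate_regression(y, y)
        assert (m.r2, m.mae, m.mse) == (1.0, 0.0, 0.0)
        c = evaluate_classification(["A", "B"], ["A", "B"])
        assert c.accuracy == 1.0 and c.weighted_f1 == 1.0

    def test_constant_predictor_r2_nonpositive(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = evaluate_regression(y, np.full(4, y.mean()))
        assert m.r2 <= 0.0 + 1e-12

    def test_two_class_toy_accuracy(self):
        m = evaluate_classification(["A", "B", "A", "B"], ["A", "A", "B", "B"])
        assert m.accuracy == 0.5

    def test_weighted_f1_matches_hand_computation(self):
        y_true = list("AAAABBBCCC")
        y_pred = list("AABCBBACCC")
        m = evaluate_classification(y_true, y_pred, labels=["A", "B", "C"])
        # per-class F1: A=4/7, B=2/3, C=6/7; support-weighted mean = 24/35
        assert m.weighted_f1 == pytest.approx(24 / 35, abs=1e-12)
        assert m.accuracy == pytest.approx(0.7)

    def test_metrics_match_definition_oracles_on_random_data(self):
        rng = np.random.default_rng(5)
        y_true = rng.normal(size=200)
        y_pred = y_true + rng.normal(scale=0.3, size=200)
        m = evaluate_regression(y_true, y_pred)
        assert m.r2 == pytest.approx(manual_r2(y_true, y_pred), abs=1e-12)
        assert m.mae == pytest.approx(np.mean(np.abs(y_true - y_pred)), abs=1e-12)
        assert m.mse == pytest.approx(np.mean((y_true - y_pred) ** 2), abs=1e-12)
        labels = ["x", "y", "z"]
        c_true = rng.choice(labels, 300)
        c_pred = rng.choice(labels, 300)
        c = evaluate_classification(c_true, c_pred, labels=labels)
        assert c.weighted_f1 == pytest.approx(
            manual_weighted_f1(c_true, c_pred, labels), abs=1e-12
        )

    def test_confusion_rows_normalize_to_one(self, synth_xy, fcnn_clf):
        X, _, yc = synth_xy
        m = evaluate_classification(yc, fcnn_clf.predict(X), labels=sorted(set(yc)))
        norm = m.confusion_normalized
        occupied = m.confusion.sum(axis=1) > 0
        assert np.allclose(norm[occupied].sum(axis=1), 1.0, atol=1e-9)


class TestCrossValidation:
    def test_perfectly_separable_classes(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.1, (40, 46)), rng.normal(5, 0.1, (40, 46))])
        y = np.array(["lo"] * 40 + ["hi"] * 40)
        result = cross_validate(ModelSpec("random_forest", "classification"),
                                X, y, folds=5, seed=0)
        assert result["mean"]["accuracy"] == 1.0
        assert result["mean"]["weighted_f1"] == 1.0

    def test_deterministic_under_seed(self):
        X, y, _ = _linear_problem(n=150, noise=0.1)
        runs = [cross_validate(ModelSpec("decision_tree", "regression", seed=4),
                               X, y, folds=5, seed=4)["mean"] for _ in range(2)]
        assert runs[0] == runs[1]

    def test_rare_class_relaxes_stratification(self):
        X = np.random.default_rng(0).normal(size=(30, 46))
        y = np.array(["a"] * 28 + ["b"] * 2)
        with pytest.warns(UserWarning, match="stratification relaxed"):
            cross_validate(ModelSpec("knn", "classification"), X, y,
                           folds=5, seed=0)

    def test_gaussian_noise_sets_the_mae_floor(self):
        """With N(0, s^2) label noise the best possible CV MAE is s*sqrt(2/pi)."""
        sigma = 0.05
        X, y, _ = _linear_problem(n=2000, seed=6, noise=sigma)
        result = cross_validate(ModelSpec("linear", "regression"), X, y,
                                folds=5, seed=6)
        expected = sigma * np.sqrt(2 / np.pi)
        assert abs(result["mean"]["mae"] - expected) / expected < 0.15


class TestFcnnOnSyntheticStudy:
    def test_loss_curve_decreases(self, fcnn_reg):
        curve = np.asarray(fcnn_reg.loss_curve_)
        assert curve[-1] <= curve[0]
        assert curve[:10].mean() > curve[-10:].mean()

    def test_cross_validated_r2_beats_085(self, synth_xy):
        X, y, _ = synth_xy
        result = cross_validate(ModelSpec("fcnn", "regression", seed=42),
                                X, y, folds=5, seed=42)
        assert result["mean"]["r2"] >= 0.85
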