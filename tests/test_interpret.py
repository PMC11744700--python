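"""Integrated gradients: closed forms, completeness, convergence, sweeps."""

import numpy as np
import pytest

from pofp.features import compute_pofp
from pofp.interpret import (
    IGConfig,
    attribution_report,
    baseline_s10_s46,
    classify_and_attribute,
    ig_sweep,
    integrated_gradient,
    path_points,
)
from pofp.models import ModelSpec, fit
from pofp.synthetic import GroundTruth, flexibility_score, rigidity_score

from _oracles import trapezoid_path_integral_ig


class TestPathPoints:
    def test_degenerate_path(self):
        x = np.ones(46)
        pts = path_points(x, x, 5)
        assert (pts == x).all()

    def test_two_steps_are_endpoints(self):
        x, b = np.full(46, 2.0), np.zeros(46)
        pts = path_points(x, b, 2)
        assert (pts[0] == b).all() and (pts[1] == x).all()

    def test_midpoint(self):
        x, b = np.full(46, 3.0), np.ones(46)
        pts = path_points(x, b, 3)
        assert np.allclose(pts[1], (x + b) / 2)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            path_points(np.zeros(46), np.zeros(10), 5)


@pytest.fixture(scope="module")
def linear_model():
    rng = np.random.default_rng(8)
    X = rng.poisson(1.0, (300, 46)).astype(float)
    w = rng.normal(0, 0.1, 46)
    return fit(ModelSpec("linear", "regression"), X, X @ w + 1.0), w


class TestLinearClosedForms:
    def test_unnormalized_ig_is_the_coefficient(self, linear_model):
        model, w = linear_model
        rng = np.random.default_rng(0)
        config = IGConfig(baseline=rng.uniform(0, 2, 46),
                          variant="unnormalized_eq4")
        res = integrated_gradient(model, rng.uniform(0, 3, 46), config)
        assert np.allclose(res.attributions, w, atol=1e-8)

    def test_normalized_ig_completeness_exact(self, linear_model):
        model, w = linear_model
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 3, 46)
        b = rng.uniform(0, 2, 46)
        res = integrated_gradient(model, x, IGConfig(baseline=b))
        assert np.allclose(res.attributions, w * (x - b), atol=1e-8)
        assert res.attributions.sum() == pytest.approx(
            res.model_output_at_x - res.model_output_at_baseline, abs=1e-6
        )

    def test_fraction_of_total_sums_to_one(self, linear_model):
        model, _ = linear_model
        rng = np.random.default_rng(2)
        config = IGConfig(variant="fraction_of_total")
        res = integrated_gradient(model, rng.uniform(1, 3, 46), config)
        assert res.attributions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_path_degeneracy(self, linear_model):
        model, _ = linear_model
        x = np.full(46, 1.5)
        res = integrated_gradient(model, x, IGConfig(baseline=x))
        assert (res.attributions == 0).all()
        assert res.model_output_at_x == res.model_output_at_baseline
        with pytest.raises(ZeroDivisionError):
            integrated_gradient(
                model, x, IGConfig(baseline=x, variant="fraction_of_total")
            )


class TestTrainedFcnn:
    def test_agrees_with_fine_discretization_oracle(self, fcnn_reg):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 3, 46)
        b = baseline_s10_s46()
        res = integrated_gradient(fcnn_reg, x, IGConfig(baseline=b, n_steps=100))
        oracle = trapezoid_path_integral_ig(fcnn_reg, x, b, 10_000)
        # ReLU nets have piecewise-constant gradients along the path, so a
        # 100-point quadrature carries O(1/n) kink error; 5% of the largest
        # attribution bounds that error at n=100.
        scale = np.max(np.abs(oracle))
        assert np.allclose(res.attributions, oracle,
                           rtol=1e-3, atol=5e-2 * scale)
        # and the error must shrink by ~an order of magnitude at 10x steps
        res1000 = integrated_gradient(
            fcnn_reg, x, IGConfig(baseline=b, n_steps=1000)
        )
        assert (np.max(np.abs(res1000.attributions - oracle))
                < 0.2 * np.max(np.abs(res.attributions - oracle)))

    def test_discretization_is_cauchy(self, fcnn_reg):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 3, 46)
        attrs = [
            integrated_gradient(fcnn_reg, x, IGConfig(n_steps=n)).attributions
            for n in (100, 1000, 10_000)
        ]
        d1 = np.linalg.norm(attrs[1] - attrs[0])
        d2 = np.linalg.norm(attrs[2] - attrs[1])
        assert d2 <= d1

    def test_completeness_within_tolerance(self, fcnn_reg, fcnn_clf):
        x = compute_pofp(
            "CN(C)c1ccc(C=Cc2ccc(C#N)cc2)cc1", mode="num"
        ).values.astype(float)
        res = integrated_gradient(fcnn_reg, x, IGConfig(n_steps=100))
        gap = res.model_output_at_x - res.model_output_at_baseline
        assert res.attributions.sum() == pytest.approx(gap, abs=1e-2)
        resc = integrated_gradient(
            fcnn_clf, x, IGConfig(n_steps=100, target="AIE")
        )
        gap = resc.model_output_at_x - resc.model_output_at_baseline
        assert resc.attributions.sum() == pytest.approx(gap, abs=1e-2)


class TestSweep:
    def test_single_value_equals_direct_call(self, fcnn_reg):
        template = baseline_s10_s46(s10=1.0, s46=10.0)
        config = IGConfig(baseline=baseline_s10_s46())
        frame = ig_sweep(fcnn_reg, template, 46, [20.0], config)
        x = template.copy()
        x[45] = 20.0
        direct = integrated_gradient(fcnn_reg, x, config)
        assert len(frame) == 1
        assert frame["ig_s46"].iloc[0] == pytest.approx(direct.attributions[45])

    def test_row_count_and_ordering(self, fcnn_reg):
        values = [6.0, 12.0, 18.0, 24.0, 30.0]
        frame = ig_sweep(fcnn_reg, baseline_s10_s46(), 46, values)
        assert len(frame) == len(values)
        assert frame["value"].tolist() == values

    def test_s46_attribution_toward_aie_is_negative_midrange(self, fcnn_clf):
        """The generator builds in an anti-AIE conjugation effect; the sweep
        must recover its sign on a fingerprint of fixed flexibility."""
        template = baseline_s10_s46(s10=1.0, s46=6.0)
        config = IGConfig(baseline=baseline_s10_s46(), target="AIE")
        frame = ig_sweep(fcnn_clf, template, 46,
                         [12.0, 18.0, 24.0, 30.0], config)
        assert (frame["ig_s46"] < 0).all()


class TestClassifyAndAttribute:
    def _strong_aie_smiles(self, synth_ds):
        gt = GroundTruth()
        best, margin = None, -np.inf
        for rec in synth_ds:
            fp = compute_pofp(rec.smiles, mode="num")
            m = flexibility_score(fp) - rigidity_score(fp, gt)
            if rec.feature_class == "AIE" and m > margin:
                best, margin = rec.smiles, m
        return best

    def test_generative_aie_molecule_predicted_aie(self, fcnn_clf, synth_ds):
        smiles = self._strong_aie_smiles(synth_ds)
        predicted, result = classify_and_attribute(fcnn_clf, smiles)
        assert predicted == "AIE"
        assert result.config.target == "AIE"

    def test_baseline_equal_features_get_zero_attribution(self, fcnn_clf):
        predicted, result = classify_and_attribute(fcnn_clf, "c1ccc(C=Cc2ccccc2)cc1")
        fp = compute_pofp("c1ccc(C=Cc2ccccc2)cc1", mode="num").values
        inactive = fp == 0  # all-zero baseline
        assert (result.attributions[inactive] == 0).all()

    def test_report_lists_active_digits_with_signs(self, fcnn_clf):
        _, result = classify_and_attribute(fcnn_clf, "c1ccc(C=Cc2ccccc2)cc1")
        report = attribution_report(result, min_abs=0.0)
        assert list(report.columns) == ["feature", "name", "attribution"]
        assert {"s10", "s46"} <= set(report["feature"])
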