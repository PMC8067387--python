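import json

import numpy as np
import pytest

from sericata import constants
from sericata.growth import (
    LengthAdhModel,
    fit_length_models,
    fit_sigmoid,
    predict_adh,
    published_length_model,
    select_best,
    sigmoid,
    sigmoid_bands,
)

PUB = constants.SIGMOID_PARAMS  # a=28.56, b=3.28, x0=22.31, y0=11.14
TEMPS7 = np.array([20.0, 22.0, 24.0, 26.0, 28.0, 32.0, 35.0])


def rates_from_times():
    return [
        (t, constants.RATE_SCALE / (d * 24.0))
        for t, d in constants.MEAN_DEV_TIME_DAYS.items()
    ]


class TestSigmoid:
    def test_noiseless_recovery_of_generating_parameters(self):
        x = np.linspace(20, 35, 9)
        y = sigmoid(x, PUB["a"], PUB["b"], PUB["x0"], PUB["y0"])
        fit = fit_sigmoid(zip(x, y))
        assert fit.a == pytest.approx(PUB["a"], abs=1e-6)
        assert fit.b == pytest.approx(PUB["b"], abs=1e-6)
        assert fit.x0 == pytest.approx(PUB["x0"], abs=1e-6)
        assert fit.y0 == pytest.approx(PUB["y0"], abs=1e-6)

    def test_optimum_temperature_from_published_times(self):
        fit = fit_sigmoid(rates_from_times())
        assert abs(fit.x0 - PUB["x0"]) <= constants.SIGMOID_X0_CI95
        assert fit.a > 0 and fit.b > 0
        assert fit.r2_adj > 0.9

    def test_curve_value_at_twenty_degrees(self):
        # direct evaluation with the published parameters
        val = sigmoid(20.0, PUB["a"], PUB["b"], PUB["x0"], PUB["y0"])
        assert val == pytest.approx(20.59, abs=0.005)

    def test_deterministic_given_inputs(self):
        f1 = fit_sigmoid(rates_from_times())
        f2 = fit_sigmoid(rates_from_times())
        assert (f1.a, f1.b, f1.x0, f1.y0) == (f2.a, f2.b, f2.x0, f2.y0)

    def test_monotone_and_limits(self):
        fit = fit_sigmoid(rates_from_times())
        x = np.linspace(0, 45, 200)
        assert np.all(np.diff(fit.predict(x)) > 0)
        assert fit.predict(-1e6) == pytest.approx(fit.y0, rel=1e-6)
        assert fit.predict(1e6) == pytest.approx(fit.y0 + fit.a, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_sigmoid([(20, 1.0), (25, 2.0), (30, 3.0), (35, 3.5)])


@pytest.fixture(scope="module")
def bands_fit():
    return fit_sigmoid(rates_from_times())


class TestSigmoidBands:

    def test_mean_curve_at_inflection(self, bands_fit):
        fit = bands_fit
        bands = sigmoid_bands(fit, [fit.x0])
        assert bands.mean[0] == pytest.approx(fit.y0 + fit.a / 2.0, rel=1e-9)

    def test_prediction_band_contains_confidence_band(self, bands_fit):
        bands = sigmoid_bands(bands_fit, np.linspace(18, 37, 50))
        assert np.all(bands.pi_low <= bands.ci_low + 1e-12)
        assert np.all(bands.pi_high >= bands.ci_high - 1e-12)

    def test_prediction_band_coverage_on_simulation(self):
        # generate noisy rate curves, refit, check new points fall inside
        rng = np.random.default_rng(21)
        x = np.linspace(18, 37, 40)
        true = sigmoid(x, PUB["a"], PUB["b"], PUB["x0"], PUB["y0"])
        sigma = 1.2
        fit = fit_sigmoid(zip(x, true + rng.normal(0, sigma, x.size)))
        bands = sigmoid_bands(fit, x)
        hits = total = 0
        for _ in range(50):
            y_new = true + rng.normal(0, sigma, x.size)
            hits += int(((bands.pi_low <= y_new) & (y_new <= bands.pi_high)).sum())
            total += x.size
        assert hits / total == pytest.approx(0.95, abs=0.03)


class TestLengthModels:
    def test_six_models_fitted_with_mse_identity(self, length_adh_sample):
        x, y = length_adh_sample
        models = fit_length_models(x, y)
        assert set(models) == {
            (f, r) for f in ("linear", "quadratic", "logarithm")
            for r in ("adh", "log10adh")
        }
        for m in models.values():
            assert m.mse == pytest.approx(m.se_est**2, rel=1e-12)
            assert m.r2_adj <= m.r2

    def test_recovers_generating_log_model(self, length_adh_sample):
        x, y = length_adh_sample
        m = fit_length_models(x, y)[("logarithm", "log10adh")]
        b0, b1 = m.coefficients
        assert b0 == pytest.approx(2.295, abs=0.03)
        assert b1 == pytest.approx(0.327, abs=0.02)
        assert m.mse == pytest.approx(0.007, abs=0.002)

    def test_perfectly_linear_data(self):
        x = np.linspace(1, 15, 20)
        y = 100.0 + 80.0 * x
        m = fit_length_models(x, y)[("linear", "adh")]
        assert m.r2_adj == pytest.approx(1.0, abs=1e-12)
        assert m.mse == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 15, 12)
        y = 50 + 90 * x + rng.normal(0, 20, 12)
        models = fit_length_models(x, y)
        for family, cols in (
            ("linear", lambda x: np.column_stack([np.ones_like(x), x])),
            ("quadratic", lambda x: np.column_stack([np.ones_like(x), x, x**2])),
        ):
            X = cols(x)
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(
                models[(family, "adh")].coefficients, beta, atol=1e-8
            )

    def test_nonpositive_inputs_named_in_error(self):
        x = np.linspace(1, 15, 12).tolist()
        y = (100 * np.ones(12)).tolist()
        y[4] = -3.0
        with pytest.raises(ValueError, match="record 4"):
            fit_length_models(x, y)


class TestSelection:
    def test_exactly_quadratic_data_selects_quadratic(self):
        x = np.linspace(1, 15, 30)
        y = 40 + 160 * x - 4.8 * x**2 + 900  # keep ADH positive
        sel = select_best(fit_length_models(x, y))
        assert sel.best.family == "quadratic"
        assert len(sel.ranking) == 6

    def test_ties_in_r2adj_break_on_lower_mse(self):
        a = LengthAdhModel("linear", "log10adh", np.array([1.0, 1.0]), 0.9, 0.8,
                           0.2, 0.04, 50, 48, None, (1, 15), 0.8)
        b = LengthAdhModel("logarithm", "log10adh", np.array([1.0, 1.0]), 0.9, 0.8,
                           0.1, 0.01, 50, 48, None, (1, 15), 0.8)
        sel = select_best({("linear", "log10adh"): a, ("logarithm", "log10adh"): b,
                           ("linear", "adh"): LengthAdhModel(
                               "linear", "adh", np.array([1.0, 1.0]), 0.5, 0.4,
                               9.0, 81.0, 50, 48, None, (1, 15), 0.3)})
        assert sel.best is b

    def test_log_generative_data_selects_log_family(self, length_adh_sample):
        x, y = length_adh_sample
        sel = select_best(fit_length_models(x, y))
        assert (sel.best.family, sel.best.response) == ("logarithm", "log10adh")


class TestPrediction:
    def test_published_model_point_predictions(self):
        m = published_length_model()
        assert predict_adh(m, 10.0).point == pytest.approx(418.8, abs=0.5)
        assert predict_adh(m, 1.0).point == pytest.approx(197.2, abs=0.5)

    def test_interval_widens_at_range_edges(self, length_adh_sample):
        x, y = length_adh_sample
        m = fit_length_models(x, y)[("logarithm", "log10adh")]
        mid = float(np.exp(np.mean(np.log(x))))  # geometric center of design
        def width(l):
            p = predict_adh(m, l)
            return np.log10(p.hi) - np.log10(p.lo)  # response-scale width
        assert width(mid) < width(m.length_range_mm[0])
        assert width(mid) < width(m.length_range_mm[1])

    def test_extrapolation_flagged_not_silent(self):
        m = published_length_model()
        assert predict_adh(m, 25.0).extrapolated
        assert not predict_adh(m, 8.0).extrapolated

    def test_interval_endpoints_positive_and_ordered(self):
        m = published_length_model()
        p = predict_adh(m, 5.0)
        assert 0 < p.lo < p.point < p.hi

    def test_bias_correction_inflates_point(self):
        m = published_length_model()
        naive = predict_adh(m, 5.0).point
        corrected = predict_adh(m, 5.0, bias_correct=True).point
        assert corrected > naive

    def test_json_round_trip_preserves_predictions(self, tmp_path, length_adh_sample):
        x, y = length_adh_sample
        m = fit_length_models(x, y)[("quadratic", "log10adh")]
        path = tmp_path / "model.json"
        m.to_json(path)
        m2 = LengthAdhModel.from_json(path)
        for l in (2.0, 5.0, 12.0):
            p1, p2 = predict_adh(m, l), predict_adh(m2, l)
            assert (p1.point, p1.lo, p1.hi) == pytest.approx((p2.point, p2.lo, p2.hi))
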