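"""Published risk score, logistic fitting, elimination and metrics."""

import math

import numpy as np
import pandas as pd
import pytest

from glykit.errors import SeparationError, ValidationError
from glykit.risk import (
    PUBLISHED_COEFFICIENTS,
    PUBLISHED_INTERCEPT,
    PUBLISHED_RISK_MODEL,
    classifier_metrics,
    classify_risk,
    fit_logistic,
    published_risk,
    risk_predictors,
    wald_backward_eliminate,
)

EXAMPLE = {"eta": 1.0, "Pi_X": 0.1, "G_b": 4.5, "I_b": 30.0, "tau": 90.0, "k_xgi": 1e-4}


class TestPublishedModel:
    def test_stored_coefficients_are_the_printed_ones(self):
        assert PUBLISHED_COEFFICIENTS == {
            "eta": 0.5310,
            "Pi_X": 0.1960,
            "G_b": 1.2799,
            "I_b": 0.0330,
            "tau": -0.0187,
            "k_xgi": -798.2059,
        }
        assert PUBLISHED_INTERCEPT == -6.0103

    def test_probability_matches_hand_evaluation(self):
        z = (
            0.5310 * 1.0 + 0.1960 * 0.1 + 1.2799 * 4.5 + 0.0330 * 30.0
            - 0.0187 * 90.0 - 798.2059 * 1e-4 - 6.0103
        )
        expected = math.exp(z) / (1.0 + math.exp(z))
        assert PUBLISHED_RISK_MODEL.predict(EXAMPLE) == pytest.approx(expected, abs=1e-12)

    def test_zero_score_gives_half(self):
        values = dict(EXAMPLE)
        # solve eta so that z == 0
        partial = sum(
            c * values[n] for n, c in PUBLISHED_COEFFICIENTS.items() if n != "eta"
        ) + PUBLISHED_INTERCEPT
        values["eta"] = -partial / PUBLISHED_COEFFICIENTS["eta"]
        assert PUBLISHED_RISK_MODEL.predict(values) == pytest.approx(0.5, abs=1e-12)

    def test_missing_predictor_named(self):
        bad = {k: v for k, v in EXAMPLE.items() if k != "tau"}
        with pytest.raises(ValidationError, match="tau"):
            PUBLISHED_RISK_MODEL.predict(bad)

    @pytest.mark.parametrize(
        "name, sign", [("G_b", +1), ("I_b", +1), ("tau", -1), ("k_xgi", -1)]
    )
    def test_monotonicity_follows_coefficient_signs(self, name, sign):
        lo = PUBLISHED_RISK_MODEL.predict(EXAMPLE)
        bumped = dict(EXAMPLE)
        bumped[name] *= 1.10
        hi = PUBLISHED_RISK_MODEL.predict(bumped)
        assert (hi - lo) * sign > 0

    def test_predictors_assembled_from_parameters(self, healthy_params):
        vals = risk_predictors(healthy_params)
        assert set(vals) == set(PUBLISHED_COEFFICIENTS)
        assert 0.0 < published_risk(healthy_params) < 1.0


class TestThreshold:
    @pytest.mark.parametrize(
        "p, label",
        [(0.60, "non-healthy"), (0.599, "healthy"), (0.0, "healthy"), (1.0, "non-healthy")],
    )
    def test_boundary_inclusive_classification(self, p, label):
        assert classify_risk(p) == label

    def test_invalid_probability(self):
        with pytest.raises(ValidationError):
            classify_risk(1.5)


def simulate_logistic(n, coeffs, intercept, seed):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({k: rng.normal(0, 1, n) for k in coeffs})
    z = intercept + X.to_numpy() @ np.array(list(coeffs.values()))
    y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-z))).astype(int)
    return X, y


class TestLogisticFit:
    def test_recovers_generating_coefficients_within_2se(self):
        truth = {"x0": 1.2, "x1": -0.7}
        X, y = simulate_logistic(2000, truth, 0.3, seed=9)
        fit = fit_logistic(X, y)
        for name, true in {**truth, "const": 0.3}.items():
            assert abs(fit.coefficients[name] - true) < 2 * fit.std_errors[name]

    def test_intercept_only_on_balanced_labels(self):
        y = np.array([0, 1] * 100)
        fit = fit_logistic(pd.DataFrame(index=np.arange(200)), y)
        assert fit.coefficients["const"] == pytest.approx(0.0, abs=1e-8)

    def test_log_likelihood_matches_grid_search(self):
        X, y = simulate_logistic(300, {"x0": 0.8}, -0.2, seed=10)
        fit = fit_logistic(X, y)

        def loglik(b0, b1):
            z = b0 + b1 * X["x0"].to_numpy()
            return np.sum(y * z - np.log1p(np.exp(z)))

        grid = [
            loglik(b0, b1)
            for b0 in np.linspace(-1.0, 1.0, 81)
            for b1 in np.linspace(0.0, 1.6, 81)
        ]
        assert fit.log_likelihood >= max(grid) - 1e-6
        assert fit.log_likelihood == pytest.approx(
            loglik(fit.coefficients["const"], fit.coefficients["x0"]), abs=1e-9
        )

    def test_refit_from_solution_is_a_fixed_point(self):
        X, y = simulate_logistic(500, {"x0": 1.0}, 0.0, seed=12)
        a = fit_logistic(X, y)
        b = fit_logistic(X, y)
        assert a.coefficients == b.coefficients

    def test_perfect_separation_raises(self):
        X = pd.DataFrame({"x0": np.concatenate([np.arange(10), np.arange(20, 30)])})
        y = np.array([0] * 10 + [1] * 10)
        with pytest.raises(SeparationError):
            fit_logistic(X, y)

    def test_singular_design_names_columns(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=100)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        y = (rng.uniform(size=100) < 0.5).astype(int)
        with pytest.raises(ValidationError, match="collinear"):
            fit_logistic(X, y)


class TestBackwardElimination:
    def test_noise_predictors_eliminated_informative_kept(self):
        """At alpha = 0.01 a clean final model appears in >= 90% of seeds.

        (At alpha each noise predictor survives with probability ~alpha,
        so the expected clean fraction is (1 - alpha)^3; alpha = 0.05
        would only give ~86%.)
        """
        kept, total = 0, 20
        for s in range(total):
            X, y = simulate_logistic(2000, {"signal": 1.5}, 0.0, seed=100 + s)
            rng = np.random.default_rng(200 + s)
            for j in range(3):
                X[f"noise{j}"] = rng.normal(size=len(X))
            fit, trace = wald_backward_eliminate(X, y, alpha=0.01)
            names = set(fit.coefficients) - {"const"}
            if "signal" in names and not any(n.startswith("noise") for n in names):
                kept += 1
        assert kept >= 0.90 * total

    def test_all_significant_model_untouched(self):
        X, y = simulate_logistic(2000, {"x0": 1.5, "x1": -1.2}, 0.0, seed=14)
        fit, trace = wald_backward_eliminate(X, y)
        assert trace == []
        assert set(fit.coefficients) == {"const", "x0", "x1"}

    def test_alpha_one_eliminates_nothing(self):
        X, y = simulate_logistic(500, {"x0": 0.01}, 0.0, seed=15)
        X["pure_noise"] = np.random.default_rng(16).normal(size=len(X))
        fit, trace = wald_backward_eliminate(X, y, alpha=1.0)
        assert trace == []
        assert set(fit.coefficients) == {"const", "x0", "pure_noise"}

    def test_never_drops_a_significant_predictor(self):
        X, y = simulate_logistic(1500, {"x0": 1.0, "x1": 0.02, "x2": 0.01}, 0.0, seed=17)
        fit, trace = wald_backward_eliminate(X, y, alpha=0.05)
        for step in trace:
            assert step.p_value >= 0.05


class TestMetrics:
    def test_perfect_classifier(self):
        p = np.array([0.9, 0.8, 0.1, 0.2])
        y = np.array([1, 1, 0, 0])
        m = classifier_metrics(p, y, threshold=0.5)
        assert m.mcc == 1.0 and m.sensitivity == 1.0 and m.specificity == 1.0
        assert m.haldane_corrected  # zero FP/FN cells

    def test_constructed_confusion_table_arithmetic(self):
        p = np.concatenate([
            np.full(77, 0.9), np.full(23, 0.1),  # 100 non-healthy: 77 TP, 23 FN
            np.full(26, 0.9), np.full(74, 0.1),  # 100 healthy: 26 FP, 74 TN
        ])
        y = np.concatenate([np.ones(100), np.zeros(100)]).astype(int)
        m = classifier_metrics(p, y, threshold=0.6)
        assert (m.tp, m.fn, m.fp, m.tn) == (77, 23, 26, 74)
        assert m.sensitivity == pytest.approx(0.77)
        assert m.specificity == pytest.approx(0.74)
        assert m.diagnostic_odds_ratio == pytest.approx((77 * 74) / (26 * 23), rel=1e-12)
        assert m.diagnostic_odds_ratio == pytest.approx(9.528, abs=5e-4)

    def test_aic_definition(self):
        m = classifier_metrics([0.5], [1], threshold=0.4, log_likelihood=-10.0, n_parameters=3)
        assert m.aic == 26.0
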