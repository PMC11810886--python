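"""Descriptive statistics, gradient verification and the yield regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from stcr import (
    CollinearPredictorError,
    fit_yield_model,
    summarize_strips,
    verify_gradient,
)
from stcr.schema import YIELD_MODEL_PREDICTORS

#: published overall-strip yield regression used for exact-recovery checks
OVERALL_YIELD_MODEL = {
    "intercept": -211.45,
    "u_n": 0.932, "u_p": 1.171, "u_k": 0.643,
    "s_n": -0.892, "s_p": 0.582, "s_k": 0.816,
    "f_n": 0.679, "f_p2o5": 0.183, "f_k2o": 0.168,
    "fym_t_ha": 3.026,
}


def _table(strip, values, var="x"):
    return pd.DataFrame({"strip": strip, var: values})


class TestSummaries:
    def test_hand_computed_example(self):
        out = summarize_strips(_table([1, 1, 1], [1.0, 2.0, 3.0]), ["x"])
        row = out.iloc[0]
        assert row["mean"] == 2.0
        assert row["sd"] == pytest.approx(1.0)
        assert row["cv_pct"] == pytest.approx(50.0)
        assert row["median"] == 2.0
        assert row["min"] == 1.0 and row["max"] == 3.0

    def test_constant_values(self):
        out = summarize_strips(_table([1] * 24, [5.0] * 24), ["x"])
        row = out.iloc[0]
        assert row["sd"] == 0.0 and row["cv_pct"] == 0.0 and row["median"] == 5.0

    def test_single_observation_flagged_not_zero(self):
        out = summarize_strips(_table([1], [4.2]), ["x"])
        row = out.iloc[0]
        assert not row["sd_defined"]
        assert np.isnan(row["sd"]) and np.isnan(row["cv_pct"])

    def test_cv_definition(self):
        # two points with mean 409 and sample SD 11.10 give CV 2.71%
        half = 11.10 / np.sqrt(2.0)
        out = summarize_strips(_table([1, 1], [409 - half, 409 + half]), ["x"])
        assert out.iloc[0]["cv_pct"] == pytest.approx(100 * 11.10 / 409, abs=1e-9)
        assert out.iloc[0]["cv_pct"] == pytest.approx(2.71, abs=0.005)

    def test_missing_variable_named(self, noisy_plots):
        with pytest.raises(KeyError, match="nope"):
            summarize_strips(noisy_plots, ["nope"])

    @given(
        data=hst.lists(
            hst.tuples(
                hst.integers(1, 3),
                hst.floats(0.1, 1e4, allow_nan=False, allow_infinity=False),
            ),
            min_size=2,
            max_size=200,
        )
    )
    def test_matches_bruteforce_oracle(self, data):
        """Summaries agree with a sorting-based median and two-pass SD."""
        df = pd.DataFrame(data, columns=["strip", "x"])
        out = summarize_strips(df, ["x"])
        for _, row in out.iterrows():
            x = sorted(df[df["strip"] == row["strip"]]["x"])
            n = len(x)
            mean = sum(x) / n
            median = x[n // 2] if n % 2 else (x[n // 2 - 1] + x[n // 2]) / 2
            assert row["mean"] == pytest.approx(mean, rel=1e-12)
            assert row["median"] == pytest.approx(median, rel=1e-12)
            if n >= 2:
                sd = (sum((v - mean) ** 2 for v in x) / (n - 1)) ** 0.5
                assert row["sd"] == pytest.approx(sd, rel=1e-9, abs=1e-12)


class TestGradient:
    def _summaries(self, means, var="s_n"):
        rows = []
        for strip, m in enumerate(means, start=1):
            rows.append({"strip": strip, "variable": var, "mean": m})
        return pd.DataFrame(rows)

    @pytest.mark.parametrize(
        "means,expected",
        [
            ((409.0, 432.0, 467.0), True),   # available N strip means
            ((12.0, 24.0, 28.0), True),      # biomass yield t/ha
            ((410.0, 410.0, 467.0), False),  # tie fails
            ((467.0, 432.0, 409.0), False),
        ],
    )
    def test_strictly_increasing_means(self, means, expected):
        report = verify_gradient(self._summaries(means), ["s_n"])
        assert bool(report.iloc[0]["passed"]) is expected

    def test_order_sensitivity_under_label_permutation(self):
        passing = self._summaries((409.0, 432.0, 467.0))
        permuted = passing.copy()
        permuted["strip"] = [2, 1, 3]
        assert bool(verify_gradient(passing, ["s_n"]).iloc[0]["passed"])
        assert not bool(verify_gradient(permuted, ["s_n"]).iloc[0]["passed"])

    def test_missing_variable_named(self):
        with pytest.raises(KeyError, match="s_k"):
            verify_gradient(self._summaries((1.0, 2.0, 3.0)), ["s_k"])

    def test_needs_two_strips(self):
        one = pd.DataFrame([{"strip": 1, "variable": "s_n", "mean": 1.0}])
        with pytest.raises(ValueError, match="two strips"):
            verify_gradient(one, ["s_n"])


class TestYieldModel:
    def _deterministic_yield(self, plots):
        y = np.full(len(plots), OVERALL_YIELD_MODEL["intercept"])
        for col in YIELD_MODEL_PREDICTORS:
            y = y + OVERALL_YIELD_MODEL[col] * plots[col].to_numpy()
        return y

    def test_exact_coefficient_recovery(self, noisy_plots):
        """Data generated from known linear coefficients with no noise is
        recovered to machine-level precision with R^2 = 1."""
        plots = noisy_plots.copy()
        plots["yield_kg_ha"] = self._deterministic_yield(plots)
        fit = fit_yield_model(plots)
        assert fit.intercept == pytest.approx(OVERALL_YIELD_MODEL["intercept"], abs=1e-6)
        for col in YIELD_MODEL_PREDICTORS:
            assert fit.coefficients[col] == pytest.approx(OVERALL_YIELD_MODEL[col], abs=1e-6)
        assert fit.r_squared >= 1 - 1e-9

    def test_zero_response_gives_zero_fit(self, noisy_plots):
        plots = noisy_plots.copy()
        plots["yield_kg_ha"] = 0.0
        fit = fit_yield_model(plots)
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)
        assert all(abs(b) < 1e-8 for b in fit.coefficients.values())

    def test_high_r2_on_synthetic_trial(self, noisy_plots):
        assert fit_yield_model(noisy_plots).r_squared >= 0.90

    def test_prediction_at_means_equals_mean_response(self, noisy_plots):
        fit = fit_yield_model(noisy_plots)
        at_means = fit.intercept + sum(
            fit.coefficients[c] * noisy_plots[c].mean() for c in YIELD_MODEL_PREDICTORS
        )
        assert at_means == pytest.approx(noisy_plots["yield_kg_ha"].mean(), rel=1e-10)

    def test_residuals_orthogonal_to_predictors(self, noisy_plots):
        fit = fit_yield_model(noisy_plots)
        r = fit.residuals / np.linalg.norm(fit.residuals)
        for col in YIELD_MODEL_PREDICTORS:
            x = noisy_plots[col].to_numpy(dtype=float)
            z = (x - x.mean()) / x.std()
            assert abs(float(z @ r)) / len(z) <= 1e-8

    def test_constant_predictor_named(self, noisy_plots):
        plots = noisy_plots.copy()
        plots["fym_t_ha"] = 6.25
        with pytest.raises(CollinearPredictorError, match="fym_t_ha"):
            fit_yield_model(plots)

    def test_collinear_predictor_named(self, noisy_plots):
        plots = noisy_plots.copy()
        plots["u_k"] = 2.0 * plots["u_n"]
        with pytest.raises(CollinearPredictorError, match="u_k"):
            fit_yield_model(plots)

    def test_too_few_plots_rejected(self, noisy_plots):
        with pytest.raises(ValueError, match="at least"):
            fit_yield_model(noisy_plots.head(10))
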