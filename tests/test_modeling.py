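"""Logistic modelling: closed-form checks, McFadden R² oracle, reduction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grscohort.modeling import (
    classification_accuracy,
    fit_logistic,
    mcfadden_r2,
    predicted_probabilities,
    reduced_model,
    scaled_or,
)


def two_by_two_data(n11, n10, n01, n00):
    """Exposure x outcome counts -> (design, outcome).

    n11: exposed cases, n10: exposed controls, n01: unexposed cases,
    n00: unexposed controls.
    """
    x = [1.0] * (n11 + n10) + [0.0] * (n01 + n00)
    y = [1.0] * n11 + [0.0] * n10 + [1.0] * n01 + [0.0] * n00
    idx = [f"s{i}" for i in range(len(x))]
    return pd.DataFrame({"exposed": x}, index=idx), pd.Series(y, index=idx)


class TestFitLogistic:
    def test_single_binary_predictor_closed_form(self):
        design, y = two_by_two_data(30, 10, 10, 30)
        fit = fit_logistic(design, y)
        assert fit.converged
        assert fit.beta["exposed"] == pytest.approx(math.log(9), abs=1e-6)
        assert fit.odds_ratio("exposed") == pytest.approx(9.0, rel=1e-5)

    def test_null_data_gives_near_zero_slopes(self):
        rng = np.random.default_rng(6)
        n = 4000
        design = pd.DataFrame(
            {"x1": rng.normal(size=n), "x2": (rng.random(n) < 0.4).astype(float)}
        )
        y = pd.Series((rng.random(n) < 0.5).astype(float))
        fit = fit_logistic(design, y)
        assert all(abs(fit.beta[t]) < 0.1 for t in fit.terms)
        assert fit.ll_model == pytest.approx(fit.ll_null, abs=2.0)

    def test_perfect_separation_flagged_not_silent(self):
        x = pd.DataFrame({"x": [0.0, 0.1, 0.2, 0.8, 0.9, 1.0]})
        y = pd.Series([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        fit = fit_logistic(x, y)
        assert not fit.converged
        assert "separation" in fit.diagnostic
        assert fit.beta.isna().all()

    def test_constant_predictor_dropped_with_warning(self):
        design, y = two_by_two_data(20, 10, 10, 20)
        design["always_one"] = 1.0
        with pytest.warns(UserWarning, match="always_one"):
            fit = fit_logistic(design, y)
        assert fit.terms == ["exposed"]
        assert fit.dropped_terms == ["always_one"]

    def test_missing_rows_dropped_and_counted(self):
        design, y = two_by_two_data(20, 10, 10, 20)
        design.iloc[0, 0] = np.nan
        fit = fit_logistic(design, y)
        assert fit.n_dropped_rows == 1
        assert fit.n_obs == len(y) - 1

    @given(st.tuples(*[st.integers(min_value=1, max_value=50)] * 4))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_slope_equals_log_cross_product_ratio(self, cells):
        """For one binary predictor the MLE slope is the 2x2 log odds ratio."""
        n11, n10, n01, n00 = cells
        design, y = two_by_two_data(n11, n10, n01, n00)
        fit = fit_logistic(design, y)
        expected = math.log((n11 * n00) / (n10 * n01))
        assert fit.beta["exposed"] == pytest.approx(expected, abs=1e-6)

    def test_extra_irrelevant_predictor_never_lowers_likelihood(self):
        rng = np.random.default_rng(9)
        n = 300
        x = rng.normal(size=n)
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-x))).astype(float))
        base = fit_logistic(pd.DataFrame({"x": x}), y)
        noisy = fit_logistic(pd.DataFrame({"x": x, "junk": rng.normal(size=n)}), y)
        assert noisy.ll_model >= base.ll_model - 1e-8


class TestMcFaddenR2:
    def test_intercept_only_is_zero(self):
        y = pd.Series([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        fit = fit_logistic(pd.DataFrame(index=y.index), y)
        assert mcfadden_r2(fit) == 0.0

    def test_hand_evaluated_two_by_two(self):
        design, y = two_by_two_data(30, 10, 10, 30)
        fit = fit_logistic(design, y)
        lm = 60 * math.log(0.75) + 20 * math.log(0.25)
        l0 = 80 * math.log(0.5)
        assert fit.ll_model == pytest.approx(lm, abs=1e-6)
        assert fit.ll_null == pytest.approx(l0, abs=1e-12)
        assert mcfadden_r2(fit) == pytest.approx(1 - lm / l0, abs=1e-8)
        assert mcfadden_r2(fit) == pytest.approx(0.1887, abs=5e-4)

    def test_matches_per_sample_likelihood_oracle(self):
        """R² recomputed from the fitted probabilities, sample by sample."""
        rng = np.random.default_rng(13)
        n = 500
        design = pd.DataFrame({"x": rng.normal(size=n), "z": rng.normal(size=n)})
        lp = 0.8 * design["x"] - 0.3 * design["z"]
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float))
        fit = fit_logistic(design, y)
        p = fit.fitted_prob
        ll_m = float((y * np.log(p) + (1 - y) * np.log(1 - p)).sum())
        pbar = y.mean()
        ll_0 = float(len(y) * (pbar * math.log(pbar) + (1 - pbar) * math.log(1 - pbar)))
        assert mcfadden_r2(fit) == pytest.approx(1 - ll_m / ll_0, abs=1e-9)
        assert 0 <= mcfadden_r2(fit) < 1


class TestScaledOR:
    def test_zero_beta(self):
        design, y = two_by_two_data(10, 10, 10, 10)
        fit = fit_logistic(design, y)
        assert scaled_or(fit, "exposed", 0.1)[0] == pytest.approx(1.0, abs=1e-6)

    def test_tenth_unit_or(self):
        design, y = two_by_two_data(30, 10, 10, 30)
        fit = fit_logistic(design, y)  # beta = ln 9 = 2.1972
        or01, (lo, hi) = scaled_or(fit, "exposed", 0.1)
        assert or01 == pytest.approx(math.exp(0.21972), abs=1e-4)
        assert or01 == pytest.approx(1.2457, abs=1e-3)
        assert lo < or01 < hi

    def test_delta_one_recovers_unscaled_or(self):
        design, y = two_by_two_data(30, 10, 10, 30)
        fit = fit_logistic(design, y)
        assert scaled_or(fit, "exposed", 1.0)[0] == pytest.approx(
            fit.odds_ratio("exposed"), rel=1e-12
        )

    def test_unknown_term_errors(self):
        design, y = two_by_two_data(10, 10, 10, 10)
        with pytest.raises(KeyError):
            scaled_or(fit_logistic(design, y), "nope")


class TestClassificationAccuracy:
    def _fit(self):
        design, y = two_by_two_data(30, 10, 10, 30)
        return fit_logistic(design, y)

    def test_explicit_probability_examples(self):
        fit = self._fit()
        design = pd.DataFrame({"exposed": [1.0, 0.0]}, index=["a", "b"])
        # fitted probs are 0.75 (exposed) and 0.25 (unexposed)
        assert classification_accuracy(fit, design, pd.Series([1.0, 0.0], index=["a", "b"])) == 1.0
        assert classification_accuracy(fit, design, pd.Series([1.0, 1.0], index=["a", "b"])) == 0.5

    def test_resubstitution_default(self):
        fit = self._fit()
        assert classification_accuracy(fit) == pytest.approx(0.75)

    def test_tie_at_threshold_classified_as_case(self):
        fit = self._fit()
        design = pd.DataFrame({"exposed": [1.0]}, index=["a"])
        prob = predicted_probabilities(fit, design).iloc[0]
        acc_case = classification_accuracy(
            fit, design, pd.Series([1.0], index=["a"]), threshold=prob
        )
        assert acc_case == 1.0  # probability exactly at threshold -> case


class TestReducedModel:
    def test_dominant_term_retained(self):
        rng = np.random.default_rng(21)
        n = 600
        strong = (rng.random(n) < 0.5).astype(float)
        noise = rng.normal(size=n)
        lp = -1 + 2.5 * strong
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float))
        fit = fit_logistic(pd.DataFrame({"strong": strong, "noise": noise}), y)
        red = reduced_model(fit)
        assert "strong" in red.terms

    def test_reduced_r2_never_exceeds_full(self):
        rng = np.random.default_rng(22)
        n = 500
        design = pd.DataFrame(
            {
                "a": rng.normal(size=n),
                "b": rng.normal(size=n),
                "c": (rng.random(n) < 0.3).astype(float),
            }
        )
        lp = 0.9 * design["a"]
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float))
        full = fit_logistic(design, y)
        red = reduced_model(full)
        assert mcfadden_r2(red) <= mcfadden_r2(full) + 1e-12

    def test_recovery_of_true_effects_across_seeds(self):
        """Backward selection keeps the three real effects in every seed and
        recovers exactly the true set in most; the two null candidates are
        each falsely retained at the nominal ~5% rate."""
        true_set = {"sex_male", "mi", "grs"}
        exact = 0
        all_true_kept = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 1500
            sex = (rng.random(n) < 0.5).astype(float)
            mi = (rng.random(n) < 0.3).astype(float)
            grs = rng.normal(0.7, 0.25, n)
            age = rng.normal(70, 10, n)
            smoker = (rng.random(n) < 0.45).astype(float)
            lp = -2.5 + math.log(3) * sex + math.log(3) * mi + 3.0 * (grs - 0.7)
            y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float))
            design = pd.DataFrame(
                {"sex_male": sex, "mi": mi, "grs": grs, "age": age, "ever_smoker": smoker}
            )
            red = reduced_model(fit_logistic(design, y))
            kept = set(red.terms)
            all_true_kept += true_set <= kept
            exact += kept == true_set
        assert all_true_kept == 20
        assert exact >= 16
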