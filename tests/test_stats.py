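"""Normality gate, group tests with FDR, correlations, and regression
fit diagnostics checked against explicit arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from switchnet.stats import (correlate, demographics_table,
                             fit_prediction_models, group_compare,
                             normality_gate, regression_table)


def _cohort_frame(rng, n=20, metric_shift=0.0):
    rows = []
    for group, shift in (("control", 0.0), ("patient", metric_shift)):
        for i in range(n):
            rows.append({
                "subject_id": f"{group}{i}", "group": group,
                "age": rng.normal(57, 9),
                "sex": "male" if rng.random() < 0.5 else "female",
                "metric": rng.normal(0.1 + shift, 0.02),
                "baseline_score": rng.normal(16, 5) if group == "patient" else np.nan,
                "change_score": rng.normal(26, 9) if group == "patient" else np.nan,
            })
    return pd.DataFrame(rows)


class TestNormalityGate:
    def test_gaussian_samples_choose_t(self, rng):
        chosen_t = sum(
            normality_gate(rng.normal(size=40), rng.normal(size=40)) == "t"
            for _ in range(50))
        assert chosen_t >= 45

    def test_skewed_samples_prefer_mann_whitney(self, rng):
        chosen_mw = sum(
            normality_gate(rng.exponential(size=20) ** 2,
                           rng.exponential(size=20) ** 2) == "mann_whitney"
            for _ in range(50))
        assert chosen_mw > 25

    def test_constant_sample_forces_nonparametric(self):
        assert normality_gate(np.ones(10), np.arange(10.0)) == "mann_whitney"

    def test_tiny_group_forces_nonparametric(self):
        assert normality_gate(np.array([1.0, 2.0]),
                              np.arange(10.0)) == "mann_whitney"


class TestGroupCompare:
    def test_single_metric_fdr_equals_raw(self, rng):
        table = group_compare(_cohort_frame(rng), ["metric"], family="node")
        assert table["p_fdr"].iloc[0] == table["p_raw"].iloc[0]

    def test_planted_shift_detected_with_direction(self, rng):
        table = group_compare(_cohort_frame(rng, metric_shift=0.08),
                              ["metric"], family="global")
        assert table["p_raw"].iloc[0] < 0.001
        assert table["direction"].iloc[0] == "patient>control"

    def test_fdr_not_below_raw(self, rng):
        frame = _cohort_frame(rng)
        for k in range(6):
            frame[f"m{k}"] = rng.normal(size=len(frame))
        table = group_compare(frame, [f"m{k}" for k in range(6)], family="node")
        assert (table["p_fdr"] >= table["p_raw"] - 1e-15).all()
        assert table["p_fdr"].between(0, 1).all()

    @settings(max_examples=25, deadline=None)
    @given(st.permutations(list(range(6))))
    def test_fdr_invariant_to_metric_order(self, order):
        rng = np.random.default_rng(5)
        frame = _cohort_frame(rng)
        for k in range(6):
            frame[f"m{k}"] = np.random.default_rng(k).normal(size=len(frame))
        cols = [f"m{k}" for k in range(6)]
        base = group_compare(frame, cols, family="node").set_index("metric")
        perm = group_compare(frame, [cols[i] for i in order],
                             family="node").set_index("metric")
        for col in cols:
            assert perm.loc[col, "p_fdr"] == pytest.approx(
                base.loc[col, "p_fdr"], abs=1e-12)


class TestCorrelate:
    def test_exact_affine_relation_r_one(self, rng):
        frame = _cohort_frame(rng)
        frame["change_score"] = np.where(frame["group"] == "patient",
                                         3 + 2 * frame["metric"], np.nan)
        r, p, n = correlate(frame, "metric", "change_score")
        assert r == pytest.approx(1.0)
        assert n == 20

    def test_too_few_subjects_rejected(self, rng):
        frame = _cohort_frame(rng, n=3)
        with pytest.raises(ValueError, match="at least 4"):
            correlate(frame, "metric", "change_score")

    def test_spearman_flag(self, rng):
        frame = _cohort_frame(rng)
        r, p, _ = correlate(frame, "metric", "change_score",
                            method="spearman")
        assert -1 <= r <= 1


class TestRegression:
    def test_four_point_exact_line(self):
        frame = pd.DataFrame({
            "group": ["patient"] * 4,
            "x": [1.0, 2.0, 3.0, 4.0],
            "y": [2.0, 4.0, 6.0, 8.0],
        })
        fit = fit_prediction_models(frame, response="y", predictors=("x",))[0]
        assert fit.coef == pytest.approx(2.0, abs=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)

    def test_fit_matches_explicit_rss_arithmetic(self, rng):
        # independent oracle: closed-form simple-regression algebra with
        # no fitting library
        frame = _cohort_frame(rng)
        fit = fit_prediction_models(frame, response="change_score",
                                    predictors=("baseline_score",))[0]
        sub = frame.dropna(subset=["change_score", "baseline_score"])
        x = sub["baseline_score"].to_numpy()
        y = sub["change_score"].to_numpy()
        n = len(x)
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - intercept - slope * x
        rss = (resid ** 2).sum()
        tss = ((y - y.mean()) ** 2).sum()
        assert fit.coef == pytest.approx(slope, abs=1e-8)
        assert fit.r_squared == pytest.approx(1 - rss / tss, abs=1e-8)
        assert fit.rmse == pytest.approx(np.sqrt(rss / n), abs=1e-8)
        assert fit.aic == pytest.approx(n * np.log(rss / n) + 4, abs=1e-8)

    def test_beta_squared_equals_r_squared(self, rng):
        frame = _cohort_frame(rng)
        fit = fit_prediction_models(frame, response="change_score",
                                    predictors=("baseline_score",))[0]
        assert fit.beta ** 2 == pytest.approx(fit.r_squared, abs=1e-10)

    def test_constant_predictor_rejected(self, rng):
        frame = _cohort_frame(rng)
        frame["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_prediction_models(frame, response="change_score",
                                  predictors=("flat",))

    def test_table_layout(self, rng):
        frame = _cohort_frame(rng)
        frame["global_rate"] = np.random.default_rng(0).random(len(frame))
        fits = fit_prediction_models(frame)
        table = regression_table(fits)
        assert list(table.columns) == ["model", "variable", "B", "beta", "p",
                                       "R2", "RMSE", "AIC", "n"]
        assert len(table) == 2


def test_demographics_report(rng):
    table = demographics_table(_cohort_frame(rng))
    assert set(table["characteristic"]) == {"age", "sex"}
    assert table["p"].between(0, 1).all()
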