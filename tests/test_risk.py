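"""Odds ratios, logistic regression (IRLS) and the Hosmer-Lemeshow test."""

import math

import numpy as np
import pandas as pd
import pytest

from pvsignal.risk import (
    SeparationError,
    build_case_control,
    fit_logistic,
    hosmer_lemeshow,
    odds_ratio_2x2,
    risk_factor_table,
)
from conftest import small_clean_set


class TestOddsRatio2x2:
    def test_symmetric_table(self):
        est, lo, hi = odds_ratio_2x2(5, 5, 5, 5)
        assert est == pytest.approx(1.0)
        assert lo * hi == pytest.approx(1.0, rel=1e-12)  # CI symmetric about 1

    def test_zero_cell_undefined(self):
        assert all(math.isnan(v) for v in odds_ratio_2x2(0, 5, 5, 5))

    def test_known_value(self):
        est, _, _ = odds_ratio_2x2(10, 90, 100, 9000)
        assert est == pytest.approx(10.0)


def table5_like_rows(n11, n10, n01, n00):
    """Case-control rows realizing a given exposed/unexposed 2x2 table."""
    return pd.DataFrame(
        {
            "exposed": [1] * n11 + [0] * n10 + [1] * n01 + [0] * n00,
            "outcome": [1] * (n11 + n10) + [0] * (n01 + n00),
        }
    )


class TestLogisticFit:
    def test_single_binary_covariate_matches_closed_form_or(self):
        rows = table5_like_rows(60, 45, 3377, 4900)
        fit = fit_logistic(rows, ["exposed"])
        closed, _, _ = odds_ratio_2x2(60, 45, 3377, 4900)
        assert abs(float(np.exp(fit.params["exposed"])) - closed) < 1e-6
        # identical Wald standard errors too
        assert float(fit.bse["exposed"]) == pytest.approx(
            math.sqrt(1 / 60 + 1 / 45 + 1 / 3377 + 1 / 4900), abs=1e-8
        )

    def test_intercept_only_recovers_prevalence(self):
        rows = pd.DataFrame({"outcome": [1] * 30 + [0] * 70})
        fit = fit_logistic(rows, [])
        p = 1 / (1 + np.exp(-fit.params["intercept"]))
        assert p == pytest.approx(0.30, abs=1e-8)

    def test_matches_statsmodels_on_multivariate_fit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        n = 5000
        X = pd.DataFrame(
            {
                "female": rng.integers(0, 2, n),
                "age_19_64": rng.integers(0, 2, n),
                "x": rng.normal(size=n),
            }
        )
        lin = -1.5 + 0.6 * X["female"] - 0.3 * X["age_19_64"] + 0.4 * X["x"]
        y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
        rows = X.copy()
        rows["outcome"] = y
        fit = fit_logistic(rows, ["female", "age_19_64", "x"])
        sm_fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(fit.params.values, sm_fit.params.values, atol=1e-6)
        np.testing.assert_allclose(fit.bse.values, sm_fit.bse.values, atol=1e-6)

    def test_parameter_recovery_within_3_se(self):
        rng = np.random.default_rng(17)
        n = 20_000
        beta_true = {"intercept": -3.0, "female": 0.65, "age_65_plus": 0.25}
        X = pd.DataFrame(
            {"female": rng.integers(0, 2, n), "age_65_plus": rng.integers(0, 2, n)}
        )
        lin = beta_true["intercept"] + X.values @ np.array([beta_true["female"], beta_true["age_65_plus"]])
        rows = X.copy()
        rows["outcome"] = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
        fit = fit_logistic(rows, ["female", "age_65_plus"])
        for term, truth in beta_true.items():
            assert abs(fit.params[term] - truth) < 3 * fit.bse[term]

    def test_convergence_metadata_reported(self):
        rows = table5_like_rows(20, 30, 200, 300)
        fit = fit_logistic(rows, ["exposed"])
        assert fit.converged and fit.max_score < 1e-8 and fit.n_iter <= 50

    def test_complete_separation_detected(self):
        rows = pd.DataFrame({"x": [0, 0, 0, 1, 1, 1], "outcome": [0, 0, 0, 1, 1, 1]})
        with pytest.raises(SeparationError):
            fit_logistic(rows, ["x"])

    def test_rank_deficient_design_rejected(self):
        rows = pd.DataFrame({"x": [1, 1, 1, 1], "outcome": [0, 1, 0, 1]})
        with pytest.raises(ValueError, match="rank"):
            fit_logistic(rows, ["x"])  # x constant -> collinear with intercept

    def test_all_events_rejected(self):
        rows = pd.DataFrame({"x": [0, 1], "outcome": [1, 1]})
        with pytest.raises(ValueError):
            fit_logistic(rows, ["x"])


class TestHosmerLemeshow:
    def test_exact_fit_gives_zero_statistic(self):
        # 10 groups of 20 with integer expected counts realized exactly
        fitted = np.repeat(np.arange(2, 12) / 20.0, 20)
        y = np.concatenate([[1] * int(20 * p) + [0] * (20 - int(20 * p)) for p in np.arange(2, 12) / 20.0])
        hl = hosmer_lemeshow(fitted, y)
        assert hl.statistic == pytest.approx(0.0, abs=1e-12)
        assert hl.df == len(hl.groups) - 2

    def test_groups_partition_the_sample(self):
        rng = np.random.default_rng(2)
        fitted = rng.random(500)
        y = (rng.random(500) < fitted).astype(float)
        hl = hosmer_lemeshow(fitted, y)
        assert int(hl.groups["n"].sum()) == 500

    def test_too_few_distinct_groups_rejected(self):
        fitted = np.full(100, 0.3)
        y = np.zeros(100)
        y[:30] = 1
        with pytest.raises(ValueError, match="distinct"):
            hosmer_lemeshow(fitted, y)


class TestCaseControlConstruction:
    def test_restricts_to_known_sex_and_age(self):
        clean = small_clean_set(
            demo_rows=[
                {"report_id": "1", "case_id": "c1", "sex": "F", "age_years": 30.0, "age_group": "19-64"},
                {"report_id": "2", "case_id": "c2", "sex": "", "age_years": 30.0, "age_group": "19-64"},
                {"report_id": "3", "case_id": "c3", "sex": "M", "age_years": float("nan"), "age_group": "unknown"},
                {"report_id": "4", "case_id": "c4", "sex": "M", "age_years": 70.0, "age_group": ">=65"},
            ],
            drug_rows=[(str(i), "Zosyn", "PS") for i in range(1, 5)],
            reac_rows=[("1", "hypokalaemia"), ("2", "nausea"), ("3", "nausea"), ("4", "rash")],
        )
        import pvsignal as pv

        pairs = pv.build_pairs(clean, pv.load_drug_dictionary())
        rows = build_case_control(clean, pairs, "piperacillin\\tazobactam", {"hypokalaemia"})
        assert len(rows) == 2  # reports 2 and 3 lack sex/age
        assert rows.set_index("report_id").loc["1", "outcome"] == 1
        assert rows.set_index("report_id").loc["4", "outcome"] == 0

    def test_risk_factor_table_produces_or_per_term(self):
        rng = np.random.default_rng(5)
        n = 4000
        rows = pd.DataFrame(
            {
                "female": rng.integers(0, 2, n),
                "age_19_64": rng.integers(0, 2, n),
                "age_65_plus": 0,
            }
        )
        rows["age_65_plus"] = ((rows["age_19_64"] == 0) & (rng.random(n) < 0.5)).astype(int)
        lin = -2.5 + 0.7 * rows["female"]
        rows["outcome"] = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
        table, hl = risk_factor_table(rows)
        assert set(table["term"]) == {"female", "age_19_64", "age_65_plus"}
        assert (table["uni_or_low"] <= table["uni_or"]).all()
        assert (table["uni_or"] <= table["uni_or_high"]).all()
        assert 0 <= hl.pvalue <= 1
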