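"""Covariate regression: percent-change transform, VIF, normality, recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liverpfas.mlr import (
    PREDICTORS,
    beta_to_percent_change,
    fit_mlr,
    percent_change_to_beta,
    residual_normality,
    select_analytes,
    vif,
)
from liverpfas.synth import AnalyteSim, default_params, generate_cohort, generate_true_concentrations
from liverpfas.dataset import table_from_truth


class TestPercentChangeTransform:
    def test_zero_beta_zero_percent(self):
        assert beta_to_percent_change(0.0, "continuous") == 0.0
        assert beta_to_percent_change(0.0, "binary") == 0.0

    def test_closed_form_values(self):
        # -0.025/yr scaled per decade: (10^-0.25 - 1)*100
        assert beta_to_percent_change(-0.025, "continuous") == pytest.approx(
            (10**-0.25 - 1) * 100, abs=1e-10
        )
        assert beta_to_percent_change(-0.025, "continuous") == pytest.approx(-43.7658674, abs=1e-6)
        # +0.0792 per category: about +20%
        assert beta_to_percent_change(0.0792, "binary") == pytest.approx(20.0045, abs=1e-3)

    def test_sign_preserved(self):
        for b in (-0.3, -0.01, 0.01, 0.3):
            for kind in ("continuous", "binary"):
                assert np.sign(beta_to_percent_change(b, kind)) == np.sign(b)

    @settings(derandomize=True, max_examples=100)
    @given(
        beta=st.floats(-0.5, 0.5, allow_nan=False),
        kind=st.sampled_from(["continuous", "binary"]),
    )
    def test_bijective_round_trip(self, beta, kind):
        pct = beta_to_percent_change(beta, kind)
        assert percent_change_to_beta(pct, kind) == pytest.approx(beta, abs=1e-10)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            beta_to_percent_change(0.1, "ordinal")


class TestSelectAnalytes:
    def test_detection_threshold(self):
        from tests.test_dataset import make_table

        cells = []
        for i in range(40):
            cells.append((f"D{i:02d}", "common", 1.0, 0.1))
            cells.append((f"D{i:02d}", "rare", 1.0 if i < 29 else None, 0.1))
        t = make_table(cells)
        assert select_analytes(t, min_detects=30) == ["common", "sum"]
        assert select_analytes(t, min_detects=29) == ["common", "rare", "sum"]
        assert select_analytes(t, min_detects=0) == ["common", "rare", "sum"]


def _simulated_table(seed, n, sims):
    params = default_params(
        seed=seed, n_donors=n,
        frac_year_range=0.0, frac_year_missing=0.0,
        frac_health_missing=0.0, frac_age_missing=0.0,
    )
    params = dataclasses.replace(params, analytes=sims)
    cohort = generate_cohort(params)
    truth = generate_true_concentrations(cohort, params)
    return table_from_truth(truth, cohort)


class TestFitMLR:
    def test_coefficients_match_normal_equation_oracle(self):
        sims = {"X": AnalyteSim(0.3, -0.2, 0.05, 0.1, -0.15, sigma=0.4)}
        t = _simulated_table(5, 80, sims)
        fit = fit_mlr(t, "X")
        from liverpfas.mlr import build_design

        d = build_design(t, "X")
        X = np.column_stack([np.ones(len(d)), d[list(PREDICTORS)].to_numpy(float)])
        y = d["log10_conc"].to_numpy(float)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
        for i, p in enumerate(PREDICTORS, start=1):
            assert fit.coefficients[p] == pytest.approx(beta[i], abs=1e-8)

    def test_recovers_known_health_effect(self):
        # NAFLD effect -0.113 log10 units is about -23%
        sims = {"X": AnalyteSim(0.5, -0.1, 0.02, 0.0, -0.113, sigma=0.4)}
        t = _simulated_table(11, 400, sims)
        fit = fit_mlr(t, "X")
        b, se = fit.coefficients["health"], fit.standard_errors["health"]
        assert abs(b - (-0.113)) < 3 * se
        assert fit.percent_changes["health"] == pytest.approx((10**b - 1) * 100, abs=1e-9)

    def test_rank_deficiency_reported(self):
        sims = {"X": AnalyteSim(0.5, sigma=0.3)}
        t = _simulated_table(3, 60, sims)
        t.donors["health"] = np.where(t.donors["sex"] == "female", "NAFLD", "normal")  # duplicate predictor
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_mlr(t, "X")

    def test_sum_label_uses_substituted_sum(self, small_cohort_table):
        fit = fit_mlr(small_cohort_table, "sum")
        assert fit.n_obs > 0 and fit.analyte_name == "sum"
        assert set(fit.vif) == set(PREDICTORS)

    def test_complete_case_only(self):
        sims = {"X": AnalyteSim(0.5, sigma=0.3)}
        params = default_params(seed=9, n_donors=300)
        params = dataclasses.replace(params, analytes=sims)
        cohort = generate_cohort(params)
        truth = generate_true_concentrations(cohort, params)
        t = table_from_truth(truth, cohort)
        fit = fit_mlr(t, "X")
        n_complete = (
            t.donors[["age", "sex", "health", "year"]].notna().all(axis=1).sum()
        )
        assert fit.n_obs == n_complete < len(t.donors)


class TestVIF:
    def test_orthogonal_predictors_unit_vif(self):
        rng = np.random.default_rng(0)
        n = 4000
        d = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        out = vif(d)
        for v in out.values():
            assert v == pytest.approx(1.0, abs=0.01)

    def test_two_predictor_closed_form(self):
        # mutual R^2 of 0.43 gives VIF 1/(1-0.43) = 1.754 for both
        rng = np.random.default_rng(1)
        n = 200000
        x = rng.normal(size=n)
        rho2 = 0.43
        y = np.sqrt(rho2) * x + np.sqrt(1 - rho2) * rng.normal(size=n)
        out = vif(pd.DataFrame({"x": x, "y": y}))
        assert out["x"] == pytest.approx(1 / (1 - 0.43), rel=0.02)

    def test_duplicated_predictor_infinite(self):
        x = np.arange(10.0)
        out = vif(pd.DataFrame({"a": x, "b": x}))
        assert not np.isfinite(out["a"])

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        d = pd.DataFrame(rng.normal(size=(500, 3)), columns=["a", "b", "c"])
        d["b"] += 0.6 * d["a"]
        v1 = vif(d)
        d2 = d.copy()
        d2["a"] = 100.0 * d2["a"] - 7.0
        d2["b"] = 0.01 * d2["b"] + 3.0
        v2 = vif(d2)
        for k in v1:
            assert v1[k] == pytest.approx(v2[k], rel=1e-6)

    def test_year_health_vif_moderate_in_default_cohort(self, small_cohort_table):
        fit = fit_mlr(small_cohort_table, "sum")
        assert 1.0 < fit.vif["year"] < 5.0
        assert 1.0 < fit.vif["health"] < 5.0


class TestResidualNormality:
    def test_normal_residuals_pass(self):
        rng = np.random.default_rng(3)
        p = residual_normality(rng.normal(size=205))
        assert all(v > 0.05 for v in p.values())

    def test_heavy_tails_rejected(self):
        rng = np.random.default_rng(4)
        p = residual_normality(rng.standard_t(2, size=205))
        assert p["shapiro"] < 0.05

    def test_small_n_rules(self):
        p = residual_normality(np.array([0.1, -0.2, 0.3, -0.1, 0.05]))
        assert not np.isnan(p["shapiro"])
        assert np.isnan(p["dagostino"])  # needs n >= 20
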