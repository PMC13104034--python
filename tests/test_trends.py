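"""Weighted temporal trend model vs an independent normal-equation oracle."""

import numpy as np
import pandas as pd
import pytest

from liverpfas.trends import (
    fit_weighted_trend,
    geometric_mean_at,
    inverse_year_weights,
    per_analyte_trends,
    percent_reduction,
)


def wls_oracle(x, y, w):
    """Closed-form weighted least squares via the normal equations.

    Independent of the fitting route used by the package (no statsmodels).
    """
    W = np.diag(w)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    return beta  # (intercept, slope)


class TestWeights:
    def test_inverse_counts(self):
        w = inverse_year_weights([2000, 2000, 2010])
        np.testing.assert_allclose(w, [0.5, 0.5, 1.0])

    def test_year_total_weight_is_one(self):
        years = np.array([2000] * 7 + [2001] * 2 + [2005] * 4)
        w = inverse_year_weights(years)
        totals = pd.Series(w).groupby(pd.Series(years)).sum()
        np.testing.assert_allclose(totals, 1.0)


class TestFit:
    def test_hand_computed_slope(self):
        # weighted means (2005, 1.5); Sxy=-5, Sxx=50 -> slope -0.1/yr
        fit = fit_weighted_trend([100.0, 100.0, 10.0], [2000, 2000, 2010])
        assert fit.beta1 == pytest.approx(-0.1, abs=1e-12)

    def test_constant_values_flat(self):
        fit = fit_weighted_trend([5.0] * 9, [2000, 2000, 2005, 2005, 2005, 2010, 2010, 2012, 2020])
        assert fit.beta1 == pytest.approx(0.0, abs=1e-12)
        assert fit.p_value > 0.99

    def test_equal_counts_match_unweighted_ols(self):
        rng = np.random.default_rng(1)
        years = np.repeat(np.arange(2000, 2010), 3)
        vals = 10 ** (1.0 - 0.03 * (years - 2000) + rng.normal(0, 0.2, years.size))
        fit = fit_weighted_trend(vals, years)
        b0, b1 = np.polyfit(years, np.log10(vals), 1)[::-1]
        assert fit.beta1 == pytest.approx(b1, abs=1e-10)
        assert fit.beta0 == pytest.approx(b0, abs=1e-8)

    def test_matches_normal_equation_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(6, 50)
            years = rng.choice(np.arange(2000, 2025), size=n)
            while np.unique(years).size < 3:
                years = rng.choice(np.arange(2000, 2025), size=n)
            vals = 10 ** rng.normal(0.5, 0.7, size=n)
            fit = fit_weighted_trend(vals, years)
            b0, b1 = wls_oracle(years.astype(float), np.log10(vals), inverse_year_weights(years))
            assert fit.beta0 == pytest.approx(b0, abs=1e-8)
            assert fit.beta1 == pytest.approx(b1, abs=1e-8)

    def test_duplicating_a_year_leaves_estimates_unchanged(self):
        years = np.array([2000, 2001, 2003, 2010, 2015])
        vals = np.array([20.0, 15.0, 9.0, 4.0, 2.0])
        fit1 = fit_weighted_trend(vals, years)
        years2 = np.concatenate([years, [2003]])
        vals2 = np.concatenate([vals, [9.0]])
        fit2 = fit_weighted_trend(vals2, years2)
        assert fit2.beta1 == pytest.approx(fit1.beta1, abs=1e-12)
        assert fit2.beta0 == pytest.approx(fit1.beta0, abs=1e-9)

    def test_preconditions(self):
        with pytest.raises(ValueError, match="observations"):
            fit_weighted_trend([1.0, 2.0], [2000, 2001])
        with pytest.raises(ValueError, match="onpositive"):
            fit_weighted_trend([1.0, 0.0, 2.0], [2000, 2001, 2002])

    def test_slope_recovery_single_simulation(self):
        rng = np.random.default_rng(7)
        years = rng.choice(np.arange(2000, 2025), size=400)
        true = -0.022  # per year
        vals = 10 ** (1.2 + true * (years - 2000) + rng.normal(0, 0.4, 400))
        fit = fit_weighted_trend(vals, years)
        assert abs(fit.beta1 - true) < 3 * fit.se_beta1


class TestDerivedQuantities:
    def test_geometric_mean_log_linear_identity(self):
        fit = fit_weighted_trend([100.0, 100.0, 10.0], [2000, 2000, 2010])
        gm2000 = geometric_mean_at(fit, 2000)
        assert geometric_mean_at(fit, 2010) == pytest.approx(gm2000 / 10.0, rel=1e-9)

    def test_percent_reduction_closed_form(self):
        fit = fit_weighted_trend([100.0, 100.0, 10.0], [2000, 2000, 2010])
        # slope -0.1/yr over 10 years is a 90% decline
        assert percent_reduction(fit, 2000, 2010) == pytest.approx(90.0, abs=1e-9)

    def test_flat_trend_zero_reduction(self):
        fit = fit_weighted_trend([5.0] * 4, [2000, 2005, 2010, 2015])
        assert percent_reduction(fit, 2000, 2024) == pytest.approx(0.0, abs=1e-9)

    def test_reduction_invariant_under_rescaling(self):
        years = [2000, 2003, 2008, 2015, 2020]
        vals = np.array([30.0, 22.0, 11.0, 6.0, 2.5])
        a = percent_reduction(fit_weighted_trend(vals, years), 2000, 2020)
        b = percent_reduction(fit_weighted_trend(vals * 77.7, years), 2000, 2020)
        assert a == pytest.approx(b, rel=1e-12)

    def test_bad_year_order(self):
        fit = fit_weighted_trend([5.0] * 4, [2000, 2005, 2010, 2015])
        with pytest.raises(ValueError):
            percent_reduction(fit, 2010, 2010)


class TestPerAnalyte:
    def test_labels_match_simulated_signs(self, small_cohort_table):
        out = per_analyte_trends(small_cohort_table).set_index("analyte_name")
        # strong simulated decline is labeled, flat analytes are not
        assert out.loc["L-PFOS", "label"] == "decline"
        assert out.loc["L-PFOS", "beta1"] < 0

    def test_flat_analyte_type_i_control(self):
        # a no-trend analyte should be flagged in well under half of seeds
        rng_master = np.random.default_rng(123)
        flagged = 0
        n_rep = 40
        for _ in range(n_rep):
            rng = np.random.default_rng(rng_master.integers(2**31))
            years = rng.choice(np.arange(2000, 2025), size=150)
            vals = 10 ** rng.normal(0.0, 0.5, 150)
            fit = fit_weighted_trend(vals, years)
            flagged += fit.p_value < 0.05
        assert flagged <= 0.2 * n_rep

    def test_sparse_analyte_skipped(self):
        from tests.test_dataset import make_table

        # analyte B has detects in only two distinct years -> skipped
        donors = pd.DataFrame(
            {
                "donor_id": ["D1", "D2", "D3", "D4"],
                "age": 50.0,
                "sex": "male",
                "health": "normal",
                "year_min": [2000, 2005, 2010, 2015],
                "year_max": [2000, 2005, 2010, 2015],
            }
        )
        cells = [(d, "A", v, 0.01) for d, v in zip(donors.donor_id, [10.0, 6.0, 3.0, 1.0])]
        cells += [("D1", "B", 1.0, 0.01), ("D2", "B", 1.0, 0.01),
                  ("D3", "B", None, 0.01), ("D4", "B", None, 0.01)]
        t = make_table(cells, donors)
        out = per_analyte_trends(t)
        assert set(out["analyte_name"]) == {"A"}
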