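"""Isotope-dilution quantification and QA/QC acceptance rules."""

import math

import numpy as np
import pandas as pd
import pytest

from liverpfas.quant import (
    QuantError,
    apply_exclusions,
    blank_correct,
    compute_mdl,
    eis_recovery_check,
    fit_calibration,
    ion_abundance_ratio,
    quantify,
    rt_check,
)


class TestCalibration:
    def test_identity_line(self):
        levels = [(x, x) for x in (0.1, 0.25, 0.5, 1.0, 2.0)]
        c = fit_calibration("A", levels, idl=0.01)
        assert c.slope == pytest.approx(1.0, abs=1e-12)
        assert c.intercept == pytest.approx(0.0, abs=1e-12)

    def test_known_slope_intercept(self):
        levels = [(x, 2 * x + 0.1) for x in (0.1, 0.25, 0.5, 1.0, 2.0)]
        c = fit_calibration("A", levels, idl=0.01)
        assert c.slope == pytest.approx(2.0, abs=1e-10)
        assert c.intercept == pytest.approx(0.1, abs=1e-10)

    def test_too_few_levels(self):
        with pytest.raises(QuantError, match=">= 5"):
            fit_calibration("A", [(0.1, 0.1), (0.5, 0.5), (1, 1)], idl=0.01)

    def test_nonpositive_slope_refused(self):
        levels = [(x, -x) for x in (0.1, 0.25, 0.5, 1.0, 2.0)]
        with pytest.raises(QuantError, match="slope"):
            fit_calibration("A", levels, idl=0.01)

    def test_nonmonotone_flagged(self):
        levels = [(0.1, 0.1), (0.25, 0.5), (0.5, 0.3), (1.0, 1.0), (2.0, 2.0)]
        assert fit_calibration("A", levels, idl=0.01).monotone is False


class TestQuantify:
    @pytest.fixture
    def unit_curve(self):
        return fit_calibration("A", [(x, x) for x in (0.1, 0.25, 0.5, 1.0, 2.0)], idl=0.01)

    def test_worked_example(self, unit_curve):
        # area ratio 0.5, 4 ng spike, 0.5 g tissue -> 4 ng/g
        assert quantify(50.0, 100.0, unit_curve, eis_spike=4.0, sample_mass=0.5) == pytest.approx(4.0, rel=1e-10)

    def test_zero_area_is_zero_concentration(self, unit_curve):
        assert quantify(0.0, 100.0, unit_curve, 4.0, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_isotope_dilution_invariance(self, unit_curve):
        a = quantify(50.0, 100.0, unit_curve, 4.0, 0.5)
        b = quantify(25.0, 50.0, unit_curve, 4.0, 0.5)
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_eis_unquantifiable(self, unit_curve):
        assert math.isnan(quantify(50.0, 0.0, unit_curve, 4.0, 0.5))


class TestMDL:
    def test_mean_plus_three_sd(self):
        # sample SD of [0.10, 0.20, 0.30] is 0.10
        assert compute_mdl([0.10, 0.20, 0.30], idl=0.02) == pytest.approx(0.50, abs=1e-12)

    def test_idl_fallback_when_no_detects(self):
        assert compute_mdl([], idl=0.02) == 0.02
        assert compute_mdl([0.0, 0.0], idl=0.02) == 0.02

    def test_single_detect_falls_back_to_idl(self):
        assert compute_mdl([0.15], idl=0.02) == 0.02

    def test_identical_blanks_zero_sd(self):
        assert compute_mdl([0.2, 0.2, 0.2], idl=0.02) == pytest.approx(0.2)

    def test_sub_idl_blanks_are_not_detects(self):
        assert compute_mdl([0.001, 0.002, 0.003], idl=0.02) == 0.02

    def test_monotone_in_max_blank_and_spread(self):
        base = compute_mdl([0.1, 0.2, 0.3], idl=0.01)
        # raising the largest blank raises both mean and SD
        assert compute_mdl([0.1, 0.2, 0.4], idl=0.01) > base
        # widening the spread around the same mean raises the MDL
        assert compute_mdl([0.05, 0.2, 0.35], idl=0.01) > base


class TestBlankCorrection:
    def test_corrected_above_mdl(self):
        rec = blank_correct(1.0, blank_mean=0.2, mdl=0.5)
        assert rec.conc == pytest.approx(0.8) and not rec.censored and rec.blank_corrected

    def test_below_mdl_censored_without_correction(self):
        rec = blank_correct(0.4, blank_mean=0.2, mdl=0.5)
        assert rec.censored and rec.conc is None

    def test_zero_blank_mean_leaves_value(self):
        rec = blank_correct(1.0, blank_mean=0.0, mdl=0.5)
        assert rec.conc == pytest.approx(1.0) and not rec.blank_corrected

    def test_falls_below_mdl_after_subtraction(self):
        rec = blank_correct(0.6, blank_mean=0.3, mdl=0.5)
        assert rec.censored

    def test_never_negative(self):
        rec = blank_correct(0.6, blank_mean=5.0, mdl=0.5)
        assert rec.censored and rec.conc is None


class TestRTCheck:
    def test_same_structure_window(self):
        assert rt_check(5.05, 5.00, same_structure=True)
        assert not rt_check(5.15, 5.00, same_structure=True)

    def test_different_structure_with_ccv_shift(self):
        # delta 0.55, CCV shift 0.20 -> |0.35| <= 0.4 passes
        assert rt_check(5.55, 5.00, same_structure=False, ccv_mean_shift=0.20)
        # delta 0.70 -> |0.50| > 0.4 fails
        assert not rt_check(5.70, 5.00, same_structure=False, ccv_mean_shift=0.20)

    def test_missing_ccv_fails_safe(self):
        assert not rt_check(5.0, 5.0, same_structure=False, ccv_mean_shift=None)
        assert not rt_check(5.0, 5.0, same_structure=False, ccv_mean_shift=float("nan"))


class TestIonAbundanceRatio:
    def test_zero_at_ccv_mean(self):
        iar, ok = ion_abundance_ratio(0.5, 1.0, [0.5, 0.5])
        assert iar == pytest.approx(0.0, abs=1e-12) and ok

    def test_large_deviation_fails(self):
        iar, ok = ion_abundance_ratio(1.2, 1.0, [0.5])
        assert iar == pytest.approx(1.4) and not ok

    def test_boundary_minus_one_passes(self):
        iar, ok = ion_abundance_ratio(0.0, 1.0, [0.5])
        assert iar == pytest.approx(-1.0) and ok

    def test_zero_quant_area_fails(self):
        iar, ok = ion_abundance_ratio(0.5, 0.0, [0.5])
        assert math.isnan(iar) and not ok

    def test_ccv_mean_over_its_own_set_averages_zero(self):
        rng = np.random.default_rng(0)
        ratios = rng.uniform(0.3, 0.7, size=6)
        iars = [ion_abundance_ratio(r, 1.0, ratios)[0] for r in ratios]
        # normalized deviations of the CCVs against their own mean balance out
        assert np.mean(iars) == pytest.approx(0.0, abs=1e-12)

    def test_zero_ccv_ratio_is_error(self):
        with pytest.raises(QuantError):
            ion_abundance_ratio(0.5, 1.0, [0.0])


class TestRecovery:
    @pytest.mark.parametrize("rec,ok", [(1.00, True), (0.10, False), (1.50, True), (0.20, True), (1.51, False)])
    def test_limits_inclusive(self, rec, ok):
        r, passed = eis_recovery_check(rec * 100.0, 100.0)
        assert r == pytest.approx(rec) and passed is ok


class TestExclusions:
    @staticmethod
    def _qc(rows):
        return pd.DataFrame(rows, columns=["sample_id", "analyte_name", "rt_ok", "iar_ok", "recovery_ok", "detected"])

    def test_all_pass_no_exclusions(self):
        qc = self._qc([("S1", f"A{i}", True, True, True, True) for i in range(4)])
        out, samples = apply_exclusions(qc)
        assert not out["excluded"].any() and not samples["sample_excluded"].any()

    def test_sample_excluded_above_threshold(self):
        # 78% of analytes give no signal -> whole sample excluded at 0.75
        rows = [("S1", f"A{i}", True, True, True, i >= 39) for i in range(50)]
        out, samples = apply_exclusions(self._qc(rows), 0.75)
        assert samples.loc[samples["sample_id"] == "S1", "sample_excluded"].item()
        assert out["excluded"].all()

    def test_single_failing_record_only(self):
        rows = [("S1", "A1", False, True, True, True)] + [
            ("S1", f"A{i}", True, True, True, True) for i in range(2, 10)
        ]
        out, samples = apply_exclusions(self._qc(rows))
        assert not samples["sample_excluded"].any()
        assert out.loc[out["analyte_name"] == "A1", "excluded"].item()
        assert out["excluded"].sum() == 1

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        rows = [
            (f"S{s}", f"A{i}", bool(rng.random() > 0.1), True, True, bool(rng.random() > 0.5))
            for s in range(5)
            for i in range(12)
        ]
        qc = self._qc(rows)
        shuffled = qc.sample(frac=1.0, random_state=1).reset_index(drop=True)
        out1, s1 = apply_exclusions(qc)
        out2, s2 = apply_exclusions(shuffled)
        key = ["sample_id", "analyte_name"]
        merged = out1.set_index(key)[["excluded"]].join(
            out2.set_index(key)[["excluded"]], rsuffix="_b"
        )
        assert (merged["excluded"] == merged["excluded_b"]).all()
        pd.testing.assert_frame_equal(
            s1.sort_values("sample_id").reset_index(drop=True),
            s2.sort_values("sample_id").reset_index(drop=True),
        )
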