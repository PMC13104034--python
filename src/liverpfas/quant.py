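"""Isotope-dilution quantification and batch QA/QC.

Implements the acceptance rules of a performance-based targeted PFAS method
(EPA 1633-style): matrix-matched calibration in isotope-dilution ratio
space, method detection limits from procedural blanks with an instrumental
fallback, blank correction gated at the MDL, retention-time windows (0.1 min
for a structurally identical internal standard, 0.4 min with CCV shift
correction otherwise), the CCV-normalized ion-abundance ratio with inclusive
+/-1 bounds, internal-standard recovery limits, and sample/record exclusion
logic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import Panel

__all__ = [
    "CalibrationCurve",
    "QCRecord",
    "ConcentrationRecord",
    "QuantError",
    "fit_calibration",
    "quantify",
    "compute_mdl",
    "blank_correct",
    "rt_check",
    "ion_abundance_ratio",
    "eis_recovery_check",
    "apply_exclusions",
    "quantify_batch",
    "DEFAULT_RECOVERY_LIMITS",
    "DEFAULT_EXCLUSION_FRACTION",
    "RT_WINDOW_SAME",
    "RT_WINDOW_DIFFERENT",
]

logger = logging.getLogger(__name__)

RT_WINDOW_SAME = 0.1        # min, EIS is the labeled analogue of the analyte
RT_WINDOW_DIFFERENT = 0.4   # min, structurally different EIS, after CCV shift correction
DEFAULT_RECOVERY_LIMITS = (0.2, 1.5)
DEFAULT_EXCLUSION_FRACTION = 0.75


class QuantError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line through (amount ratio native/EIS, area ratio native/EIS)."""

    analyte_name: str
    slope: float
    intercept: float
    idl: float                      # ng/g; concentration at signal-to-noise 10
    levels: tuple[tuple[float, float], ...] = ()
    residuals: tuple[float, ...] = ()
    monotone: bool = True


@dataclass
class QCRecord:
    sample_id: str
    analyte_name: str
    rt_ok: bool = True
    iar: float = 0.0
    iar_ok: bool = True
    eis_recovery: float = 1.0
    recovery_ok: bool = True
    excluded: bool = False
    reason: str = ""


@dataclass
class ConcentrationRecord:
    """Blank-corrected concentration with censoring state and provenance."""

    sample_id: str
    analyte_name: str
    conc: float | None              # ng/g wet weight; None when censored ("ND")
    mdl: float
    censored: bool
    blank_corrected: bool
    qc: QCRecord | None = None


def fit_calibration(
    analyte_name: str,
    levels,
    idl: float,
    *,
    min_levels: int = 5,
) -> CalibrationCurve:
    """Fit the matrix-matched calibration line by ordinary least squares.

    ``levels`` is an iterable of (amount_ratio, area_ratio) pairs or a
    DataFrame with those columns.  Requires at least ``min_levels`` points
    and a positive slope; a non-monotone area response sets ``monotone=False``
    as an audit flag without refusing the fit.
    """
    if isinstance(levels, pd.DataFrame):
        pairs = list(zip(levels["amount_ratio"].astype(float), levels["area_ratio"].astype(float)))
    else:
        pairs = [(float(x), float(y)) for x, y in levels]
    if len(pairs) < min_levels:
        raise QuantError(
            f"{analyte_name}: calibration needs >= {min_levels} levels, got {len(pairs)}"
        )
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise QuantError(f"{analyte_name}: non-positive calibration slope {slope:.4g}")
    order = np.argsort(x)
    monotone = bool(np.all(np.diff(y[order]) >= 0))
    if not monotone:
        logger.warning("%s: non-monotone calibration response", analyte_name)
    resid = y - (slope * x + intercept)
    return CalibrationCurve(
        analyte_name=analyte_name,
        slope=float(slope),
        intercept=float(intercept),
        idl=float(idl),
        levels=tuple(pairs),
        residuals=tuple(float(r) for r in resid),
        monotone=monotone,
    )


def quantify(
    area_quant: float,
    area_eis: float,
    curve: CalibrationCurve,
    eis_spike: float,
    sample_mass: float,
) -> float:
    """Raw (pre-censoring) concentration in ng/g by isotope dilution.

    amount ratio = (area_quant/area_eis - intercept)/slope; native mass =
    ratio * EIS spike; concentration = native mass / sample mass.  Because
    both channels scale identically under extraction losses, the result is
    invariant to any common multiplicative loss.  Negative back-calculated
    ratios (possible with a positive intercept near zero signal) floor at 0.

    Returns NaN when the EIS area is zero (unquantifiable record).
    """
    if area_eis <= 0:
        return float("nan")
    if sample_mass <= 0:
        raise QuantError("sample_mass must be > 0")
    if eis_spike <= 0:
        raise QuantError("eis_spike must be > 0")
    ratio = (area_quant / area_eis - curve.intercept) / curve.slope
    return max(ratio, 0.0) * eis_spike / sample_mass


def compute_mdl(blank_concentrations, idl: float) -> float:
    """Method detection limit from procedural blanks.

    A blank counts as a detect when its back-calculated concentration is at
    or above the IDL — below the signal-to-noise-10 level there is no
    analyte signal.  With two or more detects: mean + 3 x sample SD.  With
    no detects the instrumental detection limit is used; a single detect
    also falls back to the IDL (SD undefined) with a warning.
    """
    if idl <= 0:
        raise QuantError("idl must be > 0")
    detects = [float(b) for b in blank_concentrations if b is not None and float(b) >= idl]
    if len(detects) == 0:
        return float(idl)
    if len(detects) == 1:
        logger.warning("single blank detect (%.4g): SD undefined, using IDL", detects[0])
        return float(idl)
    arr = np.asarray(detects)
    mdl = float(arr.mean() + 3.0 * arr.std(ddof=1))
    return mdl if mdl > 0 else float(idl)


def blank_correct(
    raw_conc: float,
    blank_mean: float,
    mdl: float,
    *,
    sample_id: str = "",
    analyte_name: str = "",
) -> ConcentrationRecord:
    """Apply the blank correction, gated at the MDL.

    The subtraction is applied only when the raw value exceeds the MDL; a
    raw value at or below the MDL, or one that falls to or below the MDL
    after subtraction, is censored (reported ND at its MDL).  Output is
    never negative.
    """
    if mdl <= 0:
        raise QuantError("mdl must be > 0")
    if raw_conc > mdl:
        corrected = raw_conc - blank_mean
        if corrected > mdl:
            return ConcentrationRecord(sample_id, analyte_name, float(corrected), float(mdl),
                                       censored=False, blank_corrected=blank_mean != 0.0)
    return ConcentrationRecord(sample_id, analyte_name, None, float(mdl),
                               censored=True, blank_corrected=False)


def rt_check(
    rt_analyte: float,
    rt_eis: float,
    *,
    same_structure: bool,
    ccv_mean_shift: float | None = None,
    window_same: float = RT_WINDOW_SAME,
    window_different: float = RT_WINDOW_DIFFERENT,
) -> bool:
    """Retention-time acceptance.

    Same-structure EIS: |rt_analyte - rt_eis| <= 0.1 min.  Different
    structure: the difference is first corrected by the average analyte-EIS
    shift observed in the batch CCVs, then compared against 0.4 min.  A
    missing CCV shift in the different-structure case fails safe.
    """
    delta = rt_analyte - rt_eis
    if same_structure:
        return abs(delta) <= window_same
    if ccv_mean_shift is None or math.isnan(ccv_mean_shift):
        logger.warning("different-structure RT check without CCV shift: failing safe")
        return False
    return abs(delta - ccv_mean_shift) <= window_different


def ion_abundance_ratio(
    area_conf: float,
    area_quant: float,
    ccv_ratios,
) -> tuple[float, bool]:
    """CCV-normalized confirmation/quantification ratio, offset by one.

    iar = (area_conf/area_quant) / mean(CCV conf/quant ratios) - 1, so zero
    means no deviation from the calibration standards.  Acceptance is the
    closed interval [-1, 1].  Zero quantification area is undefined and
    fails; a zero CCV mean is a configuration error.
    """
    ratios = [float(r) for r in ccv_ratios]
    if not ratios:
        raise QuantError("ion-abundance check requires at least one CCV ratio")
    ccv_mean = float(np.mean(ratios))
    if ccv_mean <= 0:
        raise QuantError("CCV mean channel ratio must be > 0")
    if area_quant <= 0:
        return float("nan"), False
    iar = (area_conf / area_quant) / ccv_mean - 1.0
    return iar, bool(-1.0 <= iar <= 1.0)


def eis_recovery_check(
    area_eis: float,
    expected_area_eis: float,
    limits: tuple[float, float] = DEFAULT_RECOVERY_LIMITS,
) -> tuple[float, bool]:
    """EIS recovery as observed/expected response at the spike level.

    Bounds are inclusive (default 20-150%).
    """
    if expected_area_eis <= 0:
        raise QuantError("expected EIS response must be > 0")
    recovery = area_eis / expected_area_eis
    lo, hi = limits
    return recovery, bool(lo <= recovery <= hi)


def apply_exclusions(
    qc: pd.DataFrame,
    sample_fail_fraction_threshold: float = DEFAULT_EXCLUSION_FRACTION,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Record- and sample-level exclusion decisions.

    ``qc`` needs one row per sample x analyte with boolean columns
    ``rt_ok``, ``iar_ok``, ``recovery_ok`` and ``detected``, where
    ``detected`` means a quantifiable analyte signal was present (a
    below-MDL result still counts as a signal; "not detected" is no signal
    at all, e.g. a lost internal standard or empty channel).  A record
    failing any check is excluded.  A sample is wholly excluded when the
    fraction of its analytes that are failed *or* signal-less exceeds the
    threshold (default 0.75).  Decisions depend only on the set of records,
    not their order.

    Returns (qc with an ``excluded`` column, per-sample frame with
    ``fail_nd_fraction`` and ``sample_excluded``).
    """
    qc = qc.copy()
    qc["record_failed"] = ~(
        qc["rt_ok"].astype(bool) & qc["iar_ok"].astype(bool) & qc["recovery_ok"].astype(bool)
    )
    bad = qc["record_failed"] | ~qc["detected"].astype(bool)
    frac = bad.groupby(qc["sample_id"]).mean()
    samples = pd.DataFrame(
        {
            "sample_id": frac.index,
            "fail_nd_fraction": frac.to_numpy(),
            "sample_excluded": (frac > sample_fail_fraction_threshold).to_numpy(),
        }
    ).reset_index(drop=True)
    excluded_samples = set(samples.loc[samples["sample_excluded"], "sample_id"])
    qc["excluded"] = qc["record_failed"] | qc["sample_id"].isin(excluded_samples)
    for sid in sorted(excluded_samples):
        logger.info("sample %s excluded: fail/ND fraction %.2f > %.2f",
                    sid, frac[sid], sample_fail_fraction_threshold)
    return qc, samples


# ---------------------------------------------------------------------------
# batch driver


def quantify_batch(
    batch: pd.DataFrame,
    panel: Panel,
    calibrations: dict[str, "CalibrationCurve | pd.DataFrame"],
    idl: dict[str, float] | None = None,
    *,
    recovery_limits: tuple[float, float] = DEFAULT_RECOVERY_LIMITS,
    exclusion_fraction: float = DEFAULT_EXCLUSION_FRACTION,
    mdl_mode: str = "auto",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full quantification + QA/QC chain on one or more batches.

    Per batch and analyte: CCV statistics (channel-ratio mean, RT shift,
    expected EIS response) are derived from the batch CCV records; blanks
    are quantified to give the MDL (mean + 3 SD of detects, IDL fallback
    per ``mdl_mode``: "auto" default, "blank" forces blank-derived, "idl"
    forces the IDL) and the blank mean used for correction; specimens are
    quantified, QC-checked and blank-corrected; exclusion logic is applied.

    Returns (concentrations, qc_report) as tidy frames.  Concentrations
    carry one row per kept specimen x analyte with ``conc`` (NaN when
    censored), ``mdl``, ``censored`` and ``blank_corrected``.
    """
    if mdl_mode not in ("auto", "blank", "idl"):
        raise QuantError(f"unknown mdl_mode {mdl_mode!r}")
    idl = idl or {}
    curves: dict[str, CalibrationCurve] = {}
    for name, cal in calibrations.items():
        if isinstance(cal, CalibrationCurve):
            curves[name] = cal
        else:
            curves[name] = fit_calibration(name, cal, idl.get(name, 0.01))

    conc_rows: list[dict] = []
    qc_rows: list[dict] = []

    for batch_id, bdf in batch.groupby("batch_id", sort=True):
        ccv = bdf[bdf["role"] == "ccv"]
        blanks = bdf[bdf["role"] == "blank"]
        specimens = bdf[bdf["role"] == "specimen"]
        for analyte in panel:
            name = analyte.name
            if name not in curves:
                continue
            curve = curves[name]
            accv = ccv[ccv["analyte_name"] == name]
            ablk = blanks[blanks["analyte_name"] == name]
            aspec = specimens[specimens["analyte_name"] == name]
            ok = (accv["area_quant"] > 0) & (accv["area_conf"] > 0)
            ccv_ratios = (accv.loc[ok, "area_conf"] / accv.loc[ok, "area_quant"]).tolist()
            ccv_shift = float((accv["rt_analyte"] - accv["rt_eis"]).mean()) if len(accv) else float("nan")
            expected_eis = float(accv["area_eis"].mean()) if len(accv) else float("nan")

            blank_concs = [
                quantify(r.area_quant, r.area_eis, curve, r.eis_spike, r.sample_mass)
                for r in ablk.itertuples()
            ]
            blank_concs = [c for c in blank_concs if not math.isnan(c)]
            detects = [c for c in blank_concs if c >= curve.idl]
            if mdl_mode == "idl":
                mdl = curve.idl
            elif mdl_mode == "blank":
                if len(detects) < 2:
                    raise QuantError(f"{name}/{batch_id}: mdl_mode='blank' needs >=2 blank detects")
                mdl = compute_mdl(blank_concs, curve.idl)
            else:
                mdl = compute_mdl(blank_concs, curve.idl)
            blank_mean = float(np.mean(detects)) if detects else 0.0

            for r in aspec.itertuples():
                raw = quantify(r.area_quant, r.area_eis, curve, r.eis_spike, r.sample_mass)
                if math.isnan(expected_eis) or expected_eis <= 0:
                    recovery, rec_ok = float("nan"), False
                else:
                    recovery, rec_ok = eis_recovery_check(r.area_eis, expected_eis, recovery_limits)
                if ccv_ratios:
                    iar, iar_ok = ion_abundance_ratio(r.area_conf, r.area_quant, ccv_ratios)
                else:
                    iar, iar_ok = float("nan"), False
                rt_ok = rt_check(
                    r.rt_analyte, r.rt_eis,
                    same_structure=analyte.eis_same_structure,
                    ccv_mean_shift=ccv_shift,
                )
                rec = blank_correct(raw, blank_mean, mdl,
                                    sample_id=r.sample_id, analyte_name=name) \
                    if not math.isnan(raw) else ConcentrationRecord(
                        r.sample_id, name, None, mdl, censored=True, blank_corrected=False)
                qc_rows.append(
                    {
                        "sample_id": r.sample_id,
                        "analyte_name": name,
                        "batch_id": batch_id,
                        "rt_ok": rt_ok,
                        "iar": iar,
                        "iar_ok": iar_ok,
                        "eis_recovery": recovery,
                        "recovery_ok": rec_ok,
                        # signal present and quantifiable; below-MDL censoring
                        # is tracked separately and does not count against the
                        # sample-level exclusion fraction
                        "detected": bool(r.area_quant > 0) and not math.isnan(raw),
                    }
                )
                conc_rows.append(
                    {
                        "sample_id": r.sample_id,
                        "analyte_name": name,
                        "batch_id": batch_id,
                        "conc": rec.conc if rec.conc is not None else float("nan"),
                        "mdl": rec.mdl,
                        "censored": rec.censored,
                        "blank_corrected": rec.blank_corrected,
                    }
                )

    conc = pd.DataFrame(conc_rows)
    qc = pd.DataFrame(qc_rows)
    if qc.empty:
        return conc, qc
    qc, samples = apply_exclusions(qc, exclusion_fraction)
    key = ["sample_id", "analyte_name"]
    conc = conc.merge(qc[key + ["excluded"]], on=key, how="left")
    # A record failing QC is censored in the output (flagged, not dropped);
    # wholly excluded samples are dropped from the concentration table.
    failed = qc.set_index(key)["record_failed"]
    conc = conc.set_index(key)
    conc.loc[failed[failed].index.intersection(conc.index), ["conc", "censored"]] = [float("nan"), True]
    conc = conc.reset_index()
    dropped = set(samples.loc[samples["sample_excluded"], "sample_id"])
    conc = conc[~conc["sample_id"].isin(dropped)].reset_index(drop=True)
    qc = qc.merge(samples, on="sample_id", how="left")
    return conc, qc
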