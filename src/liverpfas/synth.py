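"""Synthetic liver-cohort and instrument-data generator.

Emulates the data structure of a retrospective biobank PFAS study: a donor
cohort (age, sex, liver-health status, collection year) whose NAFLD
probability is correlated with collection year; true per-donor liver
concentrations following a log10-linear model in year, age, sex and health;
and batch-level LC-HRMS records (peak areas for quantification/confirmation
channels, internal-standard areas, retention times, procedural blanks, CCVs
and positive controls) that the quantification module turns back into
concentrations.

Everything is driven by a single :class:`SimulationParams` object and an
integer seed; identical inputs produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .registry import Panel, default_panel

__all__ = [
    "AnalyteSim",
    "InstrumentParams",
    "SimulationParams",
    "generate_cohort",
    "generate_true_concentrations",
    "generate_batches",
    "generate_eof_measurements",
    "calibrate_health_logistic",
    "default_params",
]


@dataclass(frozen=True)
class AnalyteSim:
    """True concentration model for one analyte.

    log10 C = baseline + beta_year_decade*(year-2000)/10
            + beta_age_decade*(age-50)/10 + beta_sex*[female]
            + beta_health*[NAFLD] + Normal(0, sigma)

    ``baseline_log10`` is the geometric-mean log10 ng/g for a 50-year-old
    healthy male sampled in 2000.  Decade-scale betas are log10 units per
    10 years; sex/health betas are log10 units per category shift.
    ``idl`` is the instrumental detection limit in ng/g (signal-to-noise 10).
    """

    baseline_log10: float
    beta_year_decade: float = 0.0
    beta_age_decade: float = 0.0
    beta_sex: float = 0.0
    beta_health: float = 0.0
    sigma: float = 0.5
    idl: float = 0.02

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.idl <= 0:
            raise ValueError("idl must be > 0")


@dataclass(frozen=True)
class InstrumentParams:
    """Instrument response and noise model (plumbing around the chemistry).

    The calibration line lives in isotope-dilution ratio space:
    area ratio (native/EIS) = cal_slope * amount ratio + cal_intercept.
    ``eis_recovery_*`` model proportional extraction losses hitting both
    channels equally, which isotope dilution cancels.
    """

    response_eis: float = 1.0e5        # area counts per ng EIS
    cal_slope: float = 1.0
    cal_intercept: float = 0.0
    channel_ratio: float = 0.5         # confirmation/quantification area ratio
    area_cv: float = 0.05              # multiplicative lognormal noise CV
    blank_contam_mean: float = 0.002   # ng contamination per procedural sample
    blank_contam_sd: float = 0.0015
    eis_recovery_mean: float = 0.85
    eis_recovery_sd: float = 0.08
    ccv_ratio_sd: float = 0.02         # noise on CCV channel ratio
    rt_jitter_sd: float = 0.01         # min
    eis_rt_offset: float = 0.2         # min, for structurally different EIS
    sample_mass_mean: float = 0.5      # g wet weight
    sample_mass_sd: float = 0.02
    eis_spike: float = 4.0             # ng
    native_spike: float = 4.0          # ng, positive controls
    n_blanks: int = 8
    n_ccv: int = 3
    n_pos_controls: int = 2
    cal_levels: tuple[float, ...] = (0.05, 0.1, 0.25, 0.5, 1.0, 2.5, 5.0)

    def zeroed(self) -> "InstrumentParams":
        """Noise-free copy: unit recovery, no contamination, no jitter."""
        return replace(
            self,
            area_cv=0.0,
            blank_contam_mean=0.0,
            blank_contam_sd=0.0,
            eis_recovery_mean=1.0,
            eis_recovery_sd=0.0,
            ccv_ratio_sd=0.0,
            rt_jitter_sd=0.0,
            sample_mass_sd=0.0,
        )


# Default per-analyte truth.  Baselines (log10 ng/g at year 2000, healthy
# 50-y-old male) and effect signs/magnitudes chosen to mirror the reported
# liver concentration ranges and covariate percent changes: strong declines
# for legacy sulfonates and 8:2 FTS, flat sulfonamide precursors, a small
# increase for the chlorinated ether replacement, positive age slopes for
# bioaccumulative chains, lower levels in NAFLD livers.
def _a(base, yr=0.0, age=0.0, sex=0.0, hlth=0.0, sigma=0.5, idl=0.02) -> AnalyteSim:
    return AnalyteSim(base, yr, age, sex, hlth, sigma, idl)


# Baselines and IDLs are inverted jointly from the reported detected-value
# medians and detection frequencies under the lognormal truth model (the
# detected median is the 1 - DF/2 quantile; the detection threshold is the
# 1 - DF quantile), evaluated at the cohort-average covariates.
DEFAULT_ANALYTE_SIMS: dict[str, AnalyteSim] = {
    "PFBA":          _a(-2.33, 0.00, 0.000, 0.0, 0.00, 0.6, 0.053),
    "PFHxA":         _a(-2.47, 0.00, 0.000, 0.0, 0.00, 0.5, 0.037),
    "PFHpA":         _a(-2.70, 0.00, 0.000, 0.0, 0.00, 0.5, 0.030),
    "PFOA":          _a(-0.74, -0.119, 0.022, 0.0, 0.00, 0.45, 0.096),
    "PFNA":          _a(-0.93, -0.042, 0.028, 0.0, -0.056, 0.45, 0.083),
    "PFDA":          _a(-1.11, -0.021, 0.011, 0.0, 0.00, 0.45, 0.075),
    "PFUdA":         _a(-1.11, -0.028, 0.020, -0.049, -0.086, 0.45, 0.074),
    "PFDoA":         _a(-1.89, -0.002, 0.034, -0.083, -0.119, 0.5, 0.016),
    "PFTrDA":        _a(-1.76, 0.00, 0.000, 0.0, 0.00, 0.5, 0.064),
    "PFTeDA":        _a(-2.33, 0.00, 0.000, 0.0, 0.00, 0.5, 0.068),
    "L-PFHxS":       _a(-1.29, -0.007, 0.018, 0.0, 0.00, 0.5, 0.057),
    "Br-PFHxS":      _a(-1.94, -0.007, 0.010, 0.0, 0.00, 0.5, 0.030),
    "PFHpS":         _a(-1.42, -0.10, 0.010, 0.0, 0.00, 0.5, 0.094),
    "L-PFOS":        _a(0.46, -0.215, 0.037, 0.0, -0.108, 0.5, 0.094),
    "Br-PFOS":       _a(0.23, -0.208, 0.053, 0.0, -0.131, 0.5, 0.125),
    "PFDS":          _a(-1.24, -0.187, 0.000, 0.0, 0.00, 0.5, 0.084),
    "FOSA":          _a(-1.51, -0.056, 0.000, 0.0, 0.00, 0.4, 0.044),
    "L-N-MeFOSAA":   _a(-0.27, -0.201, 0.000, 0.0, 0.00, 0.5, 0.270),
    "Br-N-MeFOSAA":  _a(-0.89, -0.051, 0.000, 0.0, 0.00, 0.45, 0.244),
    "L-N-EtFOSAA":   _a(-0.60, -0.086, 0.000, 0.0, 0.00, 0.5, 0.529),
    "4:2 FTS":       _a(-2.70, 0.00, 0.000, 0.0, 0.00, 0.5, 0.038),
    "6:2 FTS":       _a(-1.64, 0.00, 0.000, 0.0, 0.00, 0.5, 0.106),
    "8:2 FTS":       _a(-0.68, -0.252, 0.027, 0.079, -0.137, 0.5, 0.070),
    "10:2 FTS":      _a(-1.39, 0.00, 0.000, 0.0, 0.00, 0.6, 1.07),
    "3:3 FTCA":      _a(-2.74, 0.00, 0.000, 0.0, 0.00, 0.5, 0.039),
    "5:3 FTCA":      _a(-2.50, 0.00, 0.000, 0.0, 0.00, 0.5, 0.061),
    "7:3 FTCA":      _a(-1.24, 0.00, 0.000, 0.0, 0.00, 0.4, 0.161),
    "9Cl-PF3ONS":    _a(-2.10, 0.029, 0.000, -0.030, -0.036, 0.4, 0.021),
    "11Cl-PF3OUdS":  _a(-2.82, 0.00, 0.000, 0.0, 0.00, 0.4, 0.016),
    "3,6-OPFHpA":    _a(-2.51, 0.00, 0.000, 0.0, 0.00, 0.4, 0.024),
    "PFECHS":        _a(-1.87, 0.00, 0.000, 0.0, 0.00, 0.5, 0.090),
}

# Unequal per-year sampling: heavier early-2000s and 2020s arms, a sparse
# middle, so that inverse-sample-size weighting is meaningfully exercised.
DEFAULT_YEAR_WEIGHTS: dict[int, float] = {
    2000: 10, 2001: 6, 2002: 5, 2003: 12, 2004: 6, 2005: 5, 2006: 8,
    2007: 7, 2008: 5, 2009: 4, 2010: 5, 2011: 1, 2012: 4, 2013: 6,
    2014: 4, 2015: 5, 2016: 5, 2017: 6, 2018: 7, 2019: 8, 2020: 12,
    2021: 14, 2022: 16, 2023: 14, 2024: 11,
}


@dataclass(frozen=True)
class SimulationParams:
    """All knobs of the synthetic study, with study-structure defaults.

    Cohort defaults match the emulated study's demographics: n=211 donors,
    age 57.51 +/- 13.53 truncated to [18, 85], a 50/50 sex split, 54% NAFLD
    prevalence with NAFLD probability rising logistically with collection
    year so that the year<->health squared correlation is ~0.43, and 85% of
    female donors postmenopausal (age >= 46), as in the emulated cohort.  A minority of donors carry a
    collection-year *range* or missing metadata, reproducing the exact-year
    (trend) and complete-metadata (MLR) subsets being smaller than n.
    """

    n_donors: int = 211
    seed: int = 0
    age_mean: float = 57.51
    age_sd: float = 13.53
    age_min: float = 18.0
    age_max: float = 85.0
    p_female: float = 0.5
    postmenopausal_frac: float | None = 0.85
    menopause_age: float = 46.0
    year_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_YEAR_WEIGHTS)
    )
    nafld_prevalence: float = 0.54
    year_health_r2: float = 0.43
    frac_year_range: float = 0.14
    frac_year_missing: float = 0.014
    frac_health_missing: float = 0.010
    frac_age_missing: float = 0.005
    analytes: Mapping[str, AnalyteSim] = field(
        default_factory=lambda: dict(DEFAULT_ANALYTE_SIMS)
    )
    instrument: InstrumentParams = field(default_factory=InstrumentParams)
    eof_n_donors: int = 8
    eof_fold: float = 13.0            # EOF / targeted fluorine-equivalent ratio
    eof_fold_cv: float = 0.35
    eof_matrix_blank_mean: float = 0.5  # ng F/g
    eof_matrix_blank_sd: float = 0.15
    eof_di_blank_mean: float = 0.3
    eof_di_blank_sd: float = 0.05

    def zero_noise(self) -> "SimulationParams":
        """Copy with sigma=0 everywhere and a noise-free instrument."""
        return replace(
            self,
            analytes={k: replace(v, sigma=0.0) for k, v in self.analytes.items()},
            instrument=self.instrument.zeroed(),
            frac_year_range=0.0,
            frac_year_missing=0.0,
            frac_health_missing=0.0,
            frac_age_missing=0.0,
        )


def default_params(**overrides) -> SimulationParams:
    return replace(SimulationParams(), **overrides) if overrides else SimulationParams()


# ---------------------------------------------------------------------------
# cohort


def calibrate_health_logistic(
    years: np.ndarray,
    probs: np.ndarray,
    target_r2: float,
    prevalence: float,
) -> tuple[float, float]:
    """Solve logistic parameters (a, b) for P(NAFLD | year) = expit(a + b*(year-2012)).

    Constraints: population prevalence equals ``prevalence`` and the squared
    year<->disease correlation (computed analytically over the year
    distribution given by support ``years`` with weights ``probs``) equals
    ``target_r2``.  Raises ``ValueError`` with a diagnostic when the target
    exceeds what any monotone year-dependence can achieve for this year
    distribution and prevalence.
    """
    years = np.asarray(years, dtype=float)
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    center = probs @ years  # center at the mean year so the intercept search brackets
    x = years - center
    xbar = probs @ x
    varx = probs @ (x - xbar) ** 2
    if varx <= 0:
        raise ValueError("year distribution is degenerate; cannot induce a year-health correlation")

    def solve_a(b: float) -> float:
        return brentq(lambda a: probs @ expit(a + b * x) - prevalence, -200.0, 200.0, xtol=1e-12)

    def r2_of(b: float) -> float:
        p = expit(solve_a(b) + b * x)
        pbar = probs @ p
        cov = probs @ (x * p) - xbar * pbar
        vary = pbar * (1.0 - pbar)
        return cov * cov / (varx * vary)

    b_hi = 8.0
    r2_max = r2_of(b_hi)
    if target_r2 <= 0:
        return solve_a(0.0), 0.0
    if target_r2 > r2_max:
        raise ValueError(
            f"year-health R^2 target {target_r2:.3f} infeasible: the steepest "
            f"year-threshold dependence achieves at most {r2_max:.3f} for this "
            f"year distribution and prevalence {prevalence:.2f}"
        )
    b = brentq(lambda bb: r2_of(bb) - target_r2, 1e-9, b_hi, xtol=1e-10)
    # report the intercept on the year-2012 origin stated in the contract
    return solve_a(b) + b * (2012.0 - center), b


def _draw_ages(params: SimulationParams, female: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    lo, hi, scale = params.age_min, params.age_max, params.age_sd

    def tn(lo_, hi_, n, loc):
        a = (lo_ - loc) / scale
        b = (hi_ - loc) / scale
        return truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)

    def tn_mean(lo_, hi_, loc):
        a = (lo_ - loc) / scale
        b = (hi_ - loc) / scale
        return truncnorm.mean(a, b, loc=loc, scale=scale)

    ages = tn(lo, hi, female.size, params.age_mean)
    if params.postmenopausal_frac is not None and female.any():
        # Female ages come from a pre/post-menopause mixture with a configured
        # postmenopausal share.  The mixture location is shifted so the female
        # (and hence cohort) mean age stays at the configured value.
        frac, cut = params.postmenopausal_frac, params.menopause_age
        target = tn_mean(lo, hi, params.age_mean)

        def mix_mean_err(loc):
            return (
                frac * tn_mean(max(lo, cut), hi, loc)
                + (1 - frac) * tn_mean(lo, min(cut, hi), loc)
                - target
            )
        loc_f = brentq(mix_mean_err, params.age_mean - 25.0, params.age_mean + 25.0, xtol=1e-10)
        idx = np.flatnonzero(female)
        post = rng.random(idx.size) < frac
        n_post, n_pre = int(post.sum()), int((~post).sum())
        if n_post:
            ages[idx[post]] = tn(max(lo, cut), hi, n_post, loc_f)
        if n_pre:
            ages[idx[~post]] = tn(lo, min(cut, hi), n_pre, loc_f)
    return ages


def generate_cohort(params: SimulationParams, seed: int | None = None) -> pd.DataFrame:
    """Draw a donor cohort.

    Returns a DataFrame with one row per donor.  ``age_true``/``year_true``
    are the latent values driving concentration generation; ``age``,
    ``year_min``/``year_max`` and ``health`` are the *observed* metadata
    (possibly a range or missing), which is what downstream analyses see.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = int(params.n_donors)
    if n < 0:
        raise ValueError("n_donors must be >= 0")
    cols = ["donor_id", "age_true", "age", "sex", "health", "year_true",
            "year_min", "year_max", "bmi"]
    if n == 0:
        return pd.DataFrame(columns=cols)

    years_support = np.array(sorted(params.year_weights), dtype=float)
    wts = np.array([params.year_weights[int(y)] for y in years_support], dtype=float)
    probs = wts / wts.sum()
    a_h, b_h = calibrate_health_logistic(
        years_support, probs, params.year_health_r2, params.nafld_prevalence
    )

    female = rng.random(n) < params.p_female
    ages = _draw_ages(params, female, rng)
    years = rng.choice(years_support, size=n, p=probs)
    p_nafld = expit(a_h + b_h * (years - 2012.0))
    nafld = rng.random(n) < p_nafld
    bmi = np.clip(rng.normal(31.3, 9.2, size=n), 16.5, 80.0)

    df = pd.DataFrame(
        {
            "donor_id": [f"D{i:04d}" for i in range(1, n + 1)],
            "age_true": ages,
            "age": ages,
            "sex": np.where(female, "female", "male"),
            "health": np.where(nafld, "NAFLD", "normal"),
            "year_true": years,
            "year_min": years,
            "year_max": years,
            "bmi": bmi,
        }
    )

    # Metadata degradation: year ranges, missing years, missing health/age.
    u = rng.random(n)
    is_missing = u < params.frac_year_missing
    is_range = (~is_missing) & (u < params.frac_year_missing + params.frac_year_range)
    if is_range.any():
        lo_off = rng.integers(1, 4, size=int(is_range.sum()))
        hi_off = rng.integers(1, 4, size=int(is_range.sum()))
        ymin = np.maximum(2000, years[is_range] - lo_off)
        ymax = np.minimum(2024, years[is_range] + hi_off)
        df.loc[is_range, "year_min"] = ymin
        df.loc[is_range, "year_max"] = ymax
    df.loc[is_missing, ["year_min", "year_max"]] = np.nan
    df.loc[rng.random(n) < params.frac_health_missing, "health"] = np.nan
    df.loc[rng.random(n) < params.frac_age_missing, "age"] = np.nan
    return df


# ---------------------------------------------------------------------------
# true concentrations


def generate_true_concentrations(
    cohort: pd.DataFrame, params: SimulationParams, seed: int | None = None
) -> pd.DataFrame:
    """Donor x analyte matrix of true liver concentrations (ng/g).

    log10 C = baseline + b_year*(year-2000)/10 + b_age*(age-50)/10
            + b_sex*[female] + b_health*[NAFLD] + N(0, sigma)
    using the latent (true) covariates, so observed-metadata gaps do not
    leak into the truth.
    """
    if cohort.empty:
        return pd.DataFrame(columns=list(params.analytes))
    rng = np.random.default_rng((params.seed if seed is None else seed) + 1)
    year = cohort["year_true"].to_numpy(dtype=float)
    age = cohort["age_true"].to_numpy(dtype=float)
    female = (cohort["sex"] == "female").to_numpy()
    nafld = (cohort["health"] == "NAFLD").to_numpy()
    out = {}
    for name, a in params.analytes.items():
        log10c = (
            a.baseline_log10
            + a.beta_year_decade * (year - 2000.0) / 10.0
            + a.beta_age_decade * (age - 50.0) / 10.0
            + a.beta_sex * female
            + a.beta_health * nafld
        )
        if a.sigma > 0:
            log10c = log10c + rng.normal(0.0, a.sigma, size=year.size)
        out[name] = 10.0 ** log10c
    return pd.DataFrame(out, index=cohort["donor_id"].to_numpy())


# ---------------------------------------------------------------------------
# instrument batches


def _lognoise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv <= 0:
        return np.ones(size if np.ndim(size) == 0 else size)
    s = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(0.0, s, size=size))


def make_calibrations(panel: Panel, params: SimulationParams) -> dict[str, pd.DataFrame]:
    """Noise-free calibration level tables (amount ratio, area ratio) per analyte."""
    ins = params.instrument
    x = np.asarray(ins.cal_levels, dtype=float)
    out = {}
    for a in panel:
        out[a.name] = pd.DataFrame(
            {"amount_ratio": x, "area_ratio": ins.cal_slope * x + ins.cal_intercept}
        )
    return out


def generate_batches(
    true_conc: pd.DataFrame,
    cohort: pd.DataFrame,
    panel: Panel,
    params: SimulationParams,
    seed: int | None = None,
) -> pd.DataFrame:
    """Instrument-level records for specimens, blanks, CCVs and positive controls.

    Area model (per sample x analyte): the EIS channel reads
    ``response * spike * recovery * noise``; the quantification channel reads
    ``(slope * native/spike + intercept) * area_eis * noise`` so the
    isotope-dilution ratio is preserved under any common proportional loss;
    the confirmation channel is a fixed fraction of the quantification
    channel.  Procedural blanks carry contamination draws; CCVs carry the
    mid-calibration amount ratio; positive controls carry a known native
    spike into clean matrix.
    """
    rng = np.random.default_rng((params.seed if seed is None else seed) + 2)
    ins = params.instrument
    names = [a.name for a in panel]
    rt_nominal = {a.name: 2.0 + 0.18 * i for i, a in enumerate(panel)}
    rt_eis_off = {a.name: (0.0 if a.eis_same_structure else ins.eis_rt_offset) for a in panel}

    rows: list[dict] = []

    def emit(sample_id, role, native_ng, mass, native_spike=0.0):
        recovery = ins.eis_recovery_mean + (
            rng.normal(0.0, ins.eis_recovery_sd) if ins.eis_recovery_sd > 0 else 0.0
        )
        recovery = max(recovery, 0.05)
        for name in names:
            area_eis = ins.response_eis * ins.eis_spike * recovery * float(_lognoise(rng, ins.area_cv, ()))
            ratio = ins.cal_slope * native_ng[name] / ins.eis_spike + ins.cal_intercept
            area_q = max(ratio * area_eis * float(_lognoise(rng, ins.area_cv, ())), 0.0)
            conf_noise = ins.ccv_ratio_sd if role == "ccv" else ins.area_cv
            area_c = ins.channel_ratio * area_q * float(_lognoise(rng, conf_noise, ()))
            jit = ins.rt_jitter_sd
            rows.append(
                {
                    "sample_id": sample_id,
                    "analyte_name": name,
                    "role": role,
                    "area_quant": area_q,
                    "area_conf": area_c,
                    "area_eis": area_eis,
                    "rt_analyte": rt_nominal[name] + (rng.normal(0, jit) if jit > 0 else 0.0),
                    "rt_eis": rt_nominal[name] + rt_eis_off[name] + (rng.normal(0, jit) if jit > 0 else 0.0),
                    "sample_mass": mass,
                    "eis_spike": ins.eis_spike,
                    "native_spike": native_spike,
                    "batch_id": "B01",
                }
            )

    def contamination() -> dict[str, float]:
        if ins.blank_contam_mean <= 0 and ins.blank_contam_sd <= 0:
            return {n: 0.0 for n in names}
        draw = rng.normal(ins.blank_contam_mean, ins.blank_contam_sd, size=len(names))
        return {n: max(d, 0.0) for n, d in zip(names, draw)}

    # specimens: native mass = true conc * sample mass + shared contamination
    for donor_id in true_conc.index:
        mass = ins.sample_mass_mean + (
            rng.normal(0.0, ins.sample_mass_sd) if ins.sample_mass_sd > 0 else 0.0
        )
        mass = max(mass, 0.05)
        contam = contamination()
        native = {n: float(true_conc.at[donor_id, n]) * mass + contam[n] for n in names}
        emit(donor_id, "specimen", native, mass)

    for i in range(ins.n_blanks):
        emit(f"BLK{i + 1:02d}", "blank", contamination(), ins.sample_mass_mean)

    ccv_native = {n: 1.0 * ins.eis_spike for n in names}  # mid-calibration, ratio 1
    for i in range(ins.n_ccv):
        emit(f"CCV{i + 1:02d}", "ccv", ccv_native, 1.0)

    for i in range(ins.n_pos_controls):
        native = {n: ins.native_spike + c for n, c in contamination().items()}
        emit(f"PC{i + 1:02d}", "positive_control", native, ins.sample_mass_mean,
             native_spike=ins.native_spike)

    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# extractable organofluorine


def generate_eof_measurements(
    true_conc: pd.DataFrame,
    cohort: pd.DataFrame,
    panel: Panel,
    params: SimulationParams,
    seed: int | None = None,
) -> pd.DataFrame:
    """Combustion-IC fluoride readings for an early-period donor subset.

    The true EOF of each selected donor is its targeted fluorine-equivalent
    total multiplied by a configurable gap factor (default ~13-fold),
    reflecting organofluorine not captured by the targeted panel; readings
    add the DI-water instrumental background.  Two DI blanks and two matrix
    extraction blanks accompany the batch.
    """
    from .registry import fluorine_mass_fraction

    rng = np.random.default_rng((params.seed if seed is None else seed) + 3)
    with_year = cohort.dropna(subset=["year_min"])
    chosen = with_year.sort_values(["year_min", "donor_id"]).head(params.eof_n_donors)
    frac = {a.name: fluorine_mass_fraction(a) for a in panel}
    rows = []
    for donor_id in chosen["donor_id"]:
        targeted_f = float(
            sum(true_conc.at[donor_id, n] * frac[n] for n in true_conc.columns if n in frac)
        )
        eof_true = targeted_f * params.eof_fold * float(_lognoise(rng, params.eof_fold_cv, ()))
        reading = eof_true + max(rng.normal(params.eof_di_blank_mean, params.eof_di_blank_sd), 0.0)
        rows.append({"sample_id": donor_id, "role": "specimen",
                     "fluoride_reading": reading, "batch_id": "E01", "dilution_factor": 1.0})
    for i in range(2):
        rows.append({"sample_id": f"DI{i + 1:02d}", "role": "di_blank",
                     "fluoride_reading": max(rng.normal(params.eof_di_blank_mean, params.eof_di_blank_sd), 0.0),
                     "batch_id": "E01", "dilution_factor": 1.0})
    for i in range(2):
        rows.append({"sample_id": f"MB{i + 1:02d}", "role": "matrix_blank",
                     "fluoride_reading": max(rng.normal(params.eof_matrix_blank_mean, params.eof_matrix_blank_sd), 0.0),
                     "batch_id": "E01", "dilution_factor": 1.0})
    return pd.DataFrame(rows)
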