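"""Inverse-sample-size-weighted log-linear temporal trends.

Model: log10(concentration) = beta0 + beta1 * year, fitted by weighted
least squares with each observation weighted by the inverse of its
collection year's sample count, so heavily sampled years do not dominate
the trend.  Fitted lines convert to modeled geometric means at any year and
to percent reductions between two years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "TrendFit",
    "inverse_year_weights",
    "fit_weighted_trend",
    "geometric_mean_at",
    "percent_reduction",
    "per_analyte_trends",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrendFit:
    """Weighted log-linear trend.  beta1 is in log10 units per calendar year."""

    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    p_value: float
    r2: float
    n_obs: int
    weights: tuple[float, ...] = ()

    @property
    def pct_change_per_decade(self) -> float:
        return (10.0 ** (10.0 * self.beta1) - 1.0) * 100.0


def inverse_year_weights(years: np.ndarray) -> np.ndarray:
    """w_i = 1 / (number of observations sharing observation i's year).

    Counts are taken over the observations actually entering the fit, so
    all observations from one year share one weight.
    """
    years = np.asarray(years, dtype=float)
    _, inverse, counts = np.unique(years, return_inverse=True, return_counts=True)
    return 1.0 / counts[inverse]


def fit_weighted_trend(values, years) -> TrendFit:
    """Fit log10(value) = beta0 + beta1*year by inverse-sample-size WLS.

    Requires at least 3 observations spanning 2 or more distinct years and
    strictly positive values (use a detected-only sum, dropping all-ND
    donors, or the substituted sum).  Analyte-level screens apply a stricter
    3-distinct-year gate before calling this (see per_analyte_trends).
    The year axis is centered at the weighted mean year for conditioning;
    reported coefficients are on the raw calendar-year scale.  The slope
    p-value is a two-sided t test with n-2 degrees of freedom on the
    weighted residual variance.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(years, dtype=float)
    if v.shape != y.shape:
        raise ValueError("values and years must align")
    keep = ~(np.isnan(v) | np.isnan(y))
    v, y = v[keep], y[keep]
    if v.size < 3 or np.unique(y).size < 2:
        raise ValueError(
            f"need >= 3 observations over >= 2 distinct collection years, "
            f"got {v.size} over {np.unique(y).size}"
        )
    if np.any(v <= 0):
        raise ValueError(
            "nonpositive concentration in log-linear trend; drop all-ND donors "
            "or use the substituted sum mode"
        )
    w = inverse_year_weights(y)
    ybar = float(np.average(y, weights=w))
    X = sm.add_constant(y - ybar)
    res = sm.WLS(np.log10(v), X, weights=w).fit()
    a, b = res.params
    beta0 = float(a - b * ybar)  # uncenter the intercept
    logv = np.log10(v)
    ss_res = float(np.sum(w * res.resid**2))
    ss_tot = float(np.sum(w * (logv - np.average(logv, weights=w)) ** 2))
    if ss_tot <= 1e-14 * max(1.0, np.mean(logv) ** 2):
        # constant response: no trend, by definition
        p_value, r2, b = 1.0, 0.0, 0.0
    elif ss_res <= 1e-12 * ss_tot:
        # exact line through the data: residual variance carries no information
        p_value, r2 = 0.0, 1.0
    else:
        p_value, r2 = float(res.pvalues[1]), float(res.rsquared)
    return TrendFit(
        beta0=beta0,
        beta1=float(b),
        se_beta0=float(res.bse[0]),  # SE of the centered intercept
        se_beta1=float(res.bse[1]),
        p_value=p_value,
        r2=r2,
        n_obs=int(v.size),
        weights=tuple(float(x) for x in w),
    )


def geometric_mean_at(fit: TrendFit, year: float) -> float:
    """Modeled geometric mean concentration (ng/g) at a calendar year."""
    return 10.0 ** (fit.beta0 + fit.beta1 * year)


def percent_reduction(fit: TrendFit, year_start: float, year_end: float) -> float:
    """Percent decline of the modeled geometric mean between two years.

    100 * (1 - GM(end)/GM(start)) = 100 * (1 - 10^(beta1*(end-start))).
    Negative when the trend increases.
    """
    if year_end <= year_start:
        raise ValueError("year_end must exceed year_start")
    return 100.0 * (1.0 - 10.0 ** (fit.beta1 * (year_end - year_start)))


def per_analyte_trends(
    table,
    alpha: float = 0.05,
    mode: str = "detected_only",
    min_distinct_years: int = 3,
) -> pd.DataFrame:
    """One weighted trend per analyte, with a significance label.

    ``detected_only`` fits each analyte on its detected values (the
    compound-specific trend convention); ``substituted`` uses MDL/2-filled
    values for every donor with a resolved year.  Analytes with fewer than
    ``min_distinct_years`` usable years are skipped with a log entry.
    Labels: ``decline`` / ``increase`` when the slope is significant at
    ``alpha``, else ``no-change``.
    """
    from .dataset import CohortTable, substitute_nondetects  # noqa: F401 (typing aid)

    donors = table.donors.set_index("donor_id")
    year_of = donors["year"]
    if mode == "detected_only":
        conc = table.wide("conc")
    elif mode == "substituted":
        conc = substitute_nondetects(table)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for analyte in conc.columns:
        s = conc[analyte].dropna()
        yrs = year_of.reindex(s.index)
        ok = yrs.notna() & (s > 0)
        s, yrs = s[ok], yrs[ok]
        if np.unique(yrs).size < min_distinct_years:
            logger.info("%s: skipped (%d distinct years < %d)",
                        analyte, np.unique(yrs).size, min_distinct_years)
            continue
        fit = fit_weighted_trend(s.to_numpy(), yrs.to_numpy())
        if fit.p_value < alpha:
            label = "decline" if fit.beta1 < 0 else "increase"
        else:
            label = "no-change"
        rows.append(
            {
                "analyte_name": analyte,
                "beta0": fit.beta0,
                "beta1": fit.beta1,
                "se_beta1": fit.se_beta1,
                "p_value": fit.p_value,
                "r2": fit.r2,
                "n_obs": fit.n_obs,
                "pct_change_per_decade": fit.pct_change_per_decade,
                "label": label,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["analyte_name", "beta0", "beta1", "se_beta1", "p_value", "r2",
                 "n_obs", "pct_change_per_decade", "label"],
    )
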