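"""Multivariate linear model of hepatic PFAS on donor covariates.

OLS of log10 concentration (nondetects at MDL/2) on sampling year, age,
sex and liver-health status, fitted simultaneously on the complete-metadata
donor subset.  Coefficients convert to percent changes via
(10^beta - 1) x 100, with continuous predictors scaled per decade.
Diagnostics: variance inflation factors, overall F test, and three residual
normality tests (Shapiro-Wilk, D'Agostino-Pearson, Lilliefors-corrected
Kolmogorov-Smirnov).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import kstest_normal
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "MLRFit",
    "PREDICTORS",
    "select_analytes",
    "build_design",
    "fit_mlr",
    "beta_to_percent_change",
    "percent_change_to_beta",
    "vif",
    "residual_normality",
    "fit_all_mlr",
]

logger = logging.getLogger(__name__)

PREDICTORS = ("year", "age", "sex", "health")
_KIND = {"year": "continuous", "age": "continuous", "sex": "binary", "health": "binary"}
SUM_LABEL = "sum"


@dataclass
class MLRFit:
    """Fitted covariate model for one analyte (or the PFAS sum).

    ``coefficients`` are in log10 units per year/per year-of-age for the
    continuous predictors and per category shift (male->female,
    healthy->NAFLD) for the binary ones.  ``percent_changes`` apply the
    per-decade scaling for year and age.
    """

    analyte_name: str
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    percent_changes: dict[str, float]
    r2: float
    f_p_value: float
    vif: dict[str, float]
    normality_p: dict[str, float]
    n_obs: int
    intercept: float = 0.0
    residuals: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)


def beta_to_percent_change(beta: float, predictor_kind: str) -> float:
    """Percent change implied by a log10-scale coefficient.

    Continuous predictors (year, age) report the change over 10 units:
    (10^(10*beta) - 1) x 100.  Binary predictors report the category shift:
    (10^beta - 1) x 100.  The sign of the output always matches the sign of
    beta.
    """
    if predictor_kind == "continuous":
        return (10.0 ** (10.0 * beta) - 1.0) * 100.0
    if predictor_kind == "binary":
        return (10.0 ** beta - 1.0) * 100.0
    raise ValueError(f"unknown predictor kind {predictor_kind!r}")


def percent_change_to_beta(pct: float, predictor_kind: str) -> float:
    """Inverse of :func:`beta_to_percent_change` (exact round trip)."""
    if pct <= -100.0:
        raise ValueError("percent change must exceed -100")
    b = np.log10(1.0 + pct / 100.0)
    if predictor_kind == "continuous":
        return float(b / 10.0)
    if predictor_kind == "binary":
        return float(b)
    raise ValueError(f"unknown predictor kind {predictor_kind!r}")


def select_analytes(table, min_detects: int = 30) -> list[str]:
    """Analytes with at least ``min_detects`` detected donors, plus the sum.

    The detection floor keeps parametric estimates honest for compounds
    with heterogeneous detection patterns; the PFAS sum is always modeled.
    """
    counts = (~table.wide("censored").astype(bool)).sum(axis=0)
    chosen = sorted(counts[counts >= min_detects].index)
    return chosen + [SUM_LABEL]


def build_design(table, analyte: str, dropna: bool = True) -> pd.DataFrame:
    """Complete-case design frame: log10 response + the four predictors.

    Sex is coded male=0/female=1 and health normal=0/NAFLD=1, so percent
    changes read "female vs male" and "NAFLD vs healthy".  Nondetects enter
    at MDL/2; ``sum`` uses the substituted per-donor sum.  Donors missing
    any covariate (including an unresolvable collection year) are dropped.
    """
    from .dataset import substitute_nondetects, sum_pfas

    donors = table.donors.set_index("donor_id")
    if analyte == SUM_LABEL:
        y = sum_pfas(table, mode="substituted")
    else:
        filled = substitute_nondetects(table)
        if analyte not in filled.columns:
            raise KeyError(f"analyte {analyte!r} not in cohort table")
        y = filled[analyte]
    df = pd.DataFrame(
        {
            "log10_conc": np.log10(y),
            "year": donors["year"].reindex(y.index),
            "age": donors["age"].reindex(y.index),
            "sex": donors["sex"].reindex(y.index).map({"male": 0.0, "female": 1.0}),
            "health": donors["health"].reindex(y.index).map({"normal": 0.0, "NAFLD": 1.0}),
        }
    )
    return df.dropna() if dropna else df


def vif(design: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factors, 1/(1-R^2) per predictor.

    ``design`` holds predictor columns only (no response); an intercept is
    added internally, matching the usual auxiliary-regression definition.
    Perfect collinearity reports inf rather than raising.
    """
    if design.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    X = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
    out = {}
    for i, name in enumerate(design.columns, start=1):
        with np.errstate(divide="ignore"):
            out[name] = float(variance_inflation_factor(X, i))
    return out


def residual_normality(residuals: np.ndarray) -> dict[str, float]:
    """Three residual-normality p-values (diagnostics only; no action taken).

    Shapiro-Wilk (n >= 3), D'Agostino-Pearson (n >= 20; NaN below), and the
    Kolmogorov-Smirnov test in its Lilliefors form, which calibrates for the
    mean and SD being estimated from the residuals themselves.
    """
    r = np.asarray(residuals, dtype=float)
    r = r[~np.isnan(r)]
    out = {"shapiro": float("nan"), "dagostino": float("nan"), "ks_lilliefors": float("nan")}
    if r.size >= 3:
        out["shapiro"] = float(stats.shapiro(r).pvalue)
    if r.size >= 20:
        out["dagostino"] = float(stats.normaltest(r).pvalue)
    if r.size >= 4:
        out["ks_lilliefors"] = float(kstest_normal(r, dist="norm")[1])
    return out


def fit_mlr(table, analyte: str) -> MLRFit:
    """Fit the four-covariate model for one analyte (or ``"sum"``).

    All predictors enter simultaneously; a rank-deficient design raises a
    ``ValueError`` naming the collinear columns.
    """
    design = build_design(table, analyte)
    return _fit_design(analyte, design)


def _fit_design(analyte: str, design: pd.DataFrame) -> MLRFit:
    if design.empty:
        raise ValueError(f"{analyte}: no complete-case rows")
    X = design[list(PREDICTORS)]
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy(float)]))
    if rank < X.shape[1] + 1:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        i, j = np.unravel_index(np.nanargmax(corr.to_numpy()), corr.shape)
        raise ValueError(
            f"{analyte}: rank-deficient design; most collinear pair "
            f"({corr.index[i]!r}, {corr.columns[j]!r})"
        )
    res = sm.OLS(design["log10_conc"].to_numpy(float), sm.add_constant(X.to_numpy(float))).fit()
    coefs = dict(zip(PREDICTORS, res.params[1:]))
    ses = dict(zip(PREDICTORS, res.bse[1:]))
    pvals = dict(zip(PREDICTORS, res.pvalues[1:]))
    pct = {p: beta_to_percent_change(coefs[p], _KIND[p]) for p in PREDICTORS}
    return MLRFit(
        analyte_name=analyte,
        coefficients={k: float(v) for k, v in coefs.items()},
        standard_errors={k: float(v) for k, v in ses.items()},
        p_values={k: float(v) for k, v in pvals.items()},
        percent_changes=pct,
        r2=float(res.rsquared),
        f_p_value=float(res.f_pvalue),
        vif=vif(X),
        normality_p=residual_normality(res.resid),
        n_obs=int(res.nobs),
        intercept=float(res.params[0]),
        residuals=np.asarray(res.resid),
    )


def fit_all_mlr(table, min_detects: int = 30, alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Model every eligible analyte plus the sum.

    Returns (results, diagnostics): results has one row per analyte x
    predictor (beta, SE, p, percent change, significance flag); diagnostics
    has one row per analyte (R^2, F p-value, VIFs, normality p-values, n).
    """
    results, diags = [], []
    for analyte in select_analytes(table, min_detects):
        try:
            fit = fit_mlr(table, analyte)
        except (ValueError, KeyError) as exc:
            logger.warning("%s: MLR skipped (%s)", analyte, exc)
            continue
        for p in PREDICTORS:
            results.append(
                {
                    "analyte_name": analyte,
                    "predictor": p,
                    "beta": fit.coefficients[p],
                    "se": fit.standard_errors[p],
                    "p_value": fit.p_values[p],
                    "percent_change": fit.percent_changes[p],
                    "significant": fit.p_values[p] < alpha,
                }
            )
        diags.append(
            {
                "analyte_name": analyte,
                "n_obs": fit.n_obs,
                "r2": fit.r2,
                "f_p_value": fit.f_p_value,
                **{f"vif_{p}": fit.vif[p] for p in PREDICTORS},
                **{f"norm_p_{k}": v for k, v in fit.normality_p.items()},
            }
        )
    return pd.DataFrame(results), pd.DataFrame(diags)
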