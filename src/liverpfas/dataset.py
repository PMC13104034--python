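"""Cohort table assembly and censored-data aggregation.

Joins quantified concentrations to donor metadata and provides the
statistical substrate for everything downstream: MDL/2 substitution for
nondetects, detection frequencies, per-donor PFAS sums, chemical-class
composition by year, and period summaries (median, IQR, fold range).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import Panel

__all__ = [
    "CohortTable",
    "resolve_year",
    "substitute_nondetects",
    "detection_frequency",
    "sum_pfas",
    "class_composition",
    "period_summary",
    "table_from_truth",
    "DEFAULT_PERIODS",
]

logger = logging.getLogger(__name__)

# Period bins used for decade-level comparisons: early 2000s, late 2000s,
# and the most recent arm of the study window.
DEFAULT_PERIODS: dict[str, tuple[int, int]] = {
    "2000-2005": (2000, 2005),
    "2006-2010": (2006, 2010),
    "2020-2024": (2020, 2024),
}


def resolve_year(year_min, year_max=None) -> float:
    """Collapse a collection year or (start, end) range to a numeric year.

    An exact year maps to itself; a range maps to its midpoint (2000-2005
    -> 2002.5); missing stays missing (NaN), excluding the donor from
    year-dependent analyses.  A reversed range is an error.
    """
    if year_min is None or (isinstance(year_min, float) and np.isnan(year_min)):
        return float("nan")
    y0 = float(year_min)
    if year_max is None or (isinstance(year_max, float) and np.isnan(year_max)):
        return y0
    y1 = float(year_max)
    if y1 < y0:
        raise ValueError(f"reversed collection-year range ({y0}, {y1})")
    return (y0 + y1) / 2.0


@dataclass
class CohortTable:
    """Donor x analyte concentrations joined to demographics.

    ``data`` is tidy (one row per donor x analyte: conc, censored, mdl);
    ``donors`` has one row per donor (age, sex, health, year_min/year_max
    plus the resolved ``year``).  Every concentration cell carries its MDL,
    so censored cells can be substituted unambiguously.
    """

    data: pd.DataFrame
    donors: pd.DataFrame

    def __post_init__(self) -> None:
        if self.donors["donor_id"].duplicated().any():
            dupes = self.donors.loc[self.donors["donor_id"].duplicated(), "donor_id"].tolist()
            raise ValueError(f"duplicate donor_id rows: {dupes}")
        if "year" not in self.donors.columns:
            self.donors = self.donors.copy()
            self.donors["year"] = [
                resolve_year(r.get("year_min"), r.get("year_max"))
                for _, r in self.donors.iterrows()
            ]
        if "year_exact" not in self.donors.columns:
            self.donors = self.donors.copy()
            if {"year_min", "year_max"} <= set(self.donors.columns):
                self.donors["year_exact"] = (
                    self.donors["year_min"].notna()
                    & (self.donors["year_min"] == self.donors["year_max"])
                )
            else:
                # fallback: integral resolved years count as exact
                self.donors["year_exact"] = (
                    self.donors["year"].notna()
                    & (self.donors["year"] == self.donors["year"].round())
                )
        missing_mdl = self.data["censored"].astype(bool) & ~(self.data["mdl"] > 0)
        if missing_mdl.any():
            bad = self.data.loc[missing_mdl, ["sample_id", "analyte_name"]].iloc[0]
            raise ValueError(
                f"censored cell without a valid MDL: {bad['sample_id']}/{bad['analyte_name']}"
            )

    @classmethod
    def from_frames(cls, concentrations: pd.DataFrame, donors: pd.DataFrame) -> "CohortTable":
        """Build from a concentrations table (sample_id keyed by donor) and metadata."""
        data = concentrations.rename(columns={"sample_id": "sample_id"}).copy()
        keep = donors[donors["donor_id"].isin(data["sample_id"].unique())].copy()
        return cls(data=data, donors=keep.reset_index(drop=True))

    @property
    def analytes(self) -> list[str]:
        return sorted(self.data["analyte_name"].unique())

    @property
    def n_donors(self) -> int:
        return len(self.donors)

    def wide(self, values: str = "conc") -> pd.DataFrame:
        return self.data.pivot(index="sample_id", columns="analyte_name", values=values)

    # thin method façades over the module functions
    def substituted(self) -> pd.DataFrame:
        return substitute_nondetects(self)

    def detection_frequencies(self) -> pd.Series:
        return detection_frequency(self)

    def sums(self, mode: str = "detected_only") -> pd.Series:
        return sum_pfas(self, mode=mode)


def table_from_truth(truth: pd.DataFrame, cohort: pd.DataFrame, mdls=None) -> CohortTable:
    """Cohort table straight from a true-concentration matrix.

    Bypasses the instrument layer: each cell is censored at the supplied MDL
    (dict/Series per analyte, scalar, or effectively none) and otherwise
    taken as measured.  Useful for statistical simulations where the
    quantification chain is not under study.
    """
    rows = []
    for donor_id in truth.index:
        for analyte in truth.columns:
            v = float(truth.at[donor_id, analyte])
            mdl = 1e-9 if mdls is None else (mdls if np.isscalar(mdls) else mdls[analyte])
            censored = v <= mdl
            rows.append(
                {
                    "sample_id": donor_id,
                    "analyte_name": analyte,
                    "conc": float("nan") if censored else v,
                    "mdl": mdl,
                    "censored": censored,
                }
            )
    return CohortTable.from_frames(pd.DataFrame(rows), cohort)


def substitute_nondetects(table: CohortTable) -> pd.DataFrame:
    """Numeric donor x analyte matrix with censored cells at MDL/2.

    Detected cells pass through unchanged; nondetects take half their MDL,
    the expected value of a uniform distribution between zero and the MDL.
    A censored cell with no valid MDL is an error (enforced at table
    construction).  Substitution can only raise a cell (ND cells hold NaN
    beforehand), never lower a detected one.
    """
    conc = table.wide("conc")
    cens = table.wide("censored").astype(bool)
    mdl = table.wide("mdl")
    if (cens & ~(mdl > 0)).any().any():
        raise ValueError("censored cell with missing/zero MDL")
    return conc.where(~cens, mdl / 2.0)


def detection_frequency(table: CohortTable, analyte: str | None = None):
    """Percent of donors with a detected (uncensored) value, in [0, 100]."""
    det = (~table.wide("censored").astype(bool)).mean(axis=0) * 100.0
    det.name = "detection_frequency_pct"
    if analyte is not None:
        return float(det[analyte])
    return det


def sum_pfas(table: CohortTable, mode: str = "detected_only") -> pd.Series:
    """Per-donor sum of PFAS concentrations (ng/g), branched and linear counted separately.

    ``detected_only`` sums uncensored values (the trend-plot convention);
    ``substituted`` sums the MDL/2-filled matrix (the regression input) and
    is therefore never smaller.  All-ND donors sum to 0 in detected_only
    mode and are flagged for exclusion from log-scale analyses.
    """
    if mode == "detected_only":
        conc = table.wide("conc")
        s = conc.fillna(0.0).sum(axis=1)
        n_zero = int((s <= 0).sum())
        if n_zero:
            logger.warning(
                "%d donor(s) with no detected analytes: sum is 0 and will be "
                "dropped from log-scale analyses", n_zero,
            )
    elif mode == "substituted":
        s = substitute_nondetects(table).sum(axis=1)
    else:
        raise ValueError(f"unknown sum mode {mode!r}")
    s.name = f"sum_pfas_{mode}"
    return s


def class_composition(
    table: CohortTable,
    panel: Panel,
    year: float | None = None,
    mode: str = "detected_only",
) -> pd.DataFrame:
    """Chemical-class mixture profile by collection year.

    For each exact-year cohort slice: concentrations are summed within each
    chemical class per donor, averaged across that year's donors (the
    per-year mean), and normalized so the class shares sum to 100%.
    Returns a tidy frame (year, chem_class, mean_conc, share_pct); an empty
    frame for a year with no samples.
    """
    cls_of = {a.name: a.chem_class for a in panel}
    conc = table.wide("conc") if mode == "detected_only" else substitute_nondetects(table)
    conc = conc.fillna(0.0)
    unknown = [c for c in conc.columns if c not in cls_of]
    if unknown:
        raise ValueError(f"analytes not in panel: {unknown}")
    by_class = conc.T.groupby(pd.Series(cls_of).reindex(conc.columns)).sum().T

    donors = table.donors.set_index("donor_id")
    yr = donors["year"].reindex(by_class.index)
    exact = donors["year_exact"].reindex(by_class.index).fillna(False).astype(bool)
    by_class = by_class[exact.to_numpy()]
    yr = yr[exact]

    years = [year] if year is not None else sorted(yr.unique())
    rows = []
    for y in years:
        sl = by_class[yr == y]
        if sl.empty:
            continue
        means = sl.mean(axis=0)
        total = means.sum()
        for c, m in means.items():
            rows.append(
                {
                    "year": float(y),
                    "chem_class": c,
                    "mean_conc": float(m),
                    "share_pct": float(100.0 * m / total) if total > 0 else float("nan"),
                    "n_samples": len(sl),
                }
            )
    return pd.DataFrame(rows, columns=["year", "chem_class", "mean_conc", "share_pct", "n_samples"])


def period_summary(
    values: pd.Series | np.ndarray,
    years: pd.Series | np.ndarray | None = None,
    period: tuple[float, float] | None = None,
) -> dict:
    """Median, IQR, range and fold range of per-donor sums within a period.

    ``values`` may be pre-filtered (then ``years``/``period`` are omitted)
    or filtered here by inclusive year bounds.  ``fold_range`` is max/min,
    invariant under common rescaling of all values; it is undefined (NaN)
    when the period minimum is 0.
    """
    v = np.asarray(values, dtype=float)
    if period is not None:
        if years is None:
            raise ValueError("period filtering requires years")
        y = np.asarray(years, dtype=float)
        mask = (y >= period[0]) & (y <= period[1])
        v = v[mask]
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no samples in period")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # linear interpolation
    vmin, vmax = float(v.min()), float(v.max())
    fold = vmax / vmin if vmin > 0 else float("nan")
    if vmin <= 0:
        logger.warning("period minimum is 0: fold range undefined")
    return {
        "n": int(v.size),
        "median": float(med),
        "iqr_low": float(q1),
        "iqr_high": float(q3),
        "min": vmin,
        "max": vmax,
        "fold_range": float(fold),
    }
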