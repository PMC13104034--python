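"""Extractable organofluorine (EOF) mass balance.

Combustion ion chromatography measures total fluoride in an organic tissue
extract (ng F/g).  Converting the targeted LC-HRMS concentrations to
fluorine equivalents (concentration x fluorine mass fraction) and comparing
against EOF bounds how much of the organofluorine burden the targeted panel
explains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import Panel, fluorine_mass_fraction

__all__ = [
    "MassBalanceResult",
    "eof_blank_correct",
    "eof_mdl",
    "targeted_fluorine_equivalent",
    "mass_balance",
    "mass_balance_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MassBalanceResult:
    """EOF vs targeted fluorine equivalents for one sample (ng F/g)."""

    eof: float
    targeted_f: float
    fraction_explained_pct: float
    unexplained: float
    fold_gap: float


def eof_blank_correct(reading: float, di_blank_mean: float) -> tuple[float, bool]:
    """Subtract the batch DI-water blank mean from a fluoride reading.

    Applied only when the reading exceeds the instrumental background (the
    blank mean); otherwise the value is floored at 0 and flagged censored.
    Returns (corrected ng F/g, censored flag); never negative.
    """
    if di_blank_mean < 0:
        raise ValueError("blank mean must be >= 0")
    if reading > di_blank_mean:
        return reading - di_blank_mean, False
    return 0.0, True


def eof_mdl(matrix_blanks, dilution_factor: float = 1.0) -> float:
    """EOF method detection limit: 3 x SD of matrix extraction blanks x dilution."""
    blanks = np.asarray(list(matrix_blanks), dtype=float)
    if blanks.size < 2:
        raise ValueError(f"EOF MDL needs >= 2 matrix blanks, got {blanks.size}")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    return float(3.0 * blanks.std(ddof=1) * dilution_factor)


def targeted_fluorine_equivalent(
    concentrations: pd.Series | dict,
    panel: Panel,
    censored: pd.Series | dict | None = None,
    mdls: pd.Series | dict | None = None,
    nd_mode: str = "zero",
) -> float:
    """Sum of fluorine equivalents (ng F/g) over the targeted analytes.

    Each concentration is weighted by its analyte's fluorine mass fraction
    from the registry.  Censored analytes contribute 0 by default (a
    lower-bound mass balance) or MDL/2 with ``nd_mode="mdl2"``.
    """
    if nd_mode not in ("zero", "mdl2"):
        raise ValueError(f"unknown nd_mode {nd_mode!r}")
    conc = pd.Series(concentrations, dtype=float)
    cens = pd.Series(censored).astype(bool) if censored is not None else pd.Series(False, index=conc.index)
    total = 0.0
    for name, c in conc.items():
        frac = fluorine_mass_fraction(panel.get(name))  # KeyError for unknown analyte
        if cens.get(name, False) or np.isnan(c):
            if nd_mode == "mdl2":
                if mdls is None:
                    raise ValueError("nd_mode='mdl2' requires MDLs")
                total += float(pd.Series(mdls)[name]) / 2.0 * frac
        else:
            total += float(c) * frac
    return total


def mass_balance(eof: float, targeted_f: float) -> MassBalanceResult:
    """Fraction of the EOF explained by targeted PFAS.

    fraction = 100 x targeted/EOF; fold gap = EOF/targeted (NaN when the
    targeted total is 0).  A targeted total exceeding the EOF yields a
    fraction above 100% with a data-quality warning rather than an error.
    """
    if eof <= 0:
        raise ValueError("EOF must be > 0 for a mass balance")
    if targeted_f < 0:
        raise ValueError("targeted fluorine equivalent must be >= 0")
    frac = 100.0 * targeted_f / eof
    if frac > 100.0:
        logger.warning(
            "targeted fluorine (%.3g) exceeds EOF (%.3g): fraction %.1f%% > 100%%",
            targeted_f, eof, frac,
        )
    return MassBalanceResult(
        eof=float(eof),
        targeted_f=float(targeted_f),
        fraction_explained_pct=float(frac),
        unexplained=float(max(eof - targeted_f, 0.0)),
        fold_gap=float(eof / targeted_f) if targeted_f > 0 else float("nan"),
    )


def mass_balance_table(
    eof_measurements: pd.DataFrame,
    concentrations: pd.DataFrame,
    panel: Panel,
    match: pd.DataFrame | None = None,
    nd_mode: str = "zero",
) -> pd.DataFrame:
    """Per-donor mass balance from raw EOF readings and targeted concentrations.

    EOF specimens are blank-corrected against the batch DI blanks and
    compared against the batch MDL (3 x SD of matrix blanks x dilution).
    Donor matching is by explicit sample_id, or through a ``match`` frame
    with columns (eof_sample_id, targeted_sample_id); no fuzzy matching.
    """
    rows = []
    lookup = None
    if match is not None:
        lookup = dict(zip(match["eof_sample_id"], match["targeted_sample_id"]))
    conc_by_sample = dict(tuple(concentrations.groupby("sample_id")))
    for batch_id, bdf in eof_measurements.groupby("batch_id"):
        di = bdf.loc[bdf["role"] == "di_blank", "fluoride_reading"]
        if di.empty:
            raise ValueError(f"EOF batch {batch_id}: no DI blanks for correction")
        matrix = bdf.loc[bdf["role"] == "matrix_blank", "fluoride_reading"]
        for r in bdf[bdf["role"] == "specimen"].itertuples():
            corrected, censored = eof_blank_correct(r.fluoride_reading, float(di.mean()))
            mdl = eof_mdl(matrix, r.dilution_factor) if len(matrix) >= 2 else float("nan")
            target_id = lookup.get(r.sample_id, r.sample_id) if lookup else r.sample_id
            sub = conc_by_sample.get(target_id)
            if sub is None:
                logger.warning("EOF sample %s: no matched targeted record", r.sample_id)
                continue
            targeted = targeted_fluorine_equivalent(
                sub.set_index("analyte_name")["conc"],
                panel,
                censored=sub.set_index("analyte_name")["censored"],
                mdls=sub.set_index("analyte_name")["mdl"],
                nd_mode=nd_mode,
            )
            if censored or corrected <= 0:
                logger.warning("EOF sample %s below instrumental background", r.sample_id)
                continue
            mb = mass_balance(corrected, targeted)
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "batch_id": batch_id,
                    "eof": mb.eof,
                    "eof_mdl": mdl,
                    "below_eof_mdl": bool(mb.eof < mdl) if not np.isnan(mdl) else False,
                    "targeted_f": mb.targeted_f,
                    "fraction_explained_pct": mb.fraction_explained_pct,
                    "unexplained": mb.unexplained,
                    "fold_gap": mb.fold_gap,
                }
            )
    return pd.DataFrame(rows)
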