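"""End-to-end pipeline driver and input validation.

Ties the stages together — synthetic generation (or user-supplied CSVs) ->
isotope-dilution quantification with QA/QC -> cohort assembly -> weighted
temporal trends, covariate regression and EOF mass balance — into one
reproducible run directory with a manifest (config hash, input hashes,
package version).  The run is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import (
    DEFAULT_PERIODS,
    CohortTable,
    class_composition,
    detection_frequency,
    period_summary,
    sum_pfas,
)
from .eof import mass_balance_table
from .mlr import fit_all_mlr
from .quant import quantify_batch
from .registry import Panel, default_panel
from .synth import (
    SimulationParams,
    default_params,
    generate_batches,
    generate_cohort,
    generate_eof_measurements,
    generate_true_concentrations,
    make_calibrations,
)
from .trends import fit_weighted_trend, geometric_mean_at, per_analyte_trends, percent_reduction

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "write_synthetic_inputs"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All run-level knobs, serializable losslessly to/from YAML."""

    out_dir: str = "run"
    seed: int = 0
    panel_path: str | None = None      # None -> built-in default panel
    batch_path: str | None = None      # None -> synthesize
    donors_path: str | None = None
    eof_path: str | None = None
    min_detects: int = 30
    alpha: float = 0.05
    exclusion_fraction: float = 0.75
    recovery_limits: tuple[float, float] = (0.2, 1.5)
    mdl_mode: str = "auto"
    sum_mode_trend: str = "detected_only"
    sum_mode_mlr: str = "substituted"
    eof_nd_mode: str = "zero"
    periods: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_PERIODS.items()}
    )

    def __post_init__(self) -> None:
        if self.min_detects < 0 or not (0 < self.alpha < 1) or not (0 < self.exclusion_fraction <= 1):
            raise ValueError("thresholds out of range")
        lo, hi = self.recovery_limits
        if not (0 < lo < hi):
            raise ValueError("recovery limits must satisfy 0 < lo < hi")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["recovery_limits"] = list(self.recovery_limits)
        d["periods"] = {k: list(v) for k, v in self.periods.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["recovery_limits"] = tuple(d.get("recovery_limits", (0.2, 1.5)))
        d["periods"] = {k: tuple(v) for k, v in d.get("periods", DEFAULT_PERIODS).items()}
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_synthetic_inputs(
    out_dir: str | Path,
    params: SimulationParams | None = None,
    seed: int | None = None,
    panel: Panel | None = None,
) -> dict[str, Path]:
    """Generate and write the synthetic study inputs as CSVs.

    Produces the same schemas the real-data path reads (panel.csv,
    donors.csv, batch.csv, eof.csv, calibration.csv), so synthetic and real
    inputs are interchangeable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = params or default_params()
    if seed is not None:
        params = dataclasses.replace(params, seed=seed)
    panel = panel or default_panel()
    cohort = generate_cohort(params)
    truth = generate_true_concentrations(cohort, params)
    batch = generate_batches(truth, cohort, panel, params)
    eof = generate_eof_measurements(truth, cohort, panel, params)
    cals = make_calibrations(panel, params)
    cal_rows = []
    for name, df in cals.items():
        for _, r in df.iterrows():
            cal_rows.append({"analyte_name": name, "amount_ratio": r["amount_ratio"],
                             "area_ratio": r["area_ratio"],
                             "idl": params.analytes[name].idl if name in params.analytes else 0.01})
    paths = {
        "panel": out / "panel.csv",
        "donors": out / "donors.csv",
        "batch": out / "batch.csv",
        "eof": out / "eof.csv",
        "calibration": out / "calibration.csv",
        "truth": out / "true_concentrations.csv",
    }
    panel.to_csv(paths["panel"])
    cohort.drop(columns=["age_true", "year_true"]).to_csv(paths["donors"], index=False)
    batch.to_csv(paths["batch"], index=False)
    eof.to_csv(paths["eof"], index=False)
    pd.DataFrame(cal_rows).to_csv(paths["calibration"], index=False)
    truth.rename_axis("donor_id").to_csv(paths["truth"])
    return paths


EXPECTED_SCHEMAS: dict[str, dict[str, str]] = {
    "panel": {"name": "str", "chem_class": "str", "formula": "str",
              "n_pfc": "int", "isomer": "str", "eis_name": "str"},
    "donors": {"donor_id": "str", "age": "float", "sex": "str", "health": "str",
               "year_min": "float", "year_max": "float"},
    "batch": {"sample_id": "str", "analyte_name": "str", "role": "str",
              "area_quant": "float", "area_conf": "float", "area_eis": "float",
              "rt_analyte": "float", "rt_eis": "float", "sample_mass": "float",
              "eis_spike": "float", "batch_id": "str"},
    "eof": {"sample_id": "str", "role": "str", "fluoride_reading": "float",
            "batch_id": "str", "dilution_factor": "float"},
}


def validate_inputs(paths: dict[str, str | Path]) -> pd.DataFrame:
    """Per-file, per-column presence/type/range checks.

    Returns a report frame with ``level`` in {"error", "warning"}; missing
    files and missing/non-numeric required columns are errors, out-of-range
    values (negative masses or areas, collection years outside 2000-2024)
    are flagged per row.
    """
    rows: list[dict] = []

    def add(level, file, column, message):
        rows.append({"level": level, "file": str(file), "column": column, "message": message})

    for kind, path in paths.items():
        schema = EXPECTED_SCHEMAS.get(kind)
        if schema is None:
            continue
        path = Path(path)
        if not path.exists():
            add("error", path, "", f"missing input file ({kind})")
            continue
        df = pd.read_csv(path)
        for col, typ in schema.items():
            if col not in df.columns:
                add("error", path, col, "required column missing")
                continue
            if typ in ("float", "int") and not pd.api.types.is_numeric_dtype(df[col]):
                coerced = pd.to_numeric(df[col], errors="coerce")
                if coerced.isna().all():
                    add("error", path, col, "expected numeric values")
        if kind == "batch" and "sample_mass" in df.columns and "role" in df.columns:
            bad = (df["role"] == "specimen") & ~(pd.to_numeric(df["sample_mass"], errors="coerce") > 0)
            for i in df.index[bad]:
                add("error", path, "sample_mass", f"row {i}: specimen with non-positive mass")
        if kind == "batch":
            for col in ("area_quant", "area_conf", "area_eis"):
                if col in df.columns:
                    neg = pd.to_numeric(df[col], errors="coerce") < 0
                    for i in df.index[neg]:
                        add("error", path, col, f"row {i}: negative area")
        if kind == "donors":
            for col in ("year_min", "year_max"):
                if col in df.columns:
                    y = pd.to_numeric(df[col], errors="coerce")
                    out_of_range = y.notna() & ((y < 2000) | (y > 2024))
                    for i in df.index[out_of_range]:
                        add("warning", path, col, f"row {i}: year {y[i]:.0f} outside 2000-2024")
    return pd.DataFrame(rows, columns=["level", "file", "column", "message"])


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and write every stage's outputs.

    Stages: (0) synthesize inputs when none are supplied; (1) validate;
    (2) quantify + QA/QC -> concentrations.csv, qc_report.csv; (3) cohort
    assembly -> cohort.csv, detection_frequency.csv, composition_by_year.csv,
    period_summary.csv; (4) weighted trends -> trend_fits.csv; (5) covariate
    MLR -> mlr_results.csv, mlr_diagnostics.csv; (6) EOF mass balance ->
    mass_balance.csv; plus manifest.json.  Earlier stages' outputs survive a
    later stage's failure.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.batch_path is None:
        synth_paths = write_synthetic_inputs(out / "inputs", seed=config.seed)
        panel_path = synth_paths["panel"]
        batch_path = synth_paths["batch"]
        donors_path = synth_paths["donors"]
        eof_path = synth_paths["eof"]
        cal_path = synth_paths["calibration"]
    else:
        panel_path = Path(config.panel_path) if config.panel_path else None
        batch_path = Path(config.batch_path)
        donors_path = Path(config.donors_path) if config.donors_path else None
        eof_path = Path(config.eof_path) if config.eof_path else None
        cal_path = batch_path.parent / "calibration.csv"

    inputs = {k: p for k, p in
              [("panel", panel_path), ("batch", batch_path), ("donors", donors_path), ("eof", eof_path)]
              if p is not None}
    report = validate_inputs(inputs)
    report.to_csv(out / "validation_report.csv", index=False)
    errors = report[report["level"] == "error"]
    if not errors.empty:
        raise ValueError(
            "input validation failed:\n" + "\n".join(
                f"  {r.file}:{r.column}: {r.message}" for r in errors.itertuples())
        )

    panel = Panel.from_csv(panel_path) if panel_path else default_panel()
    batch = pd.read_csv(batch_path)
    donors = pd.read_csv(donors_path)

    cal_df = pd.read_csv(cal_path)
    calibrations = {
        name: g[["amount_ratio", "area_ratio"]] for name, g in cal_df.groupby("analyte_name")
    }
    idl = cal_df.groupby("analyte_name")["idl"].first().to_dict()

    conc, qc = quantify_batch(
        batch, panel, calibrations, idl,
        recovery_limits=tuple(config.recovery_limits),
        exclusion_fraction=config.exclusion_fraction,
        mdl_mode=config.mdl_mode,
    )
    conc.to_csv(out / "concentrations.csv", index=False)
    qc.to_csv(out / "qc_report.csv", index=False)

    table = CohortTable.from_frames(conc, donors)
    merged = table.data.merge(table.donors, left_on="sample_id", right_on="donor_id", how="left")
    merged.to_csv(out / "cohort.csv", index=False)
    detection_frequency(table).rename_axis("analyte_name").reset_index().to_csv(
        out / "detection_frequency.csv", index=False)
    class_composition(table, panel).to_csv(out / "composition_by_year.csv", index=False)

    donors_idx = table.donors.set_index("donor_id")
    years = donors_idx["year"]
    sums = sum_pfas(table, mode=config.sum_mode_trend)
    yrs = years.reindex(sums.index)
    exact = donors_idx["year_exact"].reindex(sums.index).fillna(False).astype(bool) & (sums > 0)
    per_rows = []
    for label, (lo, hi) in config.periods.items():
        try:
            summ = period_summary(sums[exact], yrs[exact], (lo, hi))
        except ValueError:
            continue
        per_rows.append({"period": label, **summ})
    pd.DataFrame(per_rows).to_csv(out / "period_summary.csv", index=False)

    trend_rows = []
    try:
        fit = fit_weighted_trend(sums[exact].to_numpy(), yrs[exact].to_numpy())
        y0, y1 = min(yrs[exact]), max(yrs[exact])
        trend_rows.append({
            "analyte_name": "sum", "beta0": fit.beta0, "beta1": fit.beta1,
            "se_beta1": fit.se_beta1, "p_value": fit.p_value, "r2": fit.r2,
            "n_obs": fit.n_obs, "gm_start": geometric_mean_at(fit, y0),
            "gm_end": geometric_mean_at(fit, y1),
            "percent_reduction": percent_reduction(fit, y0, y1),
            "pct_change_per_decade": fit.pct_change_per_decade, "label": "",
        })
    except ValueError as exc:
        logger.warning("sum trend skipped: %s", exc)
    per_analyte = per_analyte_trends(table, alpha=config.alpha)
    pd.concat([pd.DataFrame(trend_rows), per_analyte], ignore_index=True).to_csv(
        out / "trend_fits.csv", index=False)

    mlr_results, mlr_diag = fit_all_mlr(table, min_detects=config.min_detects, alpha=config.alpha)
    mlr_results.to_csv(out / "mlr_results.csv", index=False)
    mlr_diag.to_csv(out / "mlr_diagnostics.csv", index=False)

    if eof_path is not None and Path(eof_path).exists():
        eof_df = pd.read_csv(eof_path)
        mb = mass_balance_table(eof_df, conc, panel, nd_mode=config.eof_nd_mode)
        mb.to_csv(out / "mass_balance.csv", index=False)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "input_sha256": {k: _sha256(Path(p)) for k, p in inputs.items() if Path(p).exists()},
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
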