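"""End-to-end orchestration: read and join input files, preprocess every
well, fit curves, extract metrics, apply groupings and write the three tidy
output CSVs (measures, summary, quality) plus a run log.

Outputs are deterministic: a persisted :class:`RunConfig` plus the input
bytes fully determine every output byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .fitting import GrowthCurveModel
from .formula import parse_formula, parse_start_values
from .grouping import apply_groups, parse_group_shorthand
from .metrics import METRIC_COLUMNS, group_means
from .model import TidyMeasures, convert_runtime_units, experiment_summary
from .preprocess import PreprocessConfig, PreprocessError, preprocess_well
from .readers import join_experiment

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

#: wells with fewer valid points than this are excluded from fitting
MIN_POINTS = 5

SPLINE_QUALITY = ["spar", "df", "crit", "penalized_rss", "cv.crit"]
PARAM_QUALITY = ["sigma", "isConv", "finTol", "logLik", "AIC", "BIC",
                 "deviance", "df.residual"]


@dataclass
class RunConfig:
    """Everything needed to (re)produce one analysis run."""

    measures: list = field(default_factory=list)
    designs: list = field(default_factory=list)
    unit: str = "seconds"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    method: str = "spline"
    model_formula: Optional[str] = None
    start_values: Optional[str] = None
    grid_size: int = 1000
    groups: Optional[str] = None
    output_dir: str = "."

    def to_yaml(self, path) -> None:
        doc = {
            "measures": [str(p) for p in self.measures],
            "designs": [str(p) for p in self.designs],
            "unit": self.unit,
            "preprocess": self.preprocess.to_dict(),
            "method": self.method,
            "model_formula": self.model_formula,
            "start_values": self.start_values,
            "grid_size": self.grid_size,
            "groups": self.groups,
            "output_dir": str(self.output_dir),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        pp = PreprocessConfig.from_dict(doc.pop("preprocess", {}) or {})
        known = {k: doc[k] for k in cls.__dataclass_fields__ if k in doc}
        known["preprocess"] = pp
        return cls(**known)


@dataclass
class PipelineResult:
    measures: pd.DataFrame
    summary: pd.DataFrame
    quality: pd.DataFrame
    group_means: Optional[pd.DataFrame]
    log: list
    files: dict


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis and write measures.csv, summary.csv and
    quality.csv (plus group_means.csv when a grouping is given) into the
    output directory.  Per-well failures are warnings; the wells are listed
    in the run log and excluded from fitting."""
    log: list[str] = []
    table = join_experiment(list(config.measures) + list(config.designs),
                            unit=config.unit, log=log)
    table = convert_runtime_units(table, config.unit)
    for _, row in experiment_summary(table).iterrows():
        log.append(
            f"run {row['run']}: {row['n_plates']} plate(s), {row['n_wells']} well(s), "
            f"{row['n_measures']} measures"
        )

    model_formula = None
    start = None
    if config.method == "manual":
        if not config.model_formula or not config.start_values:
            raise ValueError("manual method requires model_formula and start_values")
        model_formula = parse_formula(config.model_formula, mode="model")
        start = parse_start_values(config.start_values, list(model_formula.parameters))

    measures_df, summary_df, quality_df = _process_wells(
        table, config, model_formula, start, log
    )

    gm_df = None
    if config.groups:
        shape = table.shared_plate_shape()
        plates = sorted(table.data["plate"].unique())
        specs = parse_group_shorthand(config.groups, shape, plates)
        log.append(f"parsed {len(specs)} group spec(s)")
        measures_df = _grouped_view(measures_df, specs)
        summary_df = _grouped_view(summary_df, specs)
        gm_df = group_means(summary_df)

    files = _write_outputs(config, measures_df, summary_df, quality_df, gm_df, log)
    return PipelineResult(measures_df, summary_df, quality_df, gm_df, log, files)


def _process_wells(table: TidyMeasures, config: RunConfig, model_formula, start, log):
    design_cols = sorted(table.design_columns)
    opt_cols = [c for c in ("datetime", "measure_type") if c in table.data.columns]
    measures_rows = []
    summary_rows = []
    quality_rows = []
    for (run, plate, well), sub in table.data.groupby(["run", "plate", "well"], sort=True):
        x = sub["runtime"].to_numpy(float)
        y_raw = sub["measure"].to_numpy(float)
        design = {c: sub[c].iloc[0] for c in design_cols}
        failed = None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                y_pre = preprocess_well(y_raw, x, config.preprocess)
        except PreprocessError as e:
            failed = f"preprocessing failed: {e}"
            y_pre = np.full_like(y_raw, np.nan)

        base = {"run": run, "plate": plate, "well": well}
        for i in range(len(x)):
            row = dict(base)
            row["runtime"] = x[i]
            for c in opt_cols:
                row[c] = sub[c].iloc[i]
            row["measure_raw"] = y_raw[i]
            row["measure_preprocessed"] = y_pre[i]
            row.update(design)
            measures_rows.append(row)

        if failed is None:
            ok = np.isfinite(y_pre)
            if ok.sum() < MIN_POINTS:
                failed = f"only {int(ok.sum())} valid points after preprocessing"
        if failed is not None:
            log.append(f"well {run}/{plate}/{well} skipped: {failed}")
            warnings.warn(f"well {run}/{plate}/{well} skipped: {failed}")
            continue

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = GrowthCurveModel(
                    x[ok], y_pre[ok], method=config.method,
                    formula=model_formula, start=start,
                )
                fit = model.fit()
                m = fit.metrics(grid_size=config.grid_size,
                                log_base=config.preprocess.log_base)
        except Exception as e:
            log.append(f"well {run}/{plate}/{well} fit failed: {e}")
            warnings.warn(f"well {run}/{plate}/{well} fit failed: {e}")
            continue
        if not fit.converged:
            log.append(f"well {run}/{plate}/{well}: fit did not converge")

        srow = dict(base)
        srow["method"] = config.method
        srow.update(m.to_dict())
        for name, value in fit.params.items():
            if name not in srow:
                srow[name] = value
        srow.update(design)
        summary_rows.append(srow)

        qrow = dict(base)
        qrow["method"] = config.method
        qrow.update(fit.quality)
        quality_rows.append(qrow)

    measures_df = pd.DataFrame(measures_rows)
    measures_df = measures_df[
        ["run", "plate", "well", "runtime", *opt_cols,
         "measure_raw", "measure_preprocessed", *design_cols]
    ]
    summary_df = pd.DataFrame(summary_rows)
    if not summary_df.empty:
        extra_params = [
            c for c in summary_df.columns
            if c not in ("run", "plate", "well", "method", *METRIC_COLUMNS, *design_cols)
        ]
        summary_df = summary_df[
            ["run", "plate", "well", "method", *METRIC_COLUMNS, *extra_params, *design_cols]
        ]
    quality_df = pd.DataFrame(quality_rows)
    if not quality_df.empty:
        qcols = SPLINE_QUALITY if config.method == "spline" else PARAM_QUALITY
        quality_df = quality_df[["run", "plate", "well", "method", *qcols]]
    return measures_df, summary_df, quality_df


def _grouped_view(df: pd.DataFrame, specs) -> pd.DataFrame:
    if df.empty:
        return df
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return apply_groups(df, specs)


def _write_outputs(config, measures_df, summary_df, quality_df, gm_df, log) -> dict:
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, df in (
        ("measures", measures_df),
        ("summary", summary_df),
        ("quality", quality_df),
        ("group_means", gm_df),
    ):
        if df is None:
            continue
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, lineterminator="\n")
        files[name] = path
        log.append(f"wrote {path} ({len(df)} rows)")
    log_path = out_dir / "run.log"
    log_path.write_text("\n".join(log) + "\n", encoding="utf-8")
    files["log"] = log_path
    return files
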