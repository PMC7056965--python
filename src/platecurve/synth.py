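"""Seeded synthetic plate experiments: sigmoid truth curves with baseline
offsets, Gaussian noise and single-cycle spike artifacts, plus design
variables, emitted in every supported file dialect.

The default configuration emulates a chemical-genetic screening run: one
96-well (8 x 12) plate read every 15 minutes for 94 cycles, with three yeast
strains crossed with two compounds over an eight-step two-fold dilution
series from 50 uM down to 0, in a baseline-offset OD-like signal.  Dose
inhibits the drawn growth rate smoothly, so the design variables have a real
(and recoverable) effect on the curves.

Reproducibility contract: the same SimConfig always produces byte-identical
files.  Each well draws from its own random substream keyed by
(seed, run, plate, well), so changing plate size or well order never changes
another well's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .fitting import NAMED_MODELS
from .formula import parse_formula, eval_model_formula
from .model import PlateShape, TidyMeasures, WellLabel

__all__ = ["SimConfig", "SimExperiment", "simulate_experiment", "emit_fixture_files",
           "BRODY_FORMULA"]

#: The Brody (mono-molecular) growth model, usable as a manual-mode truth.
BRODY_FORMULA = "y ~ a - (a - w0) * exp(-k * x)"


def _two_fold_series(top: float, steps: int) -> list[float]:
    """Two-fold dilution from ``top`` down to 0 (the last step is the blank)."""
    return [top / 2**i for i in range(steps - 1)] + [0.0]


@dataclass
class SimConfig:
    seed: int = 0
    n_runs: int = 1
    n_plates: int = 1
    shape: PlateShape = field(default_factory=lambda: PlateShape(n_rows=8, n_cols=12))
    n_cycles: int = 94
    interval: float = 900.0  # seconds between cycles (15 min)
    truth_model: str = "gompertz"  # gompertz | logistic | richards | brody
    # uniform parameter ranges (units: measure units, per second, seconds)
    A_range: tuple[float, float] = (0.8, 1.2)
    mu_range: tuple[float, float] = (5e-5, 2e-4)
    lambda_range: tuple[float, float] = (5_000.0, 20_000.0)
    nu_range: tuple[float, float] = (0.5, 2.0)
    baseline: float = 0.08
    noise_sd: float = 0.01
    spike_prob: float = 0.0
    spike_height: float = 0.3
    # design variables cycled over wells in row-major order
    strains: tuple[str, ...] = ("BY4743", "opi3", "swd3")
    drugs: tuple[str, ...] = ("cmpd1", "cmpd2")
    doses: tuple[float, ...] = field(default_factory=lambda: tuple(_two_fold_series(50.0, 8)))
    dose_ic50: float = 25.0  # uM at which growth rate is halved

    def __post_init__(self) -> None:
        if self.truth_model not in (*NAMED_MODELS, "brody"):
            raise ValueError(f"unknown truth model {self.truth_model!r}")
        if self.noise_sd < 0 or not (0 <= self.spike_prob <= 1):
            raise ValueError("noise_sd must be >= 0 and spike_prob in [0, 1]")
        for lo, hi in (self.A_range, self.mu_range, self.lambda_range, self.nu_range):
            if not (0 < lo <= hi):
                raise ValueError("parameter ranges must be positive and ordered")


@dataclass
class SimExperiment:
    config: SimConfig
    measures: TidyMeasures
    truth: pd.DataFrame


def _well_rng(seed: int, run: str, plate: str, well: str) -> np.random.Generator:
    key = zlib.crc32(f"{run}/{plate}/{well}".encode())
    return np.random.default_rng([seed, key])


def _plate_wells(shape: PlateShape) -> list[str]:
    if shape.is_numeric:
        return [str(i) for i in range(1, shape.n_numeric_wells + 1)]
    return [
        str(WellLabel(row=r, col=c))
        for r in shape.row_letters()
        for c in range(1, shape.n_cols + 1)
    ]

_BRODY = parse_formula(BRODY_FORMULA, mode="model")


def _truth_curve(model: str, t: np.ndarray, p: dict[str, float]) -> np.ndarray:
    if model == "brody":
        # reuse A as the asymptote a; w0 and k derived from the draws
        params = {"a": p["A"], "w0": 0.1 * p["A"], "k": p["mu"] / p["A"]}
        return eval_model_formula(_BRODY, t, params)
    spec = NAMED_MODELS[model]
    args = [p["A"], p["mu"], p["lambda"]] + ([p["nu"]] if "nu" in spec["params"] else [])
    return spec["fn"](t, *args)


def simulate_experiment(config: SimConfig) -> SimExperiment:
    """Draw per-well truth parameters and generate noisy measures.

    y(t) = baseline + model(t; params) + N(0, noise_sd), with an additive
    spike of ``spike_height`` at each cycle independently with probability
    ``spike_prob``.  Dose scales the drawn growth rate by 1/(1 + dose/IC50).
    """
    t = np.arange(config.n_cycles, dtype=float) * config.interval
    wells = _plate_wells(config.shape)
    combos = [
        (s, d, dose) for s in config.strains for d in config.drugs for dose in config.doses
    ]
    rows = []
    truth_rows = []
    for run_i in range(1, config.n_runs + 1):
        run = f"run{run_i}"
        for plate_i in range(1, config.n_plates + 1):
            plate = str(plate_i)
            for w_i, well in enumerate(wells):
                strain, drug, dose = combos[w_i % len(combos)]
                rng = _well_rng(config.seed, run, plate, well)
                p = {
                    "A": rng.uniform(*config.A_range),
                    "mu": rng.uniform(*config.mu_range),
                    "lambda": rng.uniform(*config.lambda_range),
                    "nu": rng.uniform(*config.nu_range),
                }
                p["mu"] *= 1.0 / (1.0 + dose / config.dose_ic50)
                y = config.baseline + _truth_curve(config.truth_model, t, p)
                if config.noise_sd > 0:
                    y = y + rng.normal(0.0, config.noise_sd, size=y.shape)
                if config.spike_prob > 0:
                    spikes = rng.random(y.shape) < config.spike_prob
                    y = y + np.where(spikes, config.spike_height, 0.0)
                for ti, yi in zip(t, y):
                    rows.append((run, plate, well, ti, yi, strain, drug, dose))
                truth_rows.append(
                    {"run": run, "plate": plate, "well": well, **p,
                     "baseline": config.baseline,
                     "strain": strain, "drug": drug, "dose_uM": dose}
                )
    df = pd.DataFrame(
        rows, columns=["run", "plate", "well", "runtime", "measure",
                       "strain", "drug", "dose_uM"]
    )
    measures = TidyMeasures(df, unit="seconds",
                            design_columns=["strain", "drug", "dose_uM"])
    return SimExperiment(config=config, measures=measures, truth=pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# File emission


def _fmt(v: float) -> str:
    return repr(float(v))


def _hms(seconds: float) -> str:
    s = int(round(seconds))
    return f"{s // 3600}:{(s % 3600) // 60:02d}:{s % 60:02d}"


def emit_fixture_files(sim: SimExperiment, dialect: str, out_dir) -> list[Path]:
    """Write the simulated experiment to ``out_dir`` in ``dialect``
    (long_csv | wide_csv | bioscreen), one measures file per run plus a
    matching design file named <run>_design.csv.

    Design files use the plater layout for grid-shaped plates and generic
    CSV for numbered wells.  Parsing the emitted files recovers the original
    TidyMeasures.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = sim.config
    written: list[Path] = []
    df = sim.measures.data
    for run, run_df in df.groupby("run", sort=True):
        mpath = out_dir / f"{run}.csv"
        if dialect == "long_csv":
            _emit_long(run_df, mpath)
        elif dialect == "wide_csv":
            if cfg.n_plates != 1 or cfg.shape.is_numeric:
                raise ValueError("wide_csv emission supports a single grid-shaped plate")
            _emit_wide(run_df, mpath, time_fmt=_fmt)
        elif dialect == "bioscreen":
            if not cfg.shape.is_numeric or cfg.n_plates > 2:
                raise ValueError("bioscreen emission needs numbered wells on <= 2 plates")
            _emit_bioscreen(run_df, mpath)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        written.append(mpath)
        dpath = out_dir / f"{run}_design.csv"
        truth = sim.truth[sim.truth["run"] == run]
        if cfg.shape.is_numeric:
            _emit_design_csv(truth, dpath)
        else:
            _emit_design_plater(truth, cfg.shape, dpath)
        written.append(dpath)
    return written


def _emit_long(run_df: pd.DataFrame, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("run,plate,well,runtime,measure\n")
        for r in run_df.itertuples(index=False):
            fh.write(f"{r.run},{r.plate},{r.well},{_fmt(r.runtime)},{_fmt(r.measure)}\n")


def _emit_wide(run_df: pd.DataFrame, path: Path, time_fmt) -> None:
    wide = run_df.pivot(index="runtime", columns="well", values="measure").sort_index()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("time," + ",".join(wide.columns) + "\n")
        for t, row in wide.iterrows():
            cells = ["" if pd.isna(v) else _fmt(v) for v in row]
            fh.write(time_fmt(t) + "," + ",".join(cells) + "\n")


def _emit_bioscreen(run_df: pd.DataFrame, path: Path) -> None:
    df = run_df.copy()
    df["bwell"] = [
        int(w) if p == "1" else int(w) + 100 for p, w in zip(df["plate"], df["well"])
    ]
    wide = df.pivot(index="runtime", columns="bwell", values="measure").sort_index()
    wide = wide[sorted(wide.columns)]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("Time," + ",".join(str(c) for c in wide.columns) + "\n")
        for t, row in wide.iterrows():
            cells = ["" if pd.isna(v) else _fmt(v) for v in row]
            fh.write(_hms(t) + "," + ",".join(cells) + "\n")


def _emit_design_plater(truth: pd.DataFrame, shape: PlateShape, path: Path) -> None:
    variables = ["strain", "drug", "dose_uM"]
    # the design layout is identical on every plate by construction
    by_well = truth.drop_duplicates("well").set_index("well")
    cols = list(range(1, shape.n_cols + 1))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for b_i, var in enumerate(variables):
            if b_i:
                fh.write("\n")
            fh.write(var + "," + ",".join(str(c) for c in cols) + "\n")
            for letter in shape.row_letters():
                cells = []
                for c in cols:
                    well = f"{letter}{c:02d}"
                    v = by_well[var].get(well, "")
                    cells.append("" if v == "" else str(v))
                fh.write(letter + "," + ",".join(cells) + "\n")


def _emit_design_csv(truth: pd.DataFrame, path: Path) -> None:
    cols = ["plate", "well", "strain", "drug", "dose_uM"]
    truth[cols].to_csv(path, index=False, lineterminator="\n")
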