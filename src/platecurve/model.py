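"""Canonical data model for plate-based growth-curve experiments.

An experiment is a hierarchy Run ⊇ Plate ⊇ Well ⊇ Measures: every observation
belongs to exactly one run, plate and well.  The canonical in-memory container
is :class:`TidyMeasures`, a thin wrapper around a long-format pandas DataFrame
with one row per (run, plate, well, runtime) observation plus optional design
columns that are constant within a well.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "WellLabel",
    "PlateShape",
    "TidyMeasures",
    "normalize_well_label",
    "convert_runtime_units",
    "experiment_summary",
    "RUNTIME_UNITS",
]

#: Allowed runtime units and their length in seconds.
RUNTIME_UNITS = {"seconds": 1.0, "minutes": 60.0, "hours": 3600.0}

_GRID_LABEL_RE = re.compile(r"^([A-Pa-p])([0-9]{1,2})$")
_NUMERIC_LABEL_RE = re.compile(r"^[0-9]+$")

#: Standard plate sizes: wells -> (rows, cols).
STANDARD_SHAPES = [(12, (3, 4)), (24, (4, 6)), (48, (6, 8)), (96, (8, 12)), (384, (16, 24))]


class LabelError(ValueError):
    """Raised for malformed well labels."""


@dataclass(frozen=True, order=True)
class WellLabel:
    """A well position, either grid-style (row letter + column) or numeric.

    Grid labels render canonically as the uppercase row letter followed by the
    zero-padded two-digit column ("A1" normalizes to "A01").  Numeric labels
    (instruments with numbered wells, e.g. Bioscreen honeycomb plates) render
    without padding.  Equality is equality of canonical renderings.
    """

    row: Optional[str] = None
    col: Optional[int] = None
    numeric_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.numeric_id is None:
            if self.row is None or self.col is None:
                raise LabelError("grid well label needs both row and col")
            if not ("A" <= self.row <= "P") or not (1 <= self.col <= 24):
                raise LabelError(f"well label out of range: {self.row}{self.col}")
        elif self.row is not None or self.col is not None:
            raise LabelError("well label cannot be both numeric and grid-style")

    @property
    def is_numeric(self) -> bool:
        return self.numeric_id is not None

    def __str__(self) -> str:
        if self.is_numeric:
            return str(self.numeric_id)
        return f"{self.row}{self.col:02d}"

    def __repr__(self) -> str:  # pragma: no cover - debugging nicety
        return f"WellLabel({str(self)!r})"


def normalize_well_label(text: str | WellLabel | int) -> WellLabel:
    """Parse ``text`` into a canonical :class:`WellLabel`.

    Accepts grid labels like ``"a1"``/``"H12"`` (letter A-P, column 1-24) and
    bare integers for numbered wells.

    >>> str(normalize_well_label("a1"))
    'A01'
    """
    if isinstance(text, WellLabel):
        return text
    if isinstance(text, (int, np.integer)):
        return WellLabel(numeric_id=int(text))
    s = str(text).strip()
    m = _GRID_LABEL_RE.match(s)
    if m:
        return WellLabel(row=m.group(1).upper(), col=int(m.group(2)))
    if _NUMERIC_LABEL_RE.match(s):
        return WellLabel(numeric_id=int(s))
    raise LabelError(f"malformed well label: {text!r}")


@dataclass(frozen=True)
class PlateShape:
    """Rectangular plate geometry, or a numbered-well count.

    Inferred shapes are the smallest standard plate (12, 24, 48, 96 or 384
    wells) covering every observed label.
    """

    n_rows: int = 0
    n_cols: int = 0
    n_numeric_wells: int = 0

    @property
    def is_numeric(self) -> bool:
        return self.n_numeric_wells > 0

    @property
    def n_wells(self) -> int:
        return self.n_numeric_wells if self.is_numeric else self.n_rows * self.n_cols

    def contains(self, label: WellLabel) -> bool:
        if label.is_numeric:
            return self.is_numeric and 1 <= label.numeric_id <= self.n_numeric_wells
        if self.is_numeric:
            return False
        return (ord(label.row) - ord("A")) < self.n_rows and label.col <= self.n_cols

    def row_letters(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(self.n_rows)]

    @staticmethod
    def infer(labels: Iterable[WellLabel]) -> "PlateShape":
        labels = list(labels)
        if not labels:
            raise ValueError("cannot infer a plate shape from zero wells")
        if all(lb.is_numeric for lb in labels):
            return PlateShape(n_numeric_wells=max(lb.numeric_id for lb in labels))
        if any(lb.is_numeric for lb in labels):
            raise ValueError("cannot mix numeric and grid-style wells on one plate")
        max_row = max(ord(lb.row) - ord("A") for lb in labels) + 1
        max_col = max(lb.col for lb in labels)
        for _, (r, c) in STANDARD_SHAPES:
            if max_row <= r and max_col <= c:
                return PlateShape(n_rows=r, n_cols=c)
        return PlateShape(n_rows=max_row, n_cols=max_col)


#: Core columns of the tidy table, in canonical order.
KEY_COLUMNS = ["run", "plate", "well", "runtime"]
OPTIONAL_COLUMNS = ["datetime", "measure_type"]


@dataclass
class TidyMeasures:
    """The canonical long table: one row per (run, plate, well, runtime).

    ``data`` holds the columns run, plate, well (canonical label strings),
    runtime (float, in ``unit``), measure (float), plus the optional
    datetime / measure_type columns and any design columns.  Records are kept
    sorted by (run, plate, well, runtime); the key
    (run, plate, well, runtime[, measure_type]) must be unique.
    """

    data: pd.DataFrame
    unit: str = "seconds"
    design_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.unit not in RUNTIME_UNITS:
            raise ValueError(
                f"unknown runtime unit {self.unit!r}; allowed: {sorted(RUNTIME_UNITS)}"
            )
        df = self.data.copy()
        for col in KEY_COLUMNS + ["measure"]:
            if col not in df.columns:
                raise ValueError(f"TidyMeasures is missing required column {col!r}")
        df["run"] = df["run"].astype(str)
        df["plate"] = df["plate"].astype(str)
        df["well"] = [str(normalize_well_label(w)) for w in df["well"]]
        df["runtime"] = pd.to_numeric(df["runtime"])
        df["measure"] = pd.to_numeric(df["measure"])
        if (df["runtime"] < 0).any():
            raise ValueError("runtime must be >= 0")
        key = KEY_COLUMNS + (["measure_type"] if "measure_type" in df.columns else [])
        dup = df.duplicated(subset=key)
        if dup.any():
            first = df.loc[dup, key].iloc[0].to_dict()
            raise ValueError(f"duplicate measure key: {first}")
        df = df.sort_values(key, kind="mergesort").reset_index(drop=True)
        for col in self.design_columns:
            per_well = df.groupby(["run", "plate", "well"], sort=False)[col].nunique(dropna=True)
            if (per_well > 1).any():
                bad = per_well[per_well > 1].index[0]
                raise ValueError(f"design column {col!r} varies within well {bad}")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    def wells(self) -> pd.DataFrame:
        """Distinct (run, plate, well) triples, in sorted order."""
        return self.data[["run", "plate", "well"]].drop_duplicates().reset_index(drop=True)

    def well_series(self, run: str, plate: str, well: str) -> tuple[np.ndarray, np.ndarray]:
        """(runtime, measure) arrays for one well, runtime-ascending."""
        sub = self.data
        sub = sub[(sub["run"] == run) & (sub["plate"] == plate) & (sub["well"] == str(well))]
        return sub["runtime"].to_numpy(float), sub["measure"].to_numpy(float)

    def plate_shape(self, run: str, plate: str) -> PlateShape:
        sub = self.data[(self.data["run"] == run) & (self.data["plate"] == plate)]
        return PlateShape.infer(normalize_well_label(w) for w in sub["well"].unique())

    def shared_plate_shape(self) -> PlateShape:
        """Single shape covering every plate (all plates must be compatible)."""
        return PlateShape.infer(normalize_well_label(w) for w in self.data["well"].unique())


def convert_runtime_units(table: TidyMeasures, to: str) -> TidyMeasures:
    """Rescale the runtime column into unit ``to`` (seconds|minutes|hours)."""
    if to not in RUNTIME_UNITS:
        raise ValueError(f"unknown runtime unit {to!r}; allowed: {sorted(RUNTIME_UNITS)}")
    if to == table.unit:
        return table
    factor = RUNTIME_UNITS[table.unit] / RUNTIME_UNITS[to]
    df = table.data.copy()
    df["runtime"] = df["runtime"] * factor
    return TidyMeasures(df, unit=to, design_columns=list(table.design_columns))


def experiment_summary(table: TidyMeasures) -> pd.DataFrame:
    """Per-run counts: run, n_plates, n_wells (per plate), n_measures."""
    if len(table) == 0:
        raise ValueError("empty experiment")
    rows = []
    for run, sub in table.data.groupby("run", sort=True):
        n_plates = sub["plate"].nunique()
        wells_per_plate = sub.groupby("plate")["well"].nunique()
        rows.append(
            {
                "run": run,
                "n_plates": int(n_plates),
                "n_wells": int(wells_per_plate.max()),
                "n_measures": int(len(sub)),
            }
        )
    return pd.DataFrame(rows)
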