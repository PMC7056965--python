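"""Reading and tidying raw input files.

Two kinds of input exist.  Measures files hold the repeated measures
(growth-curve) data, usually written by the instrument software; design files
hold the experimental variables (strain, drug, dose, ...) for each well,
usually written by the researcher.  Formats are detected from file *content*
(never the filename) by a pluggable reader registry, and every dialect is
parsed to the same canonical :class:`~platecurve.model.TidyMeasures` table.

Built-in measures dialects:

- ``long_csv``: one observation per row with columns well, runtime, measure
  and optional run, plate, measure_type, datetime.
- ``wide_csv``: a time column followed by one column per well label.
- ``bioscreen``: the wide dialect of Bioscreen-style honeycomb instruments —
  a "Time" column in hh:mm:ss plus numbered well columns 1..200, where wells
  1-100 form plate "1" and 101-200 plate "2" (renumbered 1-100).

Design dialects: ``plater_design`` (plate-shaped blocks, one variable per
block) and ``generic_design_csv`` (a well column plus variable columns).

CSV files may be comma- or semicolon-delimited (sniffed) and may carry a
UTF-8 BOM.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .model import (
    RUNTIME_UNITS,
    TidyMeasures,
    normalize_well_label,
)

__all__ = [
    "detect_format",
    "read_measures_long_csv",
    "read_measures_wide_csv",
    "read_measures_bioscreen",
    "read_design_plater",
    "read_design_csv",
    "join_experiment",
    "READER_REGISTRY",
    "register_reader",
    "FormatError",
]


class FormatError(ValueError):
    pass


_HMS_RE = re.compile(r"^(\d+):([0-5]?\d):([0-5]?\d(?:\.\d+)?)$")
_GRID_HEADER_RE = re.compile(r"^[A-Pa-p][0-9]{1,2}$")
_TIMEISH = {"time", "runtime", "t", "time_s", "time_min", "time_h"}


def _read_lines(path, limit: int = 50) -> list[str]:
    with open(path, "r", encoding="utf-8-sig", newline="") as fh:
        return [line.rstrip("\r\n") for _, line in zip(range(limit), fh)]


def _sniff_delimiter(lines: list[str]) -> str:
    head = "\n".join(lines[:5])
    return ";" if head.count(";") > head.count(",") else ","


def _cells(line: str, sep: str) -> list[str]:
    return [c.strip().strip('"') for c in line.split(sep)]


def parse_hms(text: str) -> float:
    """'hh:mm:ss' -> seconds."""
    m = _HMS_RE.match(text.strip())
    if not m:
        raise FormatError(f"not an hh:mm:ss time literal: {text!r}")
    h, mi, s = m.groups()
    return int(h) * 3600.0 + int(mi) * 60.0 + float(s)


def _time_cell_to_seconds(text: str) -> float:
    text = str(text).strip()
    if _HMS_RE.match(text):
        return parse_hms(text)
    return float(text)


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Sniffers — each inspects the first 50 lines and must be mutually exclusive


def _sniff_long_csv(lines: list[str]) -> bool:
    if not lines:
        return False
    header = {h.lower() for h in _cells(lines[0], _sniff_delimiter(lines))}
    return {"well", "runtime", "measure"} <= header


def _sniff_bioscreen(lines: list[str]) -> bool:
    if len(lines) < 2:
        return False
    sep = _sniff_delimiter(lines)
    header = _cells(lines[0], sep)
    if len(header) < 2 or header[0].lower() != "time":
        return False
    if not all(_is_int(h) for h in header[1:] if h):
        return False
    first = _cells(lines[1], sep)[0]
    try:
        _time_cell_to_seconds(first)
        return True
    except (FormatError, ValueError):
        return False


def _sniff_wide_csv(lines: list[str]) -> bool:
    if not lines:
        return False
    sep = _sniff_delimiter(lines)
    header = _cells(lines[0], sep)
    if len(header) < 2 or header[0].lower() not in _TIMEISH:
        return False
    return all(_GRID_HEADER_RE.match(h) for h in header[1:] if h)


def _sniff_plater(lines: list[str]) -> bool:
    if len(lines) < 2:
        return False
    sep = _sniff_delimiter(lines)
    header = _cells(lines[0], sep)
    if len(header) < 2 or not header[0] or header[0].lower() in _TIMEISH:
        return False
    if not all(_is_int(h) for h in header[1:] if h):
        return False
    row0 = _cells(lines[1], sep)[0]
    return bool(re.match(r"^[A-Pa-p]$", row0))


def _sniff_generic_design(lines: list[str]) -> bool:
    if not lines:
        return False
    header = {h.lower() for h in _cells(lines[0], _sniff_delimiter(lines))}
    return "well" in header and not {"runtime", "measure"} <= header and len(header) >= 2


@dataclass
class Reader:
    name: str
    kind: str  # "measures" | "design"
    sniff: Callable[[list[str]], bool]
    parse: Callable


#: Ordered registry of known formats; extend with :func:`register_reader`.
READER_REGISTRY: list[Reader] = []


def register_reader(name: str, kind: str, sniff: Callable, parse: Callable) -> None:
    if any(r.name == name for r in READER_REGISTRY):
        raise ValueError(f"reader {name!r} already registered")
    READER_REGISTRY.append(Reader(name, kind, sniff, parse))


def detect_format(path) -> str:
    """Identify which registered format claims ``path`` (content-based)."""
    lines = _read_lines(path)
    claims = [r.name for r in READER_REGISTRY if r.sniff(lines)]
    if not claims:
        first = lines[0] if lines else "<empty file>"
        raise FormatError(f"unrecognized format for {path}; first line: {first!r}")
    if len(claims) > 1:
        raise FormatError(f"ambiguous format for {path}: claimed by {claims}")
    return claims[0]


# ---------------------------------------------------------------------------
# Measures parsers


def _read_csv(path) -> pd.DataFrame:
    lines = _read_lines(path, limit=5)
    sep = _sniff_delimiter(lines)
    return pd.read_csv(path, sep=sep, encoding="utf-8-sig", dtype=str,
                       skip_blank_lines=True)


def read_measures_long_csv(path, unit: str = "seconds") -> TidyMeasures:
    """Parse a long-format CSV (well, runtime, measure [+ run, plate,
    measure_type, datetime]).

    A missing run column defaults to the file stem; a missing plate column to
    "1".  Runtime values are taken to be in ``unit`` already.
    """
    df = _read_csv(path)
    df.columns = [c.lower() for c in df.columns]
    for col in ("well", "runtime", "measure"):
        if col not in df.columns:
            raise FormatError(f"{path}: long CSV is missing column {col!r}")
    out = pd.DataFrame({"well": df["well"]})
    out.insert(0, "run", df["run"] if "run" in df.columns else Path(path).stem)
    out.insert(1, "plate", df["plate"] if "plate" in df.columns else "1")
    for col in ("runtime", "measure"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based incl. header
            raise FormatError(f"{path}, line {row}: non-numeric {col} {df.loc[bad, col].iloc[0]!r}")
        out[col] = vals
    for opt in ("measure_type", "datetime"):
        if opt in df.columns:
            out[opt] = df[opt]
    out = out.dropna(subset=["measure"])
    return TidyMeasures(out, unit=unit)


def _melt_wide(df: pd.DataFrame, path, unit: str, plate_of, well_of) -> TidyMeasures:
    time_s = df.iloc[:, 0].map(_time_cell_to_seconds).to_numpy(float)
    factor = 1.0 / RUNTIME_UNITS[unit]
    records = []
    stem = Path(path).stem
    for col in df.columns[1:]:
        plate, well = plate_of(col), well_of(col)
        vals = pd.to_numeric(df[col], errors="coerce")
        keep = vals.notna()
        for t, v in zip(time_s[keep.to_numpy()], vals[keep]):
            records.append((stem, plate, well, t * factor, float(v)))
    out = pd.DataFrame(records, columns=["run", "plate", "well", "runtime", "measure"])
    return TidyMeasures(out, unit=unit)


def read_measures_wide_csv(path, unit: str = "seconds") -> TidyMeasures:
    """Parse a wide CSV: first column time (numeric seconds or hh:mm:ss),
    remaining headers well labels.  Blank cells are dropped, not imputed."""
    df = _read_csv(path)
    headers = list(df.columns[1:])
    canon = [str(normalize_well_label(h)) for h in headers]
    dupes = {c for c in canon if canon.count(c) > 1}
    if dupes:
        raise FormatError(f"{path}: repeated well column(s): {sorted(dupes)}")
    return _melt_wide(df, path, unit, plate_of=lambda c: "1",
                      well_of=lambda c: str(normalize_well_label(c)))


def read_measures_bioscreen(path, unit: str = "seconds") -> TidyMeasures:
    """Parse a Bioscreen-style wide file ("Time" in hh:mm:ss, numbered wells
    1..200).  Wells 1-100 become plate "1"; wells 101-200 become plate "2",
    renumbered 1-100 (the instrument's two-cassette layout)."""
    df = _read_csv(path)
    ids = [int(c) for c in df.columns[1:]]
    bad = [i for i in ids if not 1 <= i <= 200]
    if bad:
        raise FormatError(f"{path}: bioscreen well id(s) out of range 1..200: {bad}")

    def plate_of(col):
        return "1" if int(col) <= 100 else "2"

    def well_of(col):
        i = int(col)
        return str(i if i <= 100 else i - 100)

    return _melt_wide(df, path, unit, plate_of=plate_of, well_of=well_of)


# ---------------------------------------------------------------------------
# Design parsers


def read_design_plater(path) -> pd.DataFrame:
    """Parse a plater-style design file into a (well, variables...) table.

    The file is one or more plate-shaped blocks separated by a blank line.
    Each block: top-left cell is the variable name, first row the column
    numbers, first column the row letters, and the grid holds the values
    (empty cells become missing).  All blocks must share one plate shape.
    """
    with open(path, "r", encoding="utf-8-sig") as fh:
        lines = [line.rstrip("\r\n") for line in fh]
    sep = _sniff_delimiter([l for l in lines if l.strip()][:5])

    blocks: list[list[str]] = [[]]
    for line in lines:
        if not line.strip().replace(sep, ""):
            if blocks[-1]:
                blocks.append([])
        else:
            blocks[-1].append(line)
    if not blocks[-1]:
        blocks.pop()

    tables: dict[str, dict[str, str]] = {}
    shape: Optional[tuple[int, int]] = None
    for block in blocks:
        header = _cells(block[0], sep)
        var = header[0]
        if not var:
            raise FormatError(f"{path}: block missing a variable name in its top-left cell")
        if var in tables:
            raise FormatError(f"{path}: duplicate variable name {var!r}")
        cols = [c for c in header[1:] if c]
        if not all(_is_int(c) for c in cols):
            raise FormatError(f"{path}, block {var!r}: column headers must be integers")
        this_shape = (len(block) - 1, len(cols))
        if shape is None:
            shape = this_shape
        elif this_shape != shape:
            raise FormatError(
                f"{path}, block {var!r}: shape {this_shape} differs from {shape}"
            )
        values: dict[str, str] = {}
        for row_line in block[1:]:
            cells = _cells(row_line, sep)
            letter = cells[0]
            if not re.match(r"^[A-Pa-p]$", letter):
                raise FormatError(f"{path}, block {var!r}: bad row label {letter!r}")
            body = cells[1 : len(cols) + 1]
            if len(cells) - 1 > len(cols):
                extra = [c for c in cells[len(cols) + 1 :] if c]
                if extra:
                    raise FormatError(f"{path}, block {var!r}: ragged row {letter!r}")
            body = body + [""] * (len(cols) - len(body))
            for col_no, val in zip(cols, body):
                well = str(normalize_well_label(f"{letter}{int(col_no)}"))
                if val:
                    values[well] = val
        tables[var] = values

    all_wells = sorted({w for vals in tables.values() for w in vals})
    out = pd.DataFrame({"well": all_wells})
    for var, vals in tables.items():
        out[var] = [vals.get(w) for w in all_wells]
    return out


def read_design_csv(path) -> pd.DataFrame:
    """Parse a generic design CSV: a well column plus variable columns, with
    optional plate and run columns."""
    df = _read_csv(path)
    df.columns = [c.lower() if c.lower() in ("well", "plate", "run") else c for c in df.columns]
    if "well" not in df.columns:
        raise FormatError(f"{path}: design CSV needs a 'well' column")
    df["well"] = [str(normalize_well_label(w)) for w in df["well"]]
    key = ["well"] + (["plate"] if "plate" in df.columns else [])
    if df.duplicated(subset=key).any():
        dup = df[df.duplicated(subset=key)][key].iloc[0].to_dict()
        raise FormatError(f"{path}: duplicate design key {dup}")
    return df


register_reader("long_csv", "measures", _sniff_long_csv, read_measures_long_csv)
register_reader("wide_csv", "measures", _sniff_wide_csv, read_measures_wide_csv)
register_reader("bioscreen", "measures", _sniff_bioscreen, read_measures_bioscreen)
register_reader("plater_design", "design", _sniff_plater, read_design_plater)
register_reader("generic_design_csv", "design", _sniff_generic_design, read_design_csv)


# ---------------------------------------------------------------------------
# Multi-file joining


def _strip_design_token(stem: str) -> str:
    return re.sub(r"[-_]design$", "", stem)


def _match_designs(measure_stems: list[str], design_stems: list[str]) -> dict[str, Optional[str]]:
    """Map each design stem to its measures stem by longest common prefix
    after stripping a trailing _design/-design token.  Ties are errors;
    no overlap at all leaves the design unmatched (None)."""
    out: dict[str, Optional[str]] = {}
    for d in design_stems:
        base = _strip_design_token(d)
        lcp = [_common_prefix_len(base, m) for m in measure_stems]
        best = max(lcp)
        if best == 0:
            out[d] = None
            continue
        winners = [m for m, l in zip(measure_stems, lcp) if l == best]
        if len(winners) > 1:
            raise FormatError(
                f"design file {d!r} matches multiple measures files equally well: {winners}"
            )
        out[d] = winners[0]
    return out


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for ca, cb in zip(a, b):
        if ca != cb:
            break
        n += 1
    return n


def _join_design(measures: TidyMeasures, design: pd.DataFrame, log: list[str]) -> TidyMeasures:
    df = measures.data
    keys = ["well"] + (["plate"] if "plate" in design.columns else [])
    design = design.drop(columns=[c for c in ("run",) if c in design.columns])
    present = df[keys].drop_duplicates()
    merged_keys = design.merge(present, on=keys, how="left", indicator=True)
    orphan = merged_keys["_merge"] == "left_only"
    if orphan.any():
        bad = merged_keys.loc[orphan, "well"].tolist()
        warnings.warn(f"design wells absent from measures (rows dropped): {bad}")
        design = design.merge(present, on=keys, how="inner")
    out = df.merge(design, on=keys, how="left")
    new_cols = [c for c in design.columns if c not in keys]
    log.append(f"joined design columns {new_cols} on {keys}")
    return TidyMeasures(out, unit=measures.unit,
                        design_columns=sorted(set(measures.design_columns) | set(new_cols)))


def join_experiment(paths: list, unit: str = "seconds",
                    log: Optional[list[str]] = None) -> TidyMeasures:
    """Parse and join a set of measures/design files into one experiment.

    Joining heuristics: with one measures and one design file they form a
    single run; with several measures files and one design, the design joins
    onto each; with several of both, designs match measures by filename-stem
    prefix (``run1_design.csv`` matches ``run1.txt``).  The run id is the
    measures file stem unless the file itself carries a run column.
    """
    if log is None:
        log = []
    measures_files: list[tuple[str, TidyMeasures]] = []
    design_files: list[tuple[str, pd.DataFrame]] = []
    for path in paths:
        fmt = detect_format(path)
        reader = next(r for r in READER_REGISTRY if r.name == fmt)
        stem = Path(path).stem
        if reader.kind == "measures":
            parsed = reader.parse(path, unit=unit)
            measures_files.append((stem, parsed))
            log.append(f"parsed {path} as {fmt}: {len(parsed)} measures")
        else:
            parsed = reader.parse(path)
            design_files.append((stem, parsed))
            log.append(f"parsed {path} as {fmt}: {len(parsed)} design rows")
    if not measures_files:
        raise FormatError("no measures file among the inputs")

    joined: list[TidyMeasures] = []
    if len(design_files) <= 1:
        design = design_files[0][1] if design_files else None
        for stem, tm in measures_files:
            joined.append(_join_design(tm, design, log) if design is not None else tm)
    else:
        mapping = _match_designs([s for s, _ in measures_files], [s for s, _ in design_files])
        by_stem = dict(measures_files)
        designs_for: dict[str, pd.DataFrame] = {}
        for (dstem, dtable) in design_files:
            target = mapping[dstem]
            if target is None:
                warnings.warn(f"design file {dstem!r} matched no measures file; ignored")
                log.append(f"unmatched design {dstem!r} ignored")
            else:
                designs_for[target] = dtable
        for stem, tm in measures_files:
            if stem in designs_for:
                joined.append(_join_design(tm, designs_for[stem], log))
            else:
                joined.append(tm)

    frames = [tm.data for tm in joined]
    design_cols = sorted({c for tm in joined for c in tm.design_columns})
    combined = pd.concat(frames, ignore_index=True)
    return TidyMeasures(combined, unit=unit, design_columns=design_cols)
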