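"""Reference/target well grouping via the shorthand syntax

    [plate name]![ref wells]->[target wells]

Each side is a comma-separated list of wells; a colon selects a rectangle
(``B02:C03`` is every well whose row and column fall between the two corners,
inclusive) or, on numbered plates, an integer range.  Omitting the plate
prefix applies the grouping to every plate in the run.  One grouping per
line; groups may reuse wells and are not mutually exclusive.

Example: ``1!A01->A01:H12`` makes A01 the reference for all 96 wells of an
8-row x 12-column plate named "1".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence
import warnings

import pandas as pd

from .model import LabelError, PlateShape, WellLabel, normalize_well_label

__all__ = ["GroupSpec", "parse_group_shorthand", "apply_groups", "GroupingError"]


class GroupingError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSpec:
    """One parsed grouping: reference wells -> target wells, optionally
    scoped to a single plate.

    Names are positional ("g1", "g2", ... by line order); plate-scoped
    instances are named "<plate>!g<k>".
    """

    name: str
    plate: Optional[str]
    ref_wells: tuple[WellLabel, ...]
    target_wells: tuple[WellLabel, ...]

    def render(self) -> str:
        refs = ",".join(str(w) for w in self.ref_wells)
        targets = ",".join(str(w) for w in self.target_wells)
        prefix = f"{self.plate}!" if self.plate is not None else ""
        return f"{prefix}{refs}->{targets}"


def _expand_side(text: str, shape: PlateShape, line_no: int) -> tuple[WellLabel, ...]:
    wells: list[WellLabel] = []
    seen: set[WellLabel] = set()
    for item in text.split(","):
        item = item.strip()
        if not item:
            raise GroupingError(f"line {line_no}: empty well entry")
        if ":" in item:
            a_text, _, b_text = item.partition(":")
            expanded = _expand_range(a_text.strip(), b_text.strip(), shape, line_no)
        else:
            expanded = [_well(item, line_no)]
        for w in expanded:
            if not shape.contains(w):
                raise GroupingError(
                    f"line {line_no}: well {w} outside the plate shape "
                    f"({shape.n_numeric_wells or f'{shape.n_rows}x{shape.n_cols}'})"
                )
            if w not in seen:
                seen.add(w)
                wells.append(w)
    if not wells:
        raise GroupingError(f"line {line_no}: empty well set")
    return tuple(wells)


def _well(text: str, line_no: int) -> WellLabel:
    try:
        return normalize_well_label(text)
    except LabelError as e:
        raise GroupingError(f"line {line_no}: {e}") from None


def _expand_range(a_text: str, b_text: str, shape: PlateShape, line_no: int) -> list[WellLabel]:
    a = _well(a_text, line_no)
    b = _well(b_text, line_no)
    if a.is_numeric != b.is_numeric:
        raise GroupingError(f"line {line_no}: mixed range {a_text}:{b_text}")
    if a.is_numeric:
        lo, hi = sorted((a.numeric_id, b.numeric_id))
        return [WellLabel(numeric_id=i) for i in range(lo, hi + 1)]
    # rectangle, corners in any order, row-major expansion
    r0, r1 = sorted((a.row, b.row))
    c0, c1 = sorted((a.col, b.col))
    return [
        WellLabel(row=chr(r), col=c)
        for r in range(ord(r0), ord(r1) + 1)
        for c in range(c0, c1 + 1)
    ]


def parse_group_shorthand(
    text: str, shape: PlateShape, plates: Sequence[str]
) -> list[GroupSpec]:
    """Parse multiline grouping shorthand into GroupSpecs.

    ``plates`` lists the plate ids present in the run; a spec without a plate
    prefix is instantiated once per plate.  Blank lines are ignored.  All
    groups must apply to plates of one shared shape.
    """
    plates = [str(p) for p in plates]
    specs: list[GroupSpec] = []
    counter = 0
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        counter += 1
        plate: Optional[str] = None
        body = line
        if "!" in line:
            plate_part, _, body = line.partition("!")
            plate = plate_part.strip()
            if plate not in plates:
                raise GroupingError(
                    f"line {line_no}: unknown plate {plate!r} (plates in run: {plates})"
                )
        if "->" not in body:
            raise GroupingError(f"line {line_no}: missing '->' arrow in {line!r}")
        ref_text, _, target_text = body.partition("->")
        refs = _expand_side(ref_text, shape, line_no)
        targets = _expand_side(target_text, shape, line_no)
        gname = f"g{counter}"
        if plate is not None:
            specs.append(GroupSpec(f"{plate}!{gname}", plate, refs, targets))
        else:
            # one instance per plate in the run
            for p in plates:
                specs.append(GroupSpec(gname, p, refs, targets))
    return specs


def apply_groups(table: pd.DataFrame, specs: Sequence[GroupSpec]) -> pd.DataFrame:
    """Attach group and is_ref columns to a (run, plate, well)-keyed table.

    The output holds one row per original row per matching group; a well on
    both sides of one spec is marked is_ref=True once (reference status
    wins).  Rows matching no group are dropped from the grouped view.
    """
    for col in ("plate", "well"):
        if col not in table.columns:
            raise ValueError(f"table must have a {col!r} column")
    pieces = []
    for spec in specs:
        refs = {str(w) for w in spec.ref_wells}
        targets = {str(w) for w in spec.target_wells} - refs
        sub = table[table["plate"].astype(str) == spec.plate]
        matched = sub[sub["well"].isin(refs | targets)].copy()
        wanted = refs | targets
        present = set(matched["well"].unique())
        absent = sorted(wanted - present)
        if absent:
            warnings.warn(
                f"group {spec.name}: well(s) not present in the data: {', '.join(absent)}"
            )
        if matched.empty:
            continue
        matched["group"] = spec.name
        matched["is_ref"] = matched["well"].isin(refs)
        pieces.append(matched)
    if not pieces:
        warnings.warn("no wells matched any group; grouped view is empty")
        out = table.iloc[0:0].copy()
        out["group"] = pd.Series(dtype=str)
        out["is_ref"] = pd.Series(dtype=bool)
        return out
    return pd.concat(pieces, ignore_index=True)
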