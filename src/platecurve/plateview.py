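"""Static plate-view rendering: every well of every plate drawn as a
rectangle in its physical position, with data mapped to the well fill and
optional in-well growth-curve line plots.

Numeric fills use a perceptually uniform colormap (viridis), so equal steps
in the data read as equal steps in color; categorical fills use a discrete
palette.  Reference-curve overlays draw each reference curve in light,
semi-transparent gray beneath the target well's own curve.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import cm, colors as mcolors
from matplotlib.patches import Rectangle

from .model import PlateShape, normalize_well_label

__all__ = ["render_plate_view"]


def _well_xy(well: str, shape: PlateShape) -> tuple[float, float]:
    lb = normalize_well_label(well)
    if lb.is_numeric:
        # numbered wells laid out row-major on a 10-wide grid
        i = lb.numeric_id - 1
        return float(i % 10), float(i // 10)
    return float(lb.col - 1), float(ord(lb.row) - ord("A"))


def render_plate_view(
    table: pd.DataFrame,
    fill: Optional[str],
    out_path,
    curves: Optional[pd.DataFrame] = None,
    group_overlay: bool = False,
    value_column: str = "measure_preprocessed",
) -> Path:
    """Render one PNG per call: an MTP view of every (run, plate).

    ``table`` must carry run/plate/well and, when ``fill`` is given, one
    value of that column per well.  ``curves`` optionally supplies per-well
    time series (run, plate, well, runtime, value_column) drawn inside each
    rectangle; with ``group_overlay`` the table must carry group/is_ref and
    each group's reference curves are over-plotted in its target wells.
    """
    if fill is not None and fill not in table.columns:
        raise ValueError(
            f"unknown fill column {fill!r}; available: {sorted(table.columns)}"
        )
    plates = table[["run", "plate"]].drop_duplicates().itertuples(index=False)
    plates = list(plates)
    fig, axes = plt.subplots(
        len(plates), 1, figsize=(8, 5.5 * len(plates)), squeeze=False
    )

    mapper = _fill_mapper(table, fill)
    for ax, (run, plate) in zip(axes[:, 0], plates):
        sub = table[(table["run"] == run) & (table["plate"] == plate)]
        shape = PlateShape.infer(normalize_well_label(w) for w in sub["well"].unique())
        _draw_plate(ax, sub, shape, fill, mapper, curves, group_overlay,
                    value_column, run, plate)
        ax.set_title(f"{run} / plate {plate}")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=110, format="png")
    plt.close(fig)
    return out_path


def _fill_mapper(table: pd.DataFrame, fill: Optional[str]):
    if fill is None:
        return lambda v: (0.92, 0.92, 0.92, 1.0)
    col = table[fill]
    if pd.api.types.is_numeric_dtype(col):
        vals = col.astype(float)
        norm = mcolors.Normalize(vmin=np.nanmin(vals), vmax=np.nanmax(vals))
        cmap = matplotlib.colormaps["viridis"]

        def mapper(v):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return (0.92, 0.92, 0.92, 1.0)
            return cmap(norm(float(v)))

        return mapper
    levels = sorted(col.dropna().astype(str).unique())
    palette = matplotlib.colormaps["tab20" if len(levels) > 10 else "tab10"]
    lut = {lv: palette(i % palette.N) for i, lv in enumerate(levels)}
    return lambda v: lut.get(str(v), (0.92, 0.92, 0.92, 1.0))


def _draw_plate(ax, sub, shape, fill, mapper, curves, group_overlay,
                value_column, run, plate):
    pad = 0.05
    per_well = sub.drop_duplicates(subset=["well"])
    for r in per_well.itertuples(index=False):
        x0, y0 = _well_xy(r.well, shape)
        color = mapper(getattr(r, fill) if fill else None)
        ax.add_patch(
            Rectangle((x0 + pad, y0 + pad), 1 - 2 * pad, 1 - 2 * pad,
                      facecolor=color, edgecolor="black", linewidth=0.4)
        )
    if curves is not None:
        _draw_curves(ax, sub, shape, curves, group_overlay, value_column, run, plate)
    n_cols = 10 if shape.is_numeric else shape.n_cols
    n_rows = int(np.ceil(shape.n_numeric_wells / 10)) if shape.is_numeric else shape.n_rows
    ax.set_xlim(0, n_cols)
    ax.set_ylim(n_rows, 0)  # row A on top
    ax.set_xticks(np.arange(n_cols) + 0.5, [str(i + 1) for i in range(n_cols)])
    if not shape.is_numeric:
        ax.set_yticks(np.arange(n_rows) + 0.5, shape.row_letters())
    ax.set_aspect("equal")


def _scaled(points_x, points_y, x0, y0, xr, yr):
    pad = 0.12
    sx = x0 + pad + (1 - 2 * pad) * (points_x - xr[0]) / max(xr[1] - xr[0], 1e-12)
    sy = y0 + (1 - pad) - (1 - 2 * pad) * (points_y - yr[0]) / max(yr[1] - yr[0], 1e-12)
    return sx, sy


def _draw_curves(ax, sub, shape, curves, group_overlay, value_column, run, plate):
    cs = curves[(curves["run"] == run) & (curves["plate"] == plate)]
    if cs.empty:
        return
    xr = (cs["runtime"].min(), cs["runtime"].max())
    yr = (cs[value_column].min(), cs[value_column].max())
    if group_overlay and {"group", "is_ref"} <= set(sub.columns):
        # reference curves first: light translucent gray inside target wells
        for grp, gsub in sub.groupby("group"):
            refs = gsub[gsub["is_ref"].astype(bool)]["well"].unique()
            targets = gsub[~gsub["is_ref"].astype(bool)]["well"].unique()
            for tw in targets:
                x0, y0 = _well_xy(tw, shape)
                for rw in refs:
                    rc = cs[cs["well"] == rw].sort_values("runtime")
                    sx, sy = _scaled(rc["runtime"].to_numpy(), rc[value_column].to_numpy(),
                                     x0, y0, xr, yr)
                    ax.plot(sx, sy, color="gray", alpha=0.35, linewidth=0.7)
    for well in sub["well"].unique():
        wc = cs[cs["well"] == well].sort_values("runtime")
        if wc.empty:
            continue
        x0, y0 = _well_xy(well, shape)
        sx, sy = _scaled(wc["runtime"].to_numpy(), wc[value_column].to_numpy(),
                         x0, y0, xr, yr)
        ax.plot(sx, sy, color="black", linewidth=0.8)
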