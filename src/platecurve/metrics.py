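"""Per-well summary metrics extracted from a fitted curve, and per-group means.

All curve metrics are computed on a uniform evaluation grid over the fit's
observed time domain [t_min, t_max]:

- max_y_x, max_y_y: the time at which the curve (first) attains its maximum,
  and that maximum value.
- max_dy_m: the maximum slope of the fitted curve (the maximum of dy/dt).
- max_dy_x, max_dy_y: the point on the curve where the slope is (first) at
  its global maximum.
- max_dy_b, max_dy_x0: y- and x-intercepts of the tangent line at that point
  (for a log-scale sigmoid, max_dy_m estimates mu and max_dy_x0 the lag
  time lambda).
- fit_int: the area under the fitted curve over [t_min, t_max] (trapezoidal).
- min_doubling_time: ln 2 over the maximum specific growth rate.

Ties in the maxima are broken toward the earliest grid point.  Integration
never extrapolates outside the fit's support: when the first observation is
at t_min > 0, fit_int covers [t_min, t_max] only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["SummaryMetrics", "summarize_fit", "min_doubling_time", "group_means",
           "METRIC_COLUMNS"]

_FLAT_TOL = 1e-12

#: Serialization order of the metric columns.
METRIC_COLUMNS = [
    "max_y_x", "max_y_y", "max_dy_m", "max_dy_x", "max_dy_y",
    "max_dy_b", "max_dy_x0", "fit_int", "A", "mu", "lambda", "nu",
    "min_doubling_time",
]


@dataclass
class SummaryMetrics:
    max_y_x: float = math.nan
    max_y_y: float = math.nan
    max_dy_m: float = math.nan
    max_dy_x: float = math.nan
    max_dy_y: float = math.nan
    max_dy_b: float = math.nan
    max_dy_x0: float = math.nan
    fit_int: float = math.nan
    A: float = math.nan
    mu: float = math.nan
    nu: float = math.nan
    min_doubling_time: float = math.nan
    # "lambda" is a Python keyword; stored as lambda_, serialized as "lambda"
    lambda_: float = math.nan

    def to_dict(self) -> dict[str, float]:
        out = {}
        for name in METRIC_COLUMNS:
            attr = "lambda_" if name == "lambda" else name
            out[name] = getattr(self, attr)
        return out


def summarize_fit(fit, grid_size: int = 1000, log_base=None) -> SummaryMetrics:
    """Compute the summary-metric vector for one fitted curve.

    ``log_base`` declares that the measures were already log-transformed
    upstream (used by the doubling-time metric).  Flat curves (maximum slope
    <= 0 within tolerance) get missing tangent intercepts and doubling time.
    """
    t0, t1 = fit.domain
    grid = np.linspace(t0, t1, int(grid_size))
    yhat = np.asarray(fit.predict(grid), dtype=float)
    dyhat = np.asarray(fit.derivative(grid), dtype=float)

    m = SummaryMetrics()
    i_max = int(np.argmax(yhat))  # first occurrence of the global max
    m.max_y_x = float(grid[i_max])
    m.max_y_y = float(yhat[i_max])

    j = int(np.argmax(dyhat))
    m.max_dy_m = float(dyhat[j])
    m.max_dy_x = float(grid[j])
    m.max_dy_y = float(yhat[j])
    if m.max_dy_m > _FLAT_TOL:
        m.max_dy_b = m.max_dy_y - m.max_dy_m * m.max_dy_x
        m.max_dy_x0 = -m.max_dy_b / m.max_dy_m
    m.fit_int = float(np.trapezoid(yhat, grid))

    for name in ("A", "mu", "nu"):
        if name in fit.params:
            setattr(m, name, float(fit.params[name]))
    if "lambda" in fit.params:
        m.lambda_ = float(fit.params["lambda"])

    m.min_doubling_time = min_doubling_time(
        fit, log_base=log_base, _grid=(grid, yhat, dyhat)
    )
    return m


def min_doubling_time(fit, log_base=None, _grid=None) -> float:
    """ln(2) / mu*, where mu* is the maximum specific growth rate.

    On natural scale, mu* = max over the grid of d(ln yhat)/dt, defined where
    the fitted curve is positive.  If the measures were log_b-transformed
    upstream, the fitted slope is already d(log_b y)/dt, so
    mu* = ln(b) * max slope.  Returns NaN when mu* <= 0.
    """
    if _grid is None:
        t0, t1 = fit.domain
        grid = np.linspace(t0, t1, 1000)
        yhat = np.asarray(fit.predict(grid), dtype=float)
        dyhat = np.asarray(fit.derivative(grid), dtype=float)
    else:
        grid, yhat, dyhat = _grid

    if log_base is not None:
        b = math.e if log_base in ("e",) else float(log_base)
        mu_star = math.log(b) * float(np.max(dyhat))
    else:
        pos = yhat > 0
        if not np.any(pos):
            return math.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            spec = np.where(pos, dyhat / yhat, -np.inf)
        mu_star = float(np.max(spec))
    if not np.isfinite(mu_star) or mu_star <= _FLAT_TOL:
        return math.nan
    return math.log(2.0) / mu_star


def group_means(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-(group, is_ref) means of every numeric metric column.

    Missing values are excluded pairwise: each metric's mean is over the
    wells where it is present.  ``n_wells`` counts the rows in the stratum.
    Empty strata simply do not appear.
    """
    if "group" not in summary.columns or "is_ref" not in summary.columns:
        raise ValueError("summary table must carry group and is_ref columns")
    numeric = [
        c
        for c in summary.columns
        if c not in ("group", "is_ref") and pd.api.types.is_numeric_dtype(summary[c])
    ]
    grouped = summary.groupby(["group", "is_ref"], sort=True, dropna=False)
    out = grouped[numeric].mean().reset_index()
    out.insert(2, "n_wells", grouped.size().to_numpy())
    return out
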