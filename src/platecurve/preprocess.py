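"""Per-well preprocessing: log-ratio transform, running median/mean smoothing,
monotone enforcement, and formula-based background correction / calibration.

The chain runs in a fixed order: log transform -> running median -> running
mean -> enforce increasing -> background formula -> calibration formula.
Disabled steps are identities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .formula import FormulaWarning, Node, eval_well_formula, parse_formula

__all__ = [
    "PreprocessConfig",
    "log_ratio_transform",
    "running_median",
    "running_mean",
    "enforce_increasing",
    "preprocess_well",
]

_LOG_FNS = {2: np.log2, "2": np.log2, "e": np.log, 10: np.log10, "10": np.log10}


class PreprocessError(ValueError):
    pass


def log_ratio_transform(y: np.ndarray, base: int | str = "e") -> np.ndarray:
    """log_base(y / min(y)): the minimum measure maps to exactly 0.

    The minimum (rather than the first measure) anchors the ratio so noisy
    initial readings do not bias the transform.  Requires all y > 0.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise PreprocessError("log-ratio transform requires strictly positive measures")
    fn = _LOG_FNS.get(base)
    if fn is None:
        raise PreprocessError(f"unknown log base {base!r}; allowed: 2, 'e', 10")
    return fn(y / np.min(y))


def _check_window(k: int, n: int) -> None:
    if k < 1 or k % 2 == 0 or k >= n:
        raise PreprocessError(
            f"window width must be an odd integer less than the number of points "
            f"(got k={k} for n={n})"
        )


def _running(y: np.ndarray, k: int, reducer) -> np.ndarray:
    """Centered running filter with symmetrically shrinking edge windows.

    Near each edge the window narrows to widths 1, 3, ..., k so the output has
    the same length as the input and no padding values are invented.
    """
    y = np.asarray(y, dtype=float)
    _check_window(k, len(y))
    half = k // 2
    n = len(y)
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = reducer(y[i - h : i + h + 1])
    return out


def running_median(y: np.ndarray, k: int) -> np.ndarray:
    """Centered running median; removes single-timepoint spikes for k >= 3."""
    return _running(y, k, np.median)


def running_mean(y: np.ndarray, k: int) -> np.ndarray:
    """Centered running mean; attenuates low-amplitude high-frequency noise."""
    return _running(y, k, np.mean)


def enforce_increasing(y: np.ndarray) -> np.ndarray:
    """Replace any measure below its predecessor with that predecessor.

    Equivalent to the running maximum; counteracts transient dips from
    bubbles, aggregation or precipitate.  Idempotent.
    """
    return np.maximum.accumulate(np.asarray(y, dtype=float))


@dataclass
class PreprocessConfig:
    """Options for the per-well preprocessing chain.

    log_base: None (off) or 2 / 'e' / 10.
    median_window / mean_window: odd widths; 1 disables the filter.
    enforce_increasing: clamp dips to the running maximum.
    background / calibration: formula strings over y (and x), applied last.
    """

    log_base: Optional[int | str] = None
    median_window: int = 1
    mean_window: int = 1
    enforce_increasing: bool = False
    background: Optional[str] = None
    calibration: Optional[str] = None

    def __post_init__(self) -> None:
        self._background_ast: Optional[Node] = (
            parse_formula(self.background, mode="well") if self.background else None
        )
        self._calibration_ast: Optional[Node] = (
            parse_formula(self.calibration, mode="well") if self.calibration else None
        )
        for w in (self.median_window, self.mean_window):
            if w < 1 or w % 2 == 0:
                raise PreprocessError(f"window width must be a positive odd integer, got {w}")

    @property
    def is_identity(self) -> bool:
        return (
            self.log_base is None
            and self.median_window == 1
            and self.mean_window == 1
            and not self.enforce_increasing
            and self.background is None
            and self.calibration is None
        )

    def to_dict(self) -> dict:
        return {
            "log_base": self.log_base,
            "median_window": self.median_window,
            "mean_window": self.mean_window,
            "enforce_increasing": self.enforce_increasing,
            "background": self.background,
            "calibration": self.calibration,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        known = {k: d[k] for k in cls.__dataclass_fields__ if k in d}
        return cls(**known)


def preprocess_well(
    y: np.ndarray, x: np.ndarray, config: PreprocessConfig
) -> np.ndarray:
    """Apply the full preprocessing chain to one well.

    Raises PreprocessError if a step fails (e.g. nonpositive measures under a
    log transform); callers exclude such wells from fitting rather than abort.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if config.log_base is not None:
        try:
            y = log_ratio_transform(y, config.log_base)
        except PreprocessError as e:
            # nonpositive measures: skip the transform but keep the well
            warnings.warn(f"log transform skipped: {e}", FormulaWarning, stacklevel=2)
    if config.median_window > 1:
        y = running_median(y, config.median_window)
    if config.mean_window > 1:
        y = running_mean(y, config.mean_window)
    if config.enforce_increasing:
        y = enforce_increasing(y)
    with warnings.catch_warnings():
        warnings.simplefilter("error", FormulaWarning)
        try:
            if config._background_ast is not None:
                y = eval_well_formula(config._background_ast, y, x)
            if config._calibration_ast is not None:
                y = eval_well_formula(config._calibration_ast, y, x)
        except FormulaWarning as w:  # escalate to a per-well failure
            raise PreprocessError(str(w)) from None
    if not np.all(np.isfinite(y)):
        raise PreprocessError("preprocessing produced non-finite values")
    return y
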