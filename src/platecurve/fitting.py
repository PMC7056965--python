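"""Growth-curve fitting: smoothing spline, the named sigmoid growth models
(Gompertz, logistic, Richards) and arbitrary user formulas, with quality
statistics.

The named models use the reparameterization in terms of the biologically
interpretable quantities A (asymptotic growth limit), mu (maximum growth
rate, the maximum slope of the curve) and lambda (lag time, the x-intercept
of the tangent at the point of maximum slope):

    Gompertz:  y = A * exp(-exp((mu*e/A) * (lambda - t) + 1))
    logistic:  y = A / (1 + exp((4*mu/A) * (lambda - t) + 2))
    Richards:  y = A * [1 + nu * e^(1+nu) *
                        exp((mu/A) * (1+nu)^(1+1/nu) * (lambda - t))]^(-1/nu)

Fitting follows the statsmodels idiom: build a :class:`GrowthCurveModel`
from one well's (x, y) data, call :meth:`~GrowthCurveModel.fit`, and read
estimates, quality statistics and summary metrics off the returned
:class:`GrowthCurveFit` results object.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.interpolate import BSpline, make_smoothing_spline
from scipy.optimize import least_squares

from .formula import (
    ModelFormula,
    Node,
    NotDifferentiable,
    differentiate,
    eval_model_formula,
    parse_formula,
)

__all__ = [
    "GrowthCurveModel",
    "GrowthCurveFit",
    "fit_spline",
    "fit_named_model",
    "fit_manual",
    "quality_stats",
    "NAMED_MODELS",
]

_E = math.e
_RSS_FLOOR = 1e-300  # keeps logLik finite on perfect fits


# ---------------------------------------------------------------------------
# Named sigmoid models (value and analytic time-derivative)


def _gompertz(t, A, mu, lam):
    u = (mu * _E / A) * (lam - t) + 1.0
    return A * np.exp(-np.exp(_clip_exp(u)))


def _gompertz_deriv(t, A, mu, lam):
    u = _clip_exp((mu * _E / A) * (lam - t) + 1.0)
    return mu * _E * np.exp(u - np.exp(u))


def _logistic(t, A, mu, lam):
    v = _clip_exp((4.0 * mu / A) * (lam - t) + 2.0)
    return A / (1.0 + np.exp(v))


def _logistic_deriv(t, A, mu, lam):
    v = _clip_exp((4.0 * mu / A) * (lam - t) + 2.0)
    ev = np.exp(v)
    return 4.0 * mu * ev / (1.0 + ev) ** 2


def _richards(t, A, mu, lam, nu):
    w = _clip_exp((mu / A) * (1.0 + nu) ** (1.0 + 1.0 / nu) * (lam - t))
    q = nu * np.exp(_clip_exp(1.0 + nu)) * np.exp(w)
    return A * (1.0 + q) ** (-1.0 / nu)


def _richards_deriv(t, A, mu, lam, nu):
    w = _clip_exp((mu / A) * (1.0 + nu) ** (1.0 + 1.0 / nu) * (lam - t))
    q = nu * np.exp(_clip_exp(1.0 + nu)) * np.exp(w)
    return (mu / nu) * (1.0 + nu) ** (1.0 + 1.0 / nu) * q * (1.0 + q) ** (-1.0 / nu - 1.0)


def _clip_exp(z):
    return np.clip(z, -700.0, 700.0)


NAMED_MODELS: dict[str, dict] = {
    "gompertz": {"fn": _gompertz, "deriv": _gompertz_deriv, "params": ("A", "mu", "lambda")},
    "logistic": {"fn": _logistic, "deriv": _logistic_deriv, "params": ("A", "mu", "lambda")},
    "richards": {"fn": _richards, "deriv": _richards_deriv, "params": ("A", "mu", "lambda", "nu")},
}


def self_start(x: np.ndarray, y: np.ndarray, with_nu: bool = False) -> list[float]:
    """Data-driven initial estimates for (A, mu, lambda[, nu]).

    A0 = max(y); mu0 = the largest finite-difference slope; lambda0 is the
    x-intercept of the tangent through the max-slope point, clamped to
    [0, t_max]; nu0 = 1.
    """
    dy = np.diff(y) / np.diff(x)
    i = int(np.argmax(dy))
    mu0 = max(float(dy[i]), 1e-12)
    t_star = 0.5 * (x[i] + x[i + 1])
    y_star = 0.5 * (y[i] + y[i + 1])
    lam0 = float(np.clip(t_star - y_star / mu0, 0.0, x[-1]))
    A0 = max(float(np.max(y)), 1e-12)
    start = [A0, mu0, lam0]
    if with_nu:
        start.append(1.0)
    return start


# ---------------------------------------------------------------------------
# Results object


@dataclass
class GrowthCurveFit:
    """A fitted growth curve: evaluable, differentiable, with named
    coefficients and quality statistics.

    ``predict`` and ``derivative`` are defined over the observed time domain
    [t_min, t_max].  ``params`` maps coefficient names to estimates (A, mu,
    lambda[, nu] for the named models; the user's names for manual fits;
    empty for splines).  ``quality`` holds the method-specific fit statistics.
    """

    method: str
    x: np.ndarray
    y: np.ndarray
    predict: Callable[[np.ndarray], np.ndarray]
    derivative: Callable[[np.ndarray], np.ndarray]
    params: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    quality: dict[str, float | bool] = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return len(self.x)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.x[-1])

    @property
    def resid(self) -> np.ndarray:
        return self.y - self.predict(self.x)

    @property
    def deviance(self) -> float:
        return float(np.sum(self.resid**2))

    def metrics(self, grid_size: int = 1000, log_base=None):
        """Summary metrics for this fit (see :mod:`platecurve.metrics`)."""
        from .metrics import summarize_fit

        return summarize_fit(self, grid_size=grid_size, log_base=log_base)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [
            "Growth curve fit",
            "================",
            f"method:     {self.method}",
            f"n points:   {self.n_points}",
            f"domain:     [{self.x[0]:g}, {self.x[-1]:g}]",
            f"converged:  {self.converged}",
        ]
        if self.params:
            lines.append("coefficients:")
            for k, v in self.params.items():
                lines.append(f"  {k:<10s} {v: .6g}")
        if self.quality:
            lines.append("quality:")
            for k, v in self.quality.items():
                if isinstance(v, bool):
                    lines.append(f"  {k:<12s} {v}")
                elif v is None or (isinstance(v, float) and not np.isfinite(v)):
                    lines.append(f"  {k:<12s} NA")
                else:
                    lines.append(f"  {k:<12s} {v: .6g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Quality statistics


def quality_stats(n: int, p: int, rss: float, fin_tol: float = float("nan"),
                  converged: bool = True) -> dict:
    """Gaussian likelihood statistics from a residual sum of squares.

    logLik = -n/2 [ln(2 pi) + ln(RSS/n) + 1]; AIC and BIC count the error
    variance as one extra parameter; sigma = sqrt(RSS / (n - p)).
    """
    out: dict[str, float | bool] = {"isConv": bool(converged), "finTol": fin_tol}
    if n <= p:
        warnings.warn("fewer observations than parameters; quality stats set to missing")
        for k in ("sigma", "logLik", "AIC", "BIC", "deviance", "df.residual"):
            out[k] = float("nan")
        return out
    rss_f = max(rss, _RSS_FLOOR)
    log_lik = -0.5 * n * (math.log(2.0 * math.pi) + math.log(rss_f / n) + 1.0)
    out["sigma"] = math.sqrt(rss / (n - p))
    out["logLik"] = log_lik
    out["AIC"] = 2.0 * (p + 1) - 2.0 * log_lik
    out["BIC"] = math.log(n) * (p + 1) - 2.0 * log_lik
    out["deviance"] = rss
    out["df.residual"] = float(n - p)
    return out


# ---------------------------------------------------------------------------
# Spline fitting with GCV smoothing selection


def _gcv_score(x: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, float, float]:
    """(GCV, df, RSS) at penalty lam, via the smoother ('hat') matrix."""
    n = len(x)
    hat = make_smoothing_spline(x, np.eye(n), lam=lam)(x)
    df = float(np.trace(hat))
    rss = float(np.sum((y - hat @ y) ** 2))
    denom = max(n - df, 1e-10)
    return n * rss / denom**2, df, rss


def fit_spline(x: np.ndarray, y: np.ndarray, spar: Optional[float] = None) -> GrowthCurveFit:
    """Cubic smoothing spline; the penalty is chosen by generalized
    cross-validation (GCV) unless ``spar`` supplies it directly.

    Quality statistics report the chosen smoothing parameter (spar), the
    equivalent degrees of freedom (df = trace of the smoother matrix), the
    minimized criterion (crit, the GCV score), the penalized residual sum of
    squares and the cross-validation score (cv.crit, again GCV).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(np.diff(x) <= 0):
        x, y = _average_duplicates(x, y)
    if len(x) < 5:
        raise ValueError("spline fitting needs at least 5 distinct time points")

    if spar is None:
        # coarse log-grid search, then golden-section refinement
        scale = (x[-1] - x[0]) ** 3 / max(len(x), 1)
        grid = scale * np.logspace(-8.0, 8.0, 17)
        scores = [_gcv_score(x, y, lam)[0] for lam in grid]
        i = int(np.argmin(scores))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        lam = _golden_min(lambda l: _gcv_score(x, y, math.exp(l))[0], math.log(lo),
                          math.log(hi), tol=1e-2)
        lam = math.exp(lam)
    else:
        lam = float(spar)

    crit, df, rss = _gcv_score(x, y, lam)
    spline: BSpline = make_smoothing_spline(x, y, lam=lam)
    dspline = spline.derivative(1)
    # roughness penalty: integral of the squared second derivative
    tg = np.linspace(x[0], x[-1], 2001)
    rough = float(np.trapezoid(spline.derivative(2)(tg) ** 2, tg))
    fit = GrowthCurveFit(
        method="spline",
        x=x,
        y=y,
        predict=lambda t: spline(np.asarray(t, dtype=float)),
        derivative=lambda t: dspline(np.asarray(t, dtype=float)),
        params={},
        converged=True,
        quality={
            "spar": lam,
            "df": df,
            "crit": crit,
            "penalized_rss": rss + lam * rough,
            "cv.crit": crit,
        },
    )
    return fit


def _average_duplicates(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(x, kind="mergesort")
    x, y = x[order], y[order]
    ux, inv = np.unique(x, return_inverse=True)
    if len(ux) < len(x):
        warnings.warn("duplicate time points averaged before spline fitting")
        uy = np.bincount(inv, weights=y) / np.bincount(inv)
        return ux, uy
    return x, y


def _golden_min(f: Callable[[float], float], a: float, b: float, tol: float = 1e-3) -> float:
    phi = (math.sqrt(5.0) - 1.0) / 2.0
    c, d = b - phi * (b - a), a + phi * (b - a)
    fc, fd = f(c), f(d)
    while abs(b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


# ---------------------------------------------------------------------------
# Parametric fitting


def _least_squares_fit(
    residual: Callable[[np.ndarray], np.ndarray],
    start: np.ndarray,
    bounds: tuple,
) -> tuple[np.ndarray, bool, float]:
    res = least_squares(
        residual,
        x0=np.asarray(start, dtype=float),
        bounds=bounds,
        method="trf",
        xtol=1e-8,
        ftol=1e-8,
        gtol=1e-8,
        max_nfev=200 * (len(start) + 1),
    )
    return res.x, bool(res.status > 0), float(res.optimality)


def fit_named_model(
    x: np.ndarray,
    y: np.ndarray,
    model: str,
    weights: Optional[np.ndarray] = None,
) -> GrowthCurveFit:
    """Nonlinear (weighted) least-squares fit of a named sigmoid model with
    self-starting initial estimates.

    Coefficients are constrained to A > 0, mu > 0, lambda >= 0 (and nu > 0
    for Richards).  Non-convergence is reported via ``converged=False`` on
    the result, never raised.
    """
    if model not in NAMED_MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(NAMED_MODELS)}")
    spec = NAMED_MODELS[model]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    names = spec["params"]
    p = len(names)
    if len(x) < p + 2:
        raise ValueError(f"{model} fit needs at least {p + 2} points, got {len(x)}")
    w = np.ones_like(y) if weights is None else np.sqrt(np.asarray(weights, dtype=float))
    start = self_start(x, y, with_nu=(p == 4))
    lower = [1e-12, 1e-12, 0.0] + ([1e-6] if p == 4 else [])
    upper = [np.inf] * p
    start = np.maximum(start, np.asarray(lower) * 1.0000001)

    fn = spec["fn"]

    def residual(theta):
        return w * (fn(x, *theta) - y)

    theta, converged, fin_tol = _least_squares_fit(residual, start, (lower, upper))
    params = dict(zip(names, (float(v) for v in theta)))
    rss = float(np.sum(residual(theta) ** 2))
    deriv = spec["deriv"]
    fit = GrowthCurveFit(
        method=model,
        x=x,
        y=y,
        predict=lambda t, _th=tuple(theta): fn(np.asarray(t, dtype=float), *_th),
        derivative=lambda t, _th=tuple(theta): deriv(np.asarray(t, dtype=float), *_th),
        params=params,
        converged=converged,
        quality=quality_stats(len(x), p, rss, fin_tol, converged),
    )
    if not converged:
        warnings.warn(f"{model} fit did not converge")
    return fit


def fit_manual(
    x: np.ndarray,
    y: np.ndarray,
    model: ModelFormula | str,
    start: dict[str, float],
    weights: Optional[np.ndarray] = None,
) -> GrowthCurveFit:
    """Least-squares fit of a user-specified model formula.

    The model is ``y ~ f(x; params)``; ``start`` must supply an initial value
    for every parameter.  The derivative is the symbolic derivative of the
    formula with respect to x, falling back to central finite differences for
    constructs with no symbolic rule.
    """
    if isinstance(model, str):
        model = parse_formula(model, mode="model")
    missing = [pname for pname in model.parameters if pname not in start]
    if missing:
        raise ValueError(f"missing starting value(s) for parameter(s): {missing}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.sqrt(np.asarray(weights, dtype=float))
    names = list(model.parameters)
    theta0 = np.array([float(start[nm]) for nm in names])

    def residual(theta):
        vals = eval_model_formula(model, x, dict(zip(names, theta)))
        return w * (vals - y)

    theta, converged, fin_tol = _least_squares_fit(
        residual, theta0, (-np.inf, np.inf)
    )
    params = dict(zip(names, (float(v) for v in theta)))
    rss = float(np.sum(residual(theta) ** 2))

    def predict(t, _p=dict(params)):
        return eval_model_formula(model, np.asarray(t, dtype=float), _p)

    derivative = _manual_derivative(model, params, x)
    fit = GrowthCurveFit(
        method="manual",
        x=x,
        y=y,
        predict=predict,
        derivative=derivative,
        params=params,
        converged=converged,
        quality=quality_stats(len(x), len(names), rss, fin_tol, converged),
    )
    return fit


def _manual_derivative(model: ModelFormula, params: dict[str, float], x: np.ndarray):
    try:
        d_ast: Node = differentiate(model.rhs, "x")
        d_model = ModelFormula(rhs=d_ast, parameters=model.parameters, text="")

        def derivative(t, _p=dict(params)):
            return eval_model_formula(d_model, np.asarray(t, dtype=float), _p)

        # smoke-test once; some formulas differentiate but fail to evaluate
        derivative(np.asarray(x[:1]))
        return derivative
    except Exception:  # NotDifferentiable, or evaluation failure of the derivative
        h = 1e-6 * max(float(x[-1] - x[0]), 1.0)

        def derivative(t, _p=dict(params)):
            t = np.asarray(t, dtype=float)
            hi = eval_model_formula(model, t + h, _p)
            lo = eval_model_formula(model, t - h, _p)
            return (hi - lo) / (2.0 * h)

        return derivative


# ---------------------------------------------------------------------------
# Model facade


class GrowthCurveModel:
    """One well's growth curve plus a fitting method; ``fit()`` returns a
    :class:`GrowthCurveFit`.

    method: "spline" (default), "gompertz", "logistic", "richards" or
    "manual".  Manual mode requires ``formula`` (``y ~ ...``) and ``start``
    (initial value per parameter).
    """

    def __init__(
        self,
        x: np.ndarray,
        y: np.ndarray,
        method: str = "spline",
        formula: Optional[ModelFormula | str] = None,
        start: Optional[dict[str, float]] = None,
        weights: Optional[np.ndarray] = None,
    ):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if method not in ("spline", "manual", *NAMED_MODELS):
            raise ValueError(f"unknown method {method!r}")
        if method == "manual":
            if formula is None or start is None:
                raise ValueError("manual method requires a formula and starting values")
            if isinstance(formula, str):
                formula = parse_formula(formula, mode="model")
        self.method = method
        self.formula = formula
        self.start = start
        self.weights = weights

    @classmethod
    def from_dataframe(cls, df, x: str = "runtime", y: str = "measure", **kwargs):
        """Build from a tidy DataFrame slice holding one well."""
        return cls(df[x].to_numpy(float), df[y].to_numpy(float), **kwargs)

    def fit(self, spar: Optional[float] = None) -> GrowthCurveFit:
        if self.method == "spline":
            return fit_spline(self.x, self.y, spar=spar)
        if self.method == "manual":
            return fit_manual(self.x, self.y, self.formula, self.start, self.weights)
        return fit_named_model(self.x, self.y, self.method, self.weights)
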