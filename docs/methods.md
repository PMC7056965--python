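# Methods

This note documents the models, conventions and numerical choices behind
`platecurve`, and what the synthetic test bed does and does not establish
about real plate-reader data.

## Data model and conventions

An experiment is the hierarchy *run ⊇ plate ⊇ well ⊇ measures*: every
observation belongs to exactly one run, plate and well. The canonical
container is a long table with key `(run, plate, well, runtime[,
measure_type])`, unique and sorted by runtime within each well, plus design
columns (strain, drug, dose, …) constant within a well.

Well labels are stored canonically at ingest — uppercase row letter and
two-digit column (`a1` → `A01`) — and all downstream equality is on the
canonical form; numbered wells (e.g. Bioscreen honeycomb plates) render
without padding. Plate geometry is inferred as the smallest standard plate
(12, 24, 48, 96 or 384 wells) covering the observed labels unless a reader
supplies it. Runtimes are absolute elapsed times (seconds, minutes or
hours, uniform across an experiment), not intervals, and need not start at
zero. Index expressions in formulas are 1-based and inclusive (`y[1:5]` is
the first five values), matching the convention growth-curve practitioners
know from statistical environments; this is deliberately *not* the host
language's slicing rule and is the single most important thing to remember
when writing formulas.

File-format detection is content-based (the first 50 lines), never
filename-based; filenames only drive measures↔design matching (a trailing
`_design`/`-design` token is stripped, then the longest common stem prefix
wins; ties are errors) and supply default run ids. Blank measure cells in
wide layouts are dropped, not imputed. The Bioscreen split of numbered
wells into plates of 100 mirrors the instrument's two-cassette layout.

## Preprocessing

Six independent options run in a fixed order: log-ratio transform → running
median → running mean → enforce-increasing → background formula →
calibration formula. Disabled steps are identities.

- **Log-ratio transform** `log_b(y / min(y))`: sigmoid growth models assume
  a log-ratio of population size over inoculum; the minimum (not the first)
  measure anchors the ratio so noisy early readings do not bias it. The
  minimum maps to exactly 0.
- **Running median / mean** with odd window width `k < n`: the median
  removes single-timepoint spikes (bubbles, glints), the mean attenuates
  low-amplitude high-frequency noise. Edges use symmetrically shrinking
  windows (widths 1, 3, …, k), so output length equals input length and no
  padding values are invented.
- **Enforce increasing** replaces any measure below its predecessor with
  that predecessor — the running maximum; idempotent. It counteracts dips
  from aggregation or precipitate but will also erase genuine declines
  (lysis, evaporation), so it is off by default.
- **Background / calibration formulas** are user expressions over the
  vectors `y` and `x` in a closed vocabulary (arithmetic, min/max/mean/
  median, log/log2/log10/exp/sqrt/abs, 1-based slices). The evaluator is a
  plain AST interpreter: nothing outside the vocabulary is representable,
  so formulas from config files and command lines cannot execute host code.

Background subtraction runs *after* the log transform because the chain
follows the interactive panel order users see; physically, optical
background is additive on the raw scale, so users wanting pre-log
subtraction should leave `log_base` off and log via the calibration formula
instead — a documented caveat, not a hidden behaviour. Wells with fewer
than 5 valid points after preprocessing are excluded from fitting and
listed in the run log; the threshold is this package's convention (below 5
points even the 3-parameter sigmoids are barely determined).

## Fitting

`GrowthCurveModel(x, y, method=...).fit()` returns a results object with
`predict`, `derivative`, named coefficients, quality statistics, `metrics()`
and `summary()`.

**Named sigmoids** use the (A, μ, λ) reparameterization given in the
README. Self-start values: `A₀ = max(y)`; `μ₀` = the largest
finite-difference slope; `λ₀` = the x-intercept of the tangent through the
max-slope point, clamped to `[0, t_max]`; `ν₀ = 1`. Optimization is
trust-region least squares with bounds `A > 0`, `μ > 0`, `λ ≥ 0`
(`ν > 0`), relative tolerance 1e-8 and an evaluation budget of 200 per
parameter; exponent arguments are clipped at ±700 to avoid overflow far
from the optimum. Non-convergence sets `converged=False` and warns but is
never fatal — a screening run must not die on one ugly well. A weighted
least-squares hook exists; default weights are uniform.

**Smoothing spline**: a cubic smoothing spline whose penalty λ is chosen by
generalized cross-validation, GCV(λ) = n·RSS / (n − df)², with
df = tr(S(λ)) obtained by smoothing the identity matrix. The search is a
17-point log-spaced grid bracketing pass followed by golden-section
refinement; at the reported tolerances the GCV surface is flat enough that
a finer search does not change any downstream metric materially. Quality
columns report the chosen penalty (`spar`), `df`, the GCV score (as both
`crit` and `cv.crit` — the criterion minimized *is* the cross-validation
score here) and the penalized RSS (RSS + λ·∫f″²). Duplicate abscissae
(possible after unit conversion) are averaged with a warning.

**Manual mode** fits any formula `y ~ f(x; params)` from user-supplied
starting values (`a = 1,w0 = 0.5, k = 0.00003` syntax). The derivative is
the symbolic derivative of the formula AST with respect to x; constructs
with no symbolic rule (aggregates, slices) fall back to central finite
differences with step 1e-6 of the time span. Parameters are unbounded —
the package cannot know the user's parameterization.

**Quality statistics** are Gaussian: logLik = −n/2·[ln 2π + ln(RSS/n) + 1];
AIC = 2(p+1) − 2·logLik and BIC = ln(n)(p+1) − 2·logLik count the error
variance as one parameter; sigma = √(RSS/(n−p)). RSS is floored at 1e-300
so a numerically perfect fit reports a finite log-likelihood rather than
overflowing.

## Summary metrics

Metrics are read off a uniform 1000-point grid over the observed domain
`[t_min, t_max]` (CLI-tunable; doubling the grid changes smooth-fit metrics
by < 0.1%). Maxima take the *first* grid index attaining the global
maximum. The tangent line at the max-slope point gives
`max_dy_b = max_dy_y − max_dy_m·max_dy_x` and
`max_dy_x0 = −max_dy_b / max_dy_m`; on a noiseless sigmoid in this
parameterization `max_dy_m ≈ μ` and `max_dy_x0 ≈ λ`, which ties the
model-free metrics to the model coefficients and is asserted in the test
suite. `fit_int` is the trapezoidal integral of the fitted curve over
`[t_min, t_max]` only — the fit is never extrapolated below the first
observation, so experiments that start late integrate over their own
support. Flat curves (max slope ≤ 1e-12) get missing intercepts and
doubling time rather than garbage ratios.

**Minimum doubling time** is ln 2 / μ*, where μ* is the maximum *specific*
growth rate: the grid maximum of d(ln ŷ)/dt on natural-scale fits, or
ln(b) × the maximum fitted slope when the measures were already
log_b-transformed upstream. This is the standard definition; it equals the
classical doubling time only during the exponential phase the maximum picks
out.

## Grouping

Groups are named positionally (`g1`, `g2`, … by line order;
`<plate>!g<k>` when plate-scoped) since the shorthand has no name field.
Rectangle corners may come in either order and are normalized; expansion is
row-major and inclusive. A well appearing on both sides of one spec is a
reference (is_ref wins): a well cannot be its own target within a group.
Wells may appear in any number of groups; the grouped view holds one row
per (row × matching group), and ungrouped wells stay in the ungrouped
outputs. Per-group means are computed per (group, is_ref) stratum with
pairwise deletion of missing metric values.

## Synthetic experiments

The generator emulates a chemical-genetic screening run: one 96-well (8×12)
plate read every 15 minutes for 94 cycles; three yeast strains crossed with
two compounds over an eight-step two-fold dilution from 50 µM down to a
zero-dose blank; an additive baseline offset of 0.08 (a typical blank OD);
Gaussian noise (default sd 0.01, ~1% of the asymptote); and optional
single-cycle spike artifacts. Truth parameters are drawn per well from
uniform ranges — A ∈ [0.8, 1.2] OD units, μ ∈ [5e-5, 2e-4] /s (doubling
times of roughly 1–4 h on the log scale), λ ∈ [5 000, 20 000] s — and dose
scales μ by 1/(1 + dose/IC50) with IC50 = 25 µM, so the design variables
have a real, recoverable effect. Each well draws from its own substream
keyed by (seed, run, plate, well): plate size or well order never changes
another well's draws, and the same configuration always emits byte-identical
files.

What passing tests on these fixtures show: the parsers, the preprocessing
algebra, parameter recovery under additive Gaussian noise, and the
end-to-end determinism of the pipeline. What they do not show: robustness
to the failure modes of real plates — evaporation and edge effects,
spatially correlated noise, condensation fronts, non-sigmoid diauxic
shifts, or the nonlinear OD–density relationship that calibration formulas
exist to correct. Conclusions about real data still require inspecting the
curves.

## Known limitations

- One measure type is modeled at a time; joint multi-channel fits are out
  of scope.
- All grouped plates must share one geometry.
- The spline's `crit` and `cv.crit` both report GCV; leave-one-out CV is
  not offered.
- Background subtraction after the log transform (see above).
- Plate-view rendering is static PNG; there is no interactive preview.
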