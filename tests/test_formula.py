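"""Formula-language tests, including an independent recursive interpreter
used as an oracle against the production evaluator."""

import math
import random

import numpy as np
import pytest

from platecurve.formula import (
    BinOp,
    Call,
    FormulaError,
    FormulaWarning,
    Index,
    Neg,
    Num,
    Var,
    differentiate,
    eval_model_formula,
    eval_well_formula,
    parse_formula,
    parse_start_values,
)


# ---------------------------------------------------------------------------
# Parsing


def test_parse_dynamic_background_subtraction():
    ast = parse_formula("y-min(y)", mode="well")
    assert ast == BinOp("-", Var("y"), Call("min", Var("y")))


def test_parse_fixed_background_literal():
    ast = parse_formula("y-0.081", mode="well")
    assert ast == BinOp("-", Var("y"), Num(0.081))


@pytest.mark.parametrize("sep", ["~", "?"])
def test_parse_model_formula_with_either_separator(sep):
    mf = parse_formula(f"y {sep} a - (a - w0) * exp(-k * x)", mode="model")
    assert mf.parameters == ("a", "w0", "k")


def test_power_is_right_associative_and_binds_over_unary_minus():
    ast = parse_formula("-2^2", mode="well")
    assert ast == Neg(BinOp("^", Num(2.0), Num(2.0)))
    ast = parse_formula("2^3^2", mode="well")
    assert ast == BinOp("^", Num(2.0), BinOp("^", Num(3.0), Num(2.0)))


def test_unknown_variable_in_well_mode_is_rejected():
    with pytest.raises(FormulaError, match="unknown variable"):
        parse_formula("y - z", mode="well")


def test_syntax_error_points_at_the_offending_position():
    with pytest.raises(FormulaError) as exc:
        parse_formula("y + * 2", mode="well")
    assert "^" in str(exc.value)


def test_model_formula_requires_a_parameter():
    with pytest.raises(FormulaError, match="parameter"):
        parse_formula("y ~ x + 1", mode="model")


@pytest.mark.parametrize(
    "hostile",
    [
        "__import__('os')",
        "open(y)",
        "y.__class__",
        "eval(y)",
        "exec(x)",
        "import os",
    ],
)
def test_no_host_code_is_reachable_from_a_formula(hostile):
    """Only the built-in vocabulary is representable: anything else fails to
    parse, so formulas cannot touch the filesystem or host names."""
    with pytest.raises(FormulaError):
        parse_formula(hostile, mode="well")


# ---------------------------------------------------------------------------
# Evaluation semantics


def test_subtracting_the_minimum_anchors_the_curve_at_zero():
    out = eval_well_formula(parse_formula("y-min(y)"), np.array([0.10, 0.30]), np.array([0.0, 1.0]))
    np.testing.assert_allclose(out, [0.0, 0.20])


def test_slices_are_one_based_inclusive():
    y = np.array([1.0, 1, 1, 1, 1, 2])
    x = np.arange(6.0)
    out = eval_well_formula(parse_formula("y-mean(y[1:5])"), y, x)
    np.testing.assert_allclose(out, [0, 0, 0, 0, 0, 1])


def test_identity_calibration_returns_values_unchanged():
    y = np.array([0.4, 0.5, 0.9])
    out = eval_well_formula(parse_formula("y"), y, np.arange(3.0))
    np.testing.assert_allclose(out, y)


def test_scalar_results_broadcast_to_input_length():
    out = eval_well_formula(parse_formula("max(y)"), np.array([1.0, 5.0, 2.0]), np.arange(3.0))
    np.testing.assert_allclose(out, [5.0, 5.0, 5.0])


def test_out_of_bounds_slice_is_an_error():
    with pytest.raises(FormulaError, match="out of bounds"):
        eval_well_formula(parse_formula("y[1:9]"), np.ones(3), np.arange(3.0))


def test_log_of_nonpositive_warns_and_yields_missing():
    with pytest.warns(FormulaWarning):
        out = eval_well_formula(parse_formula("log(y)"), np.array([-1.0, 1.0]), np.arange(2.0))
    assert np.isnan(out[0]) and out[1] == 0.0


# ---------------------------------------------------------------------------
# Start values


def test_start_values_parse_with_scientific_notation():
    out = parse_start_values("a = 1,w0 = 0.5, k = 0.00003")
    assert out == {"a": 1.0, "w0": 0.5, "k": 3e-5}
    assert list(out) == ["a", "w0", "k"]  # order preserved


def test_single_start_value():
    assert parse_start_values("a1 = 0.05") == {"a1": 0.05}


def test_duplicate_start_value_is_an_error():
    with pytest.raises(FormulaError, match="duplicate"):
        parse_start_values("a=1,a=2")


def test_start_value_for_a_non_parameter_is_an_error():
    with pytest.raises(FormulaError, match="not a model parameter"):
        parse_start_values("b=1", parameters=["a"])


# ---------------------------------------------------------------------------
# Oracle: an independent recursive interpreter over plain Python floats


def _oracle(node, env, n):
    """Evaluate an AST elementwise with pure-Python math; vectors are lists."""
    if isinstance(node, Num):
        return node.value
    if isinstance(node, Var):
        return env[node.name]
    if isinstance(node, Neg):
        return _map1(lambda v: -v, _oracle(node.operand, env, n))
    if isinstance(node, BinOp):
        a = _oracle(node.left, env, n)
        b = _oracle(node.right, env, n)
        op = {
            "+": lambda p, q: p + q,
            "-": lambda p, q: p - q,
            "*": lambda p, q: p * q,
            "/": lambda p, q: p / q,
            "^": lambda p, q: p**q if p >= 0 or float(q).is_integer() else math.nan,
        }[node.op]
        return _map2(op, a, b)
    if isinstance(node, Call):
        v = _oracle(node.arg, env, n)
        vec = v if isinstance(v, list) else [v]
        if node.func == "min":
            return min(vec)
        if node.func == "max":
            return max(vec)
        if node.func == "mean":
            return sum(vec) / len(vec)
        if node.func == "median":
            s = sorted(vec)
            m = len(s) // 2
            return s[m] if len(s) % 2 else 0.5 * (s[m - 1] + s[m])
        fn = {
            "log": lambda t: math.log(t) if t > 0 else math.nan,
            "log2": lambda t: math.log2(t) if t > 0 else math.nan,
            "log10": lambda t: math.log10(t) if t > 0 else math.nan,
            "exp": math.exp,
            "sqrt": math.sqrt,
            "abs": abs,
        }[node.func]
        return _map1(fn, v)
    if isinstance(node, Index):
        base = env[node.var]
        lo = int(_oracle(node.lo, env, n))
        if node.hi is None:
            return base[lo - 1]
        hi = int(_oracle(node.hi, env, n))
        return base[lo - 1 : hi]
    raise TypeError(node)


def _map1(f, v):
    return [f(t) for t in v] if isinstance(v, list) else f(v)


def _map2(f, a, b):
    if isinstance(a, list) and isinstance(b, list):
        return [f(p, q) for p, q in zip(a, b)]
    if isinstance(a, list):
        return [f(p, b) for p in a]
    if isinstance(b, list):
        return [f(a, q) for q in b]
    return f(a, b)


def _random_formula(rng, depth=0):
    if depth > 3 or rng.random() < 0.25:
        return rng.choice(["y", "x", "y[1]", "y[2:4]", "mean(y[1:3])",
                           f"{rng.uniform(0.1, 3.0):.3f}"])
    kind = rng.random()
    a = _random_formula(rng, depth + 1)
    b = _random_formula(rng, depth + 1)
    if kind < 0.5:
        op = rng.choice(["+", "-", "*", "/"])
        return f"({a}) {op} ({b})"
    if kind < 0.65:
        return f"({a}) ^ {rng.choice(['0.5', '2', '3'])}"
    if kind < 0.8:
        return f"-({a})"
    fn = rng.choice(["min", "max", "mean", "median", "log", "exp", "sqrt", "abs"])
    return f"{fn}({a})"


def test_production_evaluator_matches_independent_oracle_on_random_inputs():
    """1000 random (formula, input) evaluations agree between the production
    vectorized evaluator and a pure-Python recursive interpreter."""
    rng = random.Random(20260928)
    checked = 0
    while checked < 1000:
        text = _random_formula(rng)
        try:
            ast = parse_formula(text, mode="well")
        except FormulaError:
            continue
        for _ in range(5):
            n = rng.randint(4, 9)
            y = [rng.uniform(0.1, 5.0) for _ in range(n)]
            x = [rng.uniform(0.0, 10.0) for _ in range(n)]
            with np.errstate(all="ignore"):
                try:
                    import warnings

                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        got = eval_well_formula(ast, np.array(y), np.array(x))
                except FormulaError:
                    continue
                try:
                    want = _oracle(ast, {"y": y, "x": x}, n)
                except (OverflowError, ZeroDivisionError, ValueError):
                    continue
            want_vec = np.broadcast_to(
                np.asarray(want if isinstance(want, list) else [want], float), (n,)
            ) if not isinstance(want, list) or len(want) == n else None
            if want_vec is None:
                continue  # slice results shorter than n broadcast ambiguously
            if not np.all(np.isfinite(got)) or not np.all(np.isfinite(want_vec)):
                np.testing.assert_array_equal(np.isfinite(got), np.isfinite(want_vec))
            else:
                np.testing.assert_allclose(got, want_vec, rtol=1e-10, atol=1e-12)
            checked += 1
    assert checked >= 1000


def test_evaluation_is_pure():
    ast = parse_formula("y - mean(y[1:3]) + x/2")
    y = np.array([1.0, 2.0, 3.0, 4.0])
    x = np.array([0.0, 1.0, 2.0, 3.0])
    first = eval_well_formula(ast, y, x)
    for _ in range(3):
        np.testing.assert_array_equal(eval_well_formula(ast, y, x), first)


# ---------------------------------------------------------------------------
# Symbolic differentiation


@pytest.mark.parametrize(
    "formula, params",
    [
        ("y ~ a - (a - w0) * exp(-k * x)", {"a": 1.0, "w0": 0.5, "k": 3e-5}),
        ("y ~ a * x ^ 2 + b * x + c", {"a": 0.3, "b": -1.2, "c": 5.0}),
        ("y ~ a / (1 + exp(-k * (x - m)))", {"a": 2.0, "k": 0.8, "m": 4.0}),
        ("y ~ a * log(x + b)", {"a": 1.5, "b": 2.0}),
        ("y ~ a * sqrt(x + 1)", {"a": 0.7}),
    ],
)
def test_symbolic_derivative_matches_finite_differences(formula, params):
    mf = parse_formula(formula, mode="model")
    d = differentiate(mf.rhs, "x")
    from platecurve.formula import ModelFormula

    dmf = ModelFormula(rhs=d, parameters=mf.parameters)
    x = np.linspace(0.5, 10.0, 50)
    h = 1e-6
    fd = (eval_model_formula(mf, x + h, params) - eval_model_formula(mf, x - h, params)) / (2 * h)
    np.testing.assert_allclose(eval_model_formula(dmf, x, params), fd, rtol=1e-5, atol=1e-8)
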