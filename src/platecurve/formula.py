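"""A small, safe formula language for background correction, calibration and
user-specified growth models.

Formulas are single expressions over the vector variables ``y`` (the incoming
measures) and ``x`` (the runtime), numeric literals, named model parameters,
the arithmetic operators ``+ - * / ^`` (with ``^`` right-associative and
binding tighter than unary minus), the functions min, max, mean, median, log,
log2, log10, exp, sqrt, abs, and 1-based *inclusive* indexing/slicing
``y[a]`` / ``y[a:b]`` (so ``y[1:5]`` is the first five values).  min, max,
mean and median reduce a vector to a scalar, which then broadcasts; the other
functions apply elementwise.

Model formulas take the form ``y ~ <expression>`` where the right-hand side
may reference ``x`` and any number of free parameter names; both ``~`` and
``?`` are accepted as the separator and canonicalized to ``~``.

Nothing outside this vocabulary is representable: formulas cannot call host
functions, touch the filesystem or reference arbitrary names, so they are safe
to accept from config files and command lines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "FormulaError",
    "FormulaWarning",
    "ModelFormula",
    "parse_formula",
    "eval_well_formula",
    "eval_model_formula",
    "differentiate",
    "parse_start_values",
    "FUNCTIONS",
]

AGGREGATES = {"min", "max", "mean", "median"}
ELEMENTWISE = {"log", "log2", "log10", "exp", "sqrt", "abs"}
FUNCTIONS = AGGREGATES | ELEMENTWISE
RESERVED = FUNCTIONS | {"y", "x"}


class FormulaError(ValueError):
    """Parse or evaluation error; carries the offending position when known."""

    def __init__(self, message: str, text: Optional[str] = None, pos: Optional[int] = None):
        if text is not None and pos is not None:
            message = f"{message}\n  {text}\n  {' ' * pos}^"
        super().__init__(message)
        self.pos = pos


class FormulaWarning(UserWarning):
    """Non-fatal formula evaluation issue (e.g. log of a nonpositive value)."""


# ---------------------------------------------------------------------------
# AST nodes


@dataclass(frozen=True)
class Num:
    value: float


@dataclass(frozen=True)
class Var:
    name: str


@dataclass(frozen=True)
class Neg:
    operand: "Node"


@dataclass(frozen=True)
class BinOp:
    op: str  # + - * / ^
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class Call:
    func: str
    arg: "Node"


@dataclass(frozen=True)
class Index:
    """1-based inclusive index/slice of a variable: v[lo] or v[lo:hi]."""

    var: str
    lo: "Node"
    hi: Optional["Node"] = None


Node = Num | Var | Neg | BinOp | Call | Index


def free_variables(node: Node) -> set[str]:
    if isinstance(node, Num):
        return set()
    if isinstance(node, Var):
        return {node.name}
    if isinstance(node, Neg):
        return free_variables(node.operand)
    if isinstance(node, BinOp):
        return free_variables(node.left) | free_variables(node.right)
    if isinstance(node, Call):
        return free_variables(node.arg)
    if isinstance(node, Index):
        out = {node.var} | free_variables(node.lo)
        if node.hi is not None:
            out |= free_variables(node.hi)
        return out
    raise TypeError(node)


@dataclass(frozen=True)
class ModelFormula:
    """A parsed model specification ``y ~ rhs`` with its free parameters."""

    rhs: Node
    parameters: tuple[str, ...]
    text: str = ""

    def __str__(self) -> str:
        return self.text or "y ~ <expr>"


# ---------------------------------------------------------------------------
# Tokenizer / parser

_TOKEN_OPS = set("+-*/^(),[]:")


@dataclass
class _Token:
    kind: str  # num | name | op | end
    value: str
    pos: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c in _TOKEN_OPS:
            tokens.append(_Token("op", c, i))
            i += 1
            continue
        if c.isdigit() or c == ".":
            j = i
            while j < n and (text[j].isdigit() or text[j] == "."):
                j += 1
            if j < n and text[j] in "eE":
                k = j + 1
                if k < n and text[k] in "+-":
                    k += 1
                if k < n and text[k].isdigit():
                    j = k
                    while j < n and text[j].isdigit():
                        j += 1
            lit = text[i:j]
            try:
                float(lit)
            except ValueError:
                raise FormulaError(f"bad numeric literal {lit!r}", text, i) from None
            tokens.append(_Token("num", lit, i))
            i = j
            continue
        if c.isalpha() or c == "_":
            j = i
            while j < n and (text[j].isalnum() or text[j] == "_"):
                j += 1
            tokens.append(_Token("name", text[i:j], i))
            i = j
            continue
        raise FormulaError(f"unexpected character {c!r}", text, i)
    tokens.append(_Token("end", "", n))
    return tokens


class _Parser:
    """Recursive descent with precedence ``^`` > unary minus > ``* /`` > ``+ -``."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> _Token:
        return self.tokens[self.i]

    def next(self) -> _Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, value: str) -> _Token:
        tok = self.next()
        if tok.value != value:
            raise FormulaError(f"expected {value!r}", self.text, tok.pos)
        return tok

    def parse(self) -> Node:
        node = self.expr()
        tok = self.peek()
        if tok.kind != "end":
            raise FormulaError(f"unexpected {tok.value!r}", self.text, tok.pos)
        return node

    def expr(self) -> Node:
        node = self.term()
        while self.peek().value in ("+", "-"):
            op = self.next().value
            node = BinOp(op, node, self.term())
        return node

    def term(self) -> Node:
        node = self.unary()
        while self.peek().value in ("*", "/"):
            op = self.next().value
            node = BinOp(op, node, self.unary())
        return node

    def unary(self) -> Node:
        if self.peek().value == "-":
            self.next()
            return Neg(self.unary())
        return self.power()

    def power(self) -> Node:
        base = self.atom()
        if self.peek().value == "^":
            self.next()
            return BinOp("^", base, self.unary())  # right-associative
        return base

    def atom(self) -> Node:
        tok = self.next()
        if tok.kind == "num":
            return Num(float(tok.value))
        if tok.value == "(":
            node = self.expr()
            self.expect(")")
            return node
        if tok.kind == "name":
            if self.peek().value == "(":
                if tok.value not in FUNCTIONS:
                    raise FormulaError(
                        f"unknown function {tok.value!r}; allowed: {sorted(FUNCTIONS)}",
                        self.text,
                        tok.pos,
                    )
                self.next()
                arg = self.expr()
                self.expect(")")
                return Call(tok.value, arg)
            if self.peek().value == "[":
                self.next()
                lo = self.expr()
                hi = None
                if self.peek().value == ":":
                    self.next()
                    hi = self.expr()
                self.expect("]")
                return Index(tok.value, lo, hi)
            return Var(tok.value)
        raise FormulaError(f"unexpected {tok.value or 'end of formula'!r}", self.text, tok.pos)


def parse_formula(text: str, mode: str = "well") -> Node | ModelFormula:
    """Parse a formula string.

    mode="well": an expression over y and x (background/calibration); returns
    the AST.  mode="model": a full ``y ~ rhs`` specification; returns a
    :class:`ModelFormula` whose parameters are the rhs free names other than x,
    in order of first appearance.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    if mode == "well":
        ast = _Parser(text).parse()
        extra = free_variables(ast) - {"y", "x"}
        if extra:
            raise FormulaError(
                f"unknown variable(s) {sorted(extra)} in well formula (only y and x are available)"
            )
        return ast
    if mode != "model":
        raise ValueError(f"unknown formula mode {mode!r}")
    # the tilde renders as '?' in some documents; accept both
    canon = text.replace("?", "~", 1) if "~" not in text else text
    if "~" not in canon:
        raise FormulaError("model formula must have the form 'y ~ <expression>'")
    lhs, rhs_text = canon.split("~", 1)
    if lhs.strip() != "y":
        raise FormulaError(f"left side of a model formula must be 'y', got {lhs.strip()!r}")
    rhs = _Parser(rhs_text).parse()
    params: list[str] = []
    for name in _names_in_order(rhs):
        if name == "x" or name in params:
            continue
        if name == "y":
            raise FormulaError("model right-hand side may not reference y")
        params.append(name)
    if not params:
        raise FormulaError("model formula needs at least one free parameter")
    clash = set(params) & RESERVED
    if clash:
        raise FormulaError(f"parameter name(s) {sorted(clash)} are reserved")
    return ModelFormula(rhs=rhs, parameters=tuple(params), text=f"y ~{rhs_text.rstrip()}")


def _names_in_order(node: Node) -> list[str]:
    out: list[str] = []

    def walk(n: Node) -> None:
        if isinstance(n, Var):
            out.append(n.name)
        elif isinstance(n, Neg):
            walk(n.operand)
        elif isinstance(n, BinOp):
            walk(n.left)
            walk(n.right)
        elif isinstance(n, Call):
            walk(n.arg)
        elif isinstance(n, Index):
            out.append(n.var)
            walk(n.lo)
            if n.hi is not None:
                walk(n.hi)

    walk(node)
    return out


# ---------------------------------------------------------------------------
# Evaluation


def _eval(node: Node, env: dict[str, np.ndarray | float]) -> np.ndarray | float:
    if isinstance(node, Num):
        return node.value
    if isinstance(node, Var):
        return env[node.name]
    if isinstance(node, Neg):
        return -_eval(node.operand, env)
    if isinstance(node, BinOp):
        a = _eval(node.left, env)
        b = _eval(node.right, env)
        if node.op == "+":
            return a + b
        if node.op == "-":
            return a - b
        if node.op == "*":
            return a * b
        if node.op == "/":
            return a / b
        if node.op == "^":
            # float semantics: fractional powers of negatives are missing, not complex
            with np.errstate(all="ignore"):
                return np.float_power(a, b)
        raise FormulaError(f"unknown operator {node.op!r}")
    if isinstance(node, Call):
        v = _eval(node.arg, env)
        if node.func in AGGREGATES:
            fn = {"min": np.min, "max": np.max, "mean": np.mean, "median": np.median}[node.func]
            return float(fn(np.asarray(v, dtype=float)))
        if node.func in ("log", "log2", "log10"):
            arr = np.asarray(v, dtype=float)
            bad = arr <= 0
            if np.any(bad):
                warnings.warn(
                    f"{node.func} of nonpositive value(s); result set to missing",
                    FormulaWarning,
                    stacklevel=2,
                )
            with np.errstate(divide="ignore", invalid="ignore"):
                out = {"log": np.log, "log2": np.log2, "log10": np.log10}[node.func](arr)
            out = np.where(bad, np.nan, out)
            return float(out) if np.isscalar(v) or np.ndim(v) == 0 else out
        if node.func == "sqrt":
            return np.sqrt(v)
        if node.func == "abs":
            return np.abs(v)
        if node.func == "exp":
            return np.exp(v)
        raise FormulaError(f"unknown function {node.func!r}")
    if isinstance(node, Index):
        base = np.asarray(env[node.var], dtype=float)
        lo = _index_value(node.lo, env)
        hi = _index_value(node.hi, env) if node.hi is not None else None
        n = base.shape[0] if base.ndim else 1
        if node.hi is None:
            if not (1 <= lo <= n):
                raise FormulaError(f"index {lo} out of bounds for length {n}")
            return float(base[lo - 1])
        if not (1 <= lo <= hi <= n):
            raise FormulaError(f"slice [{lo}:{hi}] out of bounds for length {n}")
        return base[lo - 1 : hi]  # 1-based inclusive
    raise TypeError(node)


def _index_value(node: Node, env: dict) -> int:
    v = _eval(node, env)
    if not np.isscalar(v) and np.ndim(v) != 0:
        raise FormulaError("indices must be scalars")
    iv = int(round(float(v)))
    if abs(iv - float(v)) > 1e-9:
        raise FormulaError(f"non-integer index {v}")
    return iv


def eval_well_formula(ast: Node, y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Evaluate a background/calibration formula on one well's vectors.

    The result always has the same length as the input; scalar results (e.g.
    the formula ``min(y)``) broadcast.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1 or y.size < 1:
        raise ValueError("y and x must be 1-D vectors of equal, nonzero length")
    try:
        out = _eval(ast, {"y": y, "x": x})
        return np.broadcast_to(np.asarray(out, dtype=float), y.shape).copy()
    except FormulaError:
        raise
    except ValueError as e:  # shape mismatches from slice arithmetic
        raise FormulaError(f"formula result does not conform to the well length: {e}") from None


def eval_model_formula(model: ModelFormula, x: np.ndarray, params: dict[str, float]) -> np.ndarray:
    """Evaluate a model's right-hand side at runtimes ``x`` with ``params``."""
    missing = [p for p in model.parameters if p not in params]
    if missing:
        raise FormulaError(f"missing parameter value(s): {missing}")
    x = np.asarray(x, dtype=float)
    env: dict[str, np.ndarray | float] = {"x": x}
    env.update({k: float(v) for k, v in params.items()})
    out = _eval(model.rhs, env)
    return np.broadcast_to(np.asarray(out, dtype=float), x.shape).copy()


# ---------------------------------------------------------------------------
# Symbolic differentiation (for analytic model derivatives)


class NotDifferentiable(FormulaError):
    """The AST contains a construct with no symbolic derivative (slice/aggregate)."""


def differentiate(node: Node, wrt: str = "x") -> Node:
    """Symbolic derivative of an AST with respect to ``wrt``.

    Supports the arithmetic operators and elementwise functions; aggregates
    and slices raise :class:`NotDifferentiable` (callers fall back to finite
    differences).
    """
    if isinstance(node, Num):
        return Num(0.0)
    if isinstance(node, Var):
        return Num(1.0) if node.name == wrt else Num(0.0)
    if isinstance(node, Neg):
        return Neg(differentiate(node.operand, wrt))
    if isinstance(node, BinOp):
        u, v = node.left, node.right
        du, dv = differentiate(u, wrt), differentiate(v, wrt)
        if node.op in ("+", "-"):
            return BinOp(node.op, du, dv)
        if node.op == "*":
            return BinOp("+", BinOp("*", du, v), BinOp("*", u, dv))
        if node.op == "/":
            num = BinOp("-", BinOp("*", du, v), BinOp("*", u, dv))
            return BinOp("/", num, BinOp("^", v, Num(2.0)))
        if node.op == "^":
            if isinstance(v, Num):  # u^c -> c*u^(c-1)*u'
                return BinOp("*", BinOp("*", v, BinOp("^", u, Num(v.value - 1.0))), du)
            # general: u^v * (v' ln u + v u'/u)
            term = BinOp("+", BinOp("*", dv, Call("log", u)), BinOp("*", v, BinOp("/", du, u)))
            return BinOp("*", BinOp("^", u, v), term)
    if isinstance(node, Call):
        du = differentiate(node.arg, wrt)
        u = node.arg
        if node.func == "exp":
            return BinOp("*", Call("exp", u), du)
        if node.func == "log":
            return BinOp("/", du, u)
        if node.func == "log2":
            return BinOp("/", du, BinOp("*", u, Num(math.log(2.0))))
        if node.func == "log10":
            return BinOp("/", du, BinOp("*", u, Num(math.log(10.0))))
        if node.func == "sqrt":
            return BinOp("/", du, BinOp("*", Num(2.0), Call("sqrt", u)))
        if node.func == "abs":
            return BinOp("*", BinOp("/", u, Call("abs", u)), du)
        raise NotDifferentiable(f"no symbolic derivative for {node.func}()")
    if isinstance(node, Index):
        raise NotDifferentiable("no symbolic derivative for index/slice expressions")
    raise TypeError(node)


# ---------------------------------------------------------------------------
# Starting values


def parse_start_values(text: str, parameters: Optional[list[str]] = None) -> dict[str, float]:
    """Parse 'a = 1,w0 = 0.5, k = 0.00003' into an ordered name->value map.

    When ``parameters`` is given, every name must be one of them.
    """
    out: dict[str, float] = {}
    if not text or not text.strip():
        raise FormulaError("empty starting-value list")
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise FormulaError(f"starting value {part!r} is not of the form name=value")
        name, _, val = part.partition("=")
        name = name.strip()
        val = val.strip()
        if not name.isidentifier():
            raise FormulaError(f"bad parameter name {name!r}")
        if name in out:
            raise FormulaError(f"duplicate starting value for {name!r}")
        if not val:
            raise FormulaError(f"missing value for parameter {name!r}")
        try:
            out[name] = float(val)
        except ValueError:
            raise FormulaError(f"bad numeric value {val!r} for parameter {name!r}") from None
        if parameters is not None and name not in parameters:
            raise FormulaError(f"{name!r} is not a model parameter (expected one of {parameters})")
    if not out:
        raise FormulaError("empty starting-value list")
    return out
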