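"""Restricted arithmetic expression language for flow and auxiliary equations.

Model equations are short arithmetic expressions over parameter names,
stock and auxiliary names, and the simulation clock ``time``.  Variable
names that are not valid Python identifiers (stock names such as
``Patient Engagement`` contain spaces) are written in square brackets,
mirroring common system-dynamics tool syntax::

    alpha_pe * [Patient-Centric] * max(0, 1 - [Patient Engagement] / K_pe)

The language is deliberately small: numeric literals, name references,
the four arithmetic operators, unary minus, parentheses, and four
functions — ``min``, ``max``, the smooth saturation ``sat(x) = x/(1+|x|)``
and the ramp ``ramp(x) = max(x, 0)``.  Anything richer (attribute
access, comparisons, comprehensions, other calls) is rejected at parse
time, so a model file can never execute arbitrary code.
"""

from __future__ import annotations

import ast
import hashlib
import re
from dataclasses import dataclass, field

__all__ = ["ExprError", "CompiledExpr", "compile_expr", "mangle_symbol", "TIME"]

#: Reserved name for the simulation clock inside expressions.
TIME = "time"

_BRACKET_RE = re.compile(r"\[([^\[\]]+)\]")
_SANITIZE_RE = re.compile(r"\W+")
#: Bracketed names must look like variable names: leading letter, then
#: word characters, spaces, hyphens or dashes.
_NAME_RE = re.compile(r"[^\W\d_][\w \-–—']*")


def _sat(x: float) -> float:
    """Smooth saturation: x / (1 + |x|); maps [0, inf) onto [0, 1)."""
    return x / (1.0 + abs(x))


def _ramp(x: float) -> float:
    return x if x > 0.0 else 0.0


_FUNCS: dict[str, object] = {"min": min, "max": max, "sat": _sat, "ramp": _ramp}

_ALLOWED_NODES = (
    ast.Expression,
    ast.BinOp,
    ast.UnaryOp,
    ast.Add,
    ast.Sub,
    ast.Mult,
    ast.Div,
    ast.USub,
    ast.UAdd,
    ast.Constant,
    ast.Name,
    ast.Call,
    ast.Load,
)


class ExprError(ValueError):
    """Raised when an expression fails to parse or uses a disallowed form."""

    def __init__(self, expr: str, message: str):
        self.expr = expr
        super().__init__(f"{message} in expression {expr!r}")


def mangle_symbol(name: str) -> str:
    """Deterministic internal identifier for a model symbol.

    Valid Python identifiers (that do not shadow a builtin function of
    the language) pass through unchanged; anything else — names with
    spaces, hyphens, etc. — is sanitized and suffixed with a short hash
    so distinct symbols can never collide.
    """
    if name.isidentifier() and name not in _FUNCS:
        return name
    digest = hashlib.md5(name.encode()).hexdigest()[:8]
    return f"_v_{_SANITIZE_RE.sub('_', name).strip('_')}_{digest}"


@dataclass(frozen=True)
class CompiledExpr:
    """A validated expression compiled to a Python code object.

    ``names`` is the set of model symbols the expression reads (``time``
    included when referenced).  The code object refers to symbols via
    :func:`mangle_symbol`, so many expressions can share one evaluation
    environment keyed by mangled identifiers.
    """

    source: str
    names: frozenset[str]
    code: object = field(compare=False, repr=False)

    def evaluate(self, env: dict[str, float]) -> float:
        """Evaluate against ``env`` mapping model symbol -> value."""
        local = {mangle_symbol(n): env[n] for n in self.names}
        return eval(self.code, {"__builtins__": {}, **_FUNCS}, local)  # noqa: S307

    def evaluate_mangled(self, mangled_env: dict[str, float]) -> float:
        """Fast path: ``mangled_env`` is keyed by mangled identifiers."""
        return eval(self.code, _EVAL_GLOBALS, mangled_env)  # noqa: S307


_EVAL_GLOBALS = {"__builtins__": {}, **_FUNCS}


def compile_expr(source: str) -> CompiledExpr:
    """Parse, validate and compile an expression.

    Raises :class:`ExprError` on syntax errors, disallowed constructs,
    non-numeric literals, or calls to functions outside the whitelist.
    """
    if not isinstance(source, str) or not source.strip():
        raise ExprError(str(source), "empty expression")

    table: dict[str, str] = {}

    def _sub(match: re.Match) -> str:
        name = match.group(1).strip()
        if not _NAME_RE.fullmatch(name):
            raise ExprError(source, f"invalid bracketed name {name!r}")
        mangled = mangle_symbol(name)
        table[mangled] = name
        return mangled

    mangled_src = _BRACKET_RE.sub(_sub, source)
    if "[" in mangled_src or "]" in mangled_src:
        raise ExprError(source, "unbalanced square brackets")

    try:
        tree = ast.parse(mangled_src, mode="eval")
    except SyntaxError as exc:
        raise ExprError(source, f"syntax error: {exc.msg}") from None

    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise ExprError(source, f"disallowed construct {type(node).__name__}")
        if isinstance(node, ast.Constant) and not isinstance(node.value, (int, float)):
            raise ExprError(source, f"non-numeric literal {node.value!r}")
        if isinstance(node, ast.Call):
            if not isinstance(node.func, ast.Name) or node.func.id not in _FUNCS:
                raise ExprError(source, "call to unknown function")
            if node.keywords:
                raise ExprError(source, "keyword arguments not supported")

    call_funcs = {id(n.func) for n in ast.walk(tree) if isinstance(n, ast.Call)}
    names: set[str] = set()
    for node in ast.walk(tree):
        if isinstance(node, ast.Name) and id(node) not in call_funcs:
            if node.id in _FUNCS:
                raise ExprError(source, f"{node.id!r} is a function, not a value")
            names.add(table.get(node.id, node.id))

    code = compile(tree, f"<expr: {source}>", "eval")
    return CompiledExpr(source=source, names=frozenset(names), code=code)
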