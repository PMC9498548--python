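"""Whitelist-based arithmetic expression evaluation for auxiliary variables.

Auxiliary rate expressions are plain arithmetic over parameter, stock and
auxiliary names (plus ``t``), with a handful of elementary functions. They
are parsed once with :mod:`ast`, checked against a node whitelist, and
compiled to code objects so the simulation inner loop pays only an ``eval``
of pre-compiled bytecode per auxiliary per step.
"""

from __future__ import annotations

import ast
import math

__all__ = ["ExpressionError", "referenced_names", "compile_expression", "FUNCTIONS"]


def _clamp(x: float, lo: float, hi: float) -> float:
    return lo if x < lo else hi if x > hi else x


#: Functions callable from auxiliary expressions.
FUNCTIONS = {
    "min": min,
    "max": max,
    "abs": abs,
    "exp": math.exp,
    "log": math.log,
    "sqrt": math.sqrt,
    "clamp": _clamp,
}

_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow)
_ALLOWED_UNARY = (ast.USub, ast.UAdd)


class ExpressionError(ValueError):
    """Raised when an expression cannot be parsed or uses forbidden syntax."""


def _parse(expression: str) -> ast.Expression:
    try:
        tree = ast.parse(expression, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"cannot parse expression {expression!r}: {exc}") from exc
    for node in ast.walk(tree):
        if isinstance(node, (ast.Expression, ast.Name, ast.Load)):
            continue
        if isinstance(node, ast.Constant):
            if not isinstance(node.value, (int, float)):
                raise ExpressionError(
                    f"non-numeric constant {node.value!r} in {expression!r}"
                )
            continue
        if isinstance(node, ast.BinOp) and isinstance(node.op, _ALLOWED_BINOPS):
            continue
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, _ALLOWED_UNARY):
            continue
        if isinstance(node, _ALLOWED_BINOPS + _ALLOWED_UNARY):
            continue
        if isinstance(node, ast.Call):
            if (
                isinstance(node.func, ast.Name)
                and node.func.id in FUNCTIONS
                and not node.keywords
            ):
                continue
            raise ExpressionError(
                f"only calls to {sorted(FUNCTIONS)} are allowed, got "
                f"{ast.dump(node.func)} in {expression!r}"
            )
        raise ExpressionError(
            f"forbidden syntax {type(node).__name__} in expression {expression!r}"
        )
    return tree


def referenced_names(expression: str) -> set[str]:
    """Names an expression reads (function names excluded)."""
    tree = _parse(expression)
    names: set[str] = set()
    for node in ast.walk(tree):
        if isinstance(node, ast.Name) and node.id not in FUNCTIONS:
            names.add(node.id)
    return names


def compile_expression(expression: str):
    """Validate and compile an expression; evaluate with :func:`evaluate`."""
    return compile(_parse(expression), f"<expr:{expression}>", "eval")


_EVAL_GLOBALS = {"__builtins__": {}, **FUNCTIONS}


def evaluate(code, namespace: dict) -> float:
    """Evaluate a compiled expression against a name → value namespace."""
    return eval(code, _EVAL_GLOBALS, namespace)
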