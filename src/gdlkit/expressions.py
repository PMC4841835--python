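"""The declarative expression language for features and key-frame rules.

Expressions are data, not code: a small functional/infix notation parsed
into an AST, type-checked against the active topology and feature list, and
compiled to fast closures for per-frame evaluation.  Three value types
exist — ``number`` (float), ``vector`` (3-D float array) and ``boolean``.

Grammar (precedence low to high)::

    expr    := or
    or      := and ('or' and)*
    and     := not ('and' not)*
    not     := 'not' not | cmp
    cmp     := arith (('<'|'<='|'>'|'>='|'=='|'!=') arith)?
    arith   := term (('+'|'-') term)*
    term    := unary (('*'|'/') unary)*
    unary   := '-' unary | primary
    primary := NUMBER | 'true' | 'false' | IDENT | IDENT '(' args ')' | '(' expr ')'

Built-in functions: ``vec(x,y,z)``, ``joint(Name)``, ``prev(Feature)``,
``add/sub`` (numbers or vectors), ``scale(v,s)``, ``dot``, ``cross``,
``norm``, ``angle`` (degrees), component accessors ``x/y/z``, ``abs``,
``sqrt``, ``min``, ``max``, ``sin``, ``cos``, ``tan``, ``atan2`` (radians),
``degrees``, ``radians``.  ``joint`` is only available in feature
definitions (rules see features, not raw joints); ``prev`` reads the
previous frame's value of an earlier-defined feature and falls back to the
current frame's value when there is no history yet.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import DegenerateVectorError, ExpressionError, ValidationError

__all__ = [
    "Node", "Num", "BoolLit", "Ref", "JointRef", "Prev", "Call", "BinOp", "UnOp",
    "parse", "to_source", "infer_type", "compile_expr", "EvalContext",
]

NUMBER, VECTOR, BOOLEAN = "number", "vector", "boolean"


# --------------------------------------------------------------------------
# AST
# --------------------------------------------------------------------------

class Node:
    __slots__ = ()


@dataclass(frozen=True)
class Num(Node):
    value: float


@dataclass(frozen=True)
class BoolLit(Node):
    value: bool


@dataclass(frozen=True)
class Ref(Node):
    """Reference to a previously defined feature."""
    name: str


@dataclass(frozen=True)
class JointRef(Node):
    name: str


@dataclass(frozen=True)
class Prev(Node):
    name: str


@dataclass(frozen=True)
class Call(Node):
    func: str
    args: tuple


@dataclass(frozen=True)
class BinOp(Node):
    op: str
    left: Node
    right: Node


@dataclass(frozen=True)
class UnOp(Node):
    op: str  # '-' or 'not'
    operand: Node


# --------------------------------------------------------------------------
# tokenizer / parser
# --------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"""
    (?P<num>\d+\.\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?|\d+(?:[eE][+-]?\d+)?)
  | (?P<ident>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<op><=|>=|==|!=|[-+*/<>(),])
  | (?P<ws>\s+)
""", re.VERBOSE)

_KEYWORDS = {"and", "or", "not", "true", "false"}


def _tokenize(text: str) -> list[tuple[str, str]]:
    out, i = [], 0
    while i < len(text):
        m = _TOKEN_RE.match(text, i)
        if not m:
            raise ExpressionError(f"bad character {text[i]!r} at position {i} in {text!r}")
        i = m.end()
        if m.lastgroup == "ws":
            continue
        out.append((m.lastgroup, m.group()))
    out.append(("eof", ""))
    return out


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.toks = _tokenize(text)
        self.i = 0

    def peek(self) -> tuple[str, str]:
        return self.toks[self.i]

    def next(self) -> tuple[str, str]:
        tok = self.toks[self.i]
        self.i += 1
        return tok

    def expect(self, value: str) -> None:
        kind, val = self.next()
        if val != value:
            raise ExpressionError(f"expected {value!r}, got {val!r} in {self.text!r}")

    def parse(self) -> Node:
        node = self.or_expr()
        if self.peek()[0] != "eof":
            raise ExpressionError(f"trailing input {self.peek()[1]!r} in {self.text!r}")
        return node

    def or_expr(self) -> Node:
        node = self.and_expr()
        while self.peek() == ("ident", "or"):
            self.next()
            node = BinOp("or", node, self.and_expr())
        return node

    def and_expr(self) -> Node:
        node = self.not_expr()
        while self.peek() == ("ident", "and"):
            self.next()
            node = BinOp("and", node, self.not_expr())
        return node

    def not_expr(self) -> Node:
        if self.peek() == ("ident", "not"):
            self.next()
            return UnOp("not", self.not_expr())
        return self.cmp_expr()

    def cmp_expr(self) -> Node:
        node = self.arith()
        kind, val = self.peek()
        if kind == "op" and val in ("<", "<=", ">", ">=", "==", "!="):
            self.next()
            node = BinOp(val, node, self.arith())
        return node

    def arith(self) -> Node:
        node = self.term()
        while self.peek()[0] == "op" and self.peek()[1] in "+-":
            op = self.next()[1]
            node = BinOp(op, node, self.term())
        return node

    def term(self) -> Node:
        node = self.unary()
        while self.peek()[0] == "op" and self.peek()[1] in "*/":
            op = self.next()[1]
            node = BinOp(op, node, self.unary())
        return node

    def unary(self) -> Node:
        if self.peek() == ("op", "-"):
            self.next()
            return UnOp("-", self.unary())
        return self.primary()

    def primary(self) -> Node:
        kind, val = self.next()
        if kind == "num":
            return Num(float(val))
        if kind == "op" and val == "(":
            node = self.or_expr()
            self.expect(")")
            return node
        if kind == "ident":
            if val == "true":
                return BoolLit(True)
            if val == "false":
                return BoolLit(False)
            if val in ("and", "or", "not"):
                raise ExpressionError(f"unexpected keyword {val!r} in {self.text!r}")
            if self.peek() == ("op", "("):
                self.next()
                if val in ("joint", "prev"):
                    k, name = self.next()
                    if k != "ident":
                        raise ExpressionError(f"{val}() takes a bare identifier")
                    self.expect(")")
                    return JointRef(name) if val == "joint" else Prev(name)
                args: list[Node] = []
                if self.peek() != ("op", ")"):
                    args.append(self.or_expr())
                    while self.peek() == ("op", ","):
                        self.next()
                        args.append(self.or_expr())
                self.expect(")")
                return Call(val, tuple(args))
            return Ref(val)
        raise ExpressionError(f"unexpected token {val!r} in {self.text!r}")


def parse(text: str) -> Node:
    """Parse expression source into an AST."""
    return _Parser(text).parse()


# --------------------------------------------------------------------------
# canonical printing
# --------------------------------------------------------------------------

_PREC = {"or": 1, "and": 2, "not": 3,
         "<": 4, "<=": 4, ">": 4, ">=": 4, "==": 4, "!=": 4,
         "+": 5, "-": 5, "*": 6, "/": 6, "neg": 7}


def _num_str(v: float) -> str:
    return repr(float(v))


def to_source(node: Node, _parent_prec: int = 0) -> str:
    """Deterministic canonical source for an AST.

    ``parse(to_source(n))`` is structurally equal to ``n`` and
    ``to_source`` is idempotent through a parse cycle, which makes
    serialized definition files byte-stable across read/write round trips.
    """
    if isinstance(node, Num):
        s = _num_str(node.value)
        prec = 8
    elif isinstance(node, BoolLit):
        s, prec = ("true" if node.value else "false"), 8
    elif isinstance(node, Ref):
        s, prec = node.name, 8
    elif isinstance(node, JointRef):
        s, prec = f"joint({node.name})", 8
    elif isinstance(node, Prev):
        s, prec = f"prev({node.name})", 8
    elif isinstance(node, Call):
        s = f"{node.func}({', '.join(to_source(a) for a in node.args)})"
        prec = 8
    elif isinstance(node, UnOp):
        prec = _PREC["not"] if node.op == "not" else _PREC["neg"]
        inner = to_source(node.operand, prec)
        s = f"not {inner}" if node.op == "not" else f"-{inner}"
    elif isinstance(node, BinOp):
        prec = _PREC[node.op]
        # left-associative: right child needs strictly higher precedence
        left = to_source(node.left, prec)
        right = to_source(node.right, prec + 1)
        s = f"{left} {node.op} {right}"
    else:  # pragma: no cover
        raise TypeError(f"unknown node {node!r}")
    if prec < _parent_prec:
        s = f"({s})"
    return s


# --------------------------------------------------------------------------
# type checking
# --------------------------------------------------------------------------

_FUNC_SIGS: dict[str, list[tuple[tuple[str, ...], str]]] = {
    "vec": [((NUMBER, NUMBER, NUMBER), VECTOR)],
    "add": [((NUMBER, NUMBER), NUMBER), ((VECTOR, VECTOR), VECTOR)],
    "sub": [((NUMBER, NUMBER), NUMBER), ((VECTOR, VECTOR), VECTOR)],
    "scale": [((VECTOR, NUMBER), VECTOR)],
    "dot": [((VECTOR, VECTOR), NUMBER)],
    "cross": [((VECTOR, VECTOR), VECTOR)],
    "norm": [((VECTOR,), NUMBER)],
    "angle": [((VECTOR, VECTOR), NUMBER)],
    "x": [((VECTOR,), NUMBER)],
    "y": [((VECTOR,), NUMBER)],
    "z": [((VECTOR,), NUMBER)],
    "abs": [((NUMBER,), NUMBER)],
    "sqrt": [((NUMBER,), NUMBER)],
    "min": [((NUMBER, NUMBER), NUMBER)],
    "max": [((NUMBER, NUMBER), NUMBER)],
    "sin": [((NUMBER,), NUMBER)],
    "cos": [((NUMBER,), NUMBER)],
    "tan": [((NUMBER,), NUMBER)],
    "atan2": [((NUMBER, NUMBER), NUMBER)],
    "degrees": [((NUMBER,), NUMBER)],
    "radians": [((NUMBER,), NUMBER)],
}


def infer_type(node: Node,
               feature_kinds: Mapping[str, str],
               joints: Sequence[str] | None) -> str:
    """Type-check an AST; returns its result type.

    ``feature_kinds`` maps earlier feature names to their value type
    (``number``/``vector``/``boolean``).  ``joints`` is the set of legal
    joint names, or ``None`` when ``joint()`` is not allowed (rule context).
    Raises :class:`ValidationError` on unknown references and
    :class:`ExpressionError` on type mismatches.
    """
    if isinstance(node, Num):
        return NUMBER
    if isinstance(node, BoolLit):
        return BOOLEAN
    if isinstance(node, Ref):
        if node.name not in feature_kinds:
            raise ValidationError(f"reference to undefined feature {node.name!r}")
        return feature_kinds[node.name]
    if isinstance(node, JointRef):
        if joints is None:
            raise ValidationError(
                f"joint({node.name}) is not allowed in this context (rules see features only)")
        if node.name not in joints:
            raise ValidationError(f"unknown joint {node.name!r}")
        return VECTOR
    if isinstance(node, Prev):
        if node.name not in feature_kinds:
            raise ValidationError(f"prev() of undefined feature {node.name!r}")
        return feature_kinds[node.name]
    if isinstance(node, Call):
        sigs = _FUNC_SIGS.get(node.func)
        if sigs is None:
            raise ValidationError(f"unknown function {node.func!r}")
        arg_types = tuple(infer_type(a, feature_kinds, joints) for a in node.args)
        for params, ret in sigs:
            if params == arg_types:
                return ret
        raise ExpressionError(
            f"{node.func}() does not accept argument types {arg_types}")
    if isinstance(node, UnOp):
        t = infer_type(node.operand, feature_kinds, joints)
        if node.op == "not":
            if t != BOOLEAN:
                raise ExpressionError(f"'not' needs a boolean, got {t}")
            return BOOLEAN
        if t == NUMBER:
            return NUMBER
        if t == VECTOR:
            return VECTOR
        raise ExpressionError(f"unary '-' needs number or vector, got {t}")
    if isinstance(node, BinOp):
        lt = infer_type(node.left, feature_kinds, joints)
        rt = infer_type(node.right, feature_kinds, joints)
        op = node.op
        if op in ("and", "or"):
            if lt != BOOLEAN or rt != BOOLEAN:
                raise ExpressionError(f"{op!r} needs booleans, got {lt}, {rt}")
            return BOOLEAN
        if op in ("<", "<=", ">", ">=", "==", "!="):
            if lt != NUMBER or rt != NUMBER:
                raise ExpressionError(f"comparison {op!r} needs numbers, got {lt}, {rt}")
            return BOOLEAN
        if op in ("+", "-"):
            if lt == rt and lt in (NUMBER, VECTOR):
                return lt
            raise ExpressionError(f"{op!r} needs two numbers or two vectors, got {lt}, {rt}")
        if op == "*":
            if lt == rt == NUMBER:
                return NUMBER
            if {lt, rt} == {NUMBER, VECTOR}:
                return VECTOR
            raise ExpressionError(f"'*' needs numbers or vector*number, got {lt}, {rt}")
        if op == "/":
            if lt == NUMBER and rt == NUMBER:
                return NUMBER
            if lt == VECTOR and rt == NUMBER:
                return VECTOR
            raise ExpressionError(f"'/' needs number/number or vector/number, got {lt}, {rt}")
    raise TypeError(f"unknown node {node!r}")  # pragma: no cover


# --------------------------------------------------------------------------
# compilation
# --------------------------------------------------------------------------

@dataclass
class EvalContext:
    """Per-frame evaluation environment.

    ``values`` accumulates this frame's feature values as they are computed
    in definition order; ``prev_values`` holds the previous frame's values
    (or ``None`` on the first frame).
    """
    positions: Mapping[str, np.ndarray] | None
    values: dict
    prev_values: Mapping | None = None
    timestamp: float = 0.0


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    na = math.sqrt(float(a[0] * a[0] + a[1] * a[1] + a[2] * a[2]))
    nb = math.sqrt(float(b[0] * b[0] + b[1] * b[1] + b[2] * b[2]))
    if na == 0.0:
        raise DegenerateVectorError("left")
    if nb == 0.0:
        raise DegenerateVectorError("right")
    cx = a[1] * b[2] - a[2] * b[1]
    cy = a[2] * b[0] - a[0] * b[2]
    cz = a[0] * b[1] - a[1] * b[0]
    cn = math.sqrt(float(cx * cx + cy * cy + cz * cz))
    d = float(a[0] * b[0] + a[1] * b[1] + a[2] * b[2])
    return math.degrees(math.atan2(cn, d))


_IMPLS: dict[str, Callable] = {
    "vec": lambda x, y, z: np.array([x, y, z], dtype=float),
    "add": lambda a, b: a + b,
    "sub": lambda a, b: a - b,
    "scale": lambda v, s: v * s,
    "dot": lambda a, b: float(np.dot(a, b)),
    "cross": lambda a, b: np.cross(a, b),
    "norm": lambda a: float(np.linalg.norm(a)),
    "angle": _angle_deg,
    "x": lambda v: float(v[0]),
    "y": lambda v: float(v[1]),
    "z": lambda v: float(v[2]),
    "abs": abs,
    "sqrt": math.sqrt,
    "min": min,
    "max": max,
    "sin": math.sin,
    "cos": math.cos,
    "tan": math.tan,
    "atan2": math.atan2,
    "degrees": math.degrees,
    "radians": math.radians,
}


def compile_expr(node: Node) -> Callable[[EvalContext], object]:
    """Compile an AST into a closure over an :class:`EvalContext`.

    Assumes the AST already passed :func:`infer_type`; the closures do no
    type checking of their own.
    """
    if isinstance(node, Num):
        v = node.value
        return lambda ctx: v
    if isinstance(node, BoolLit):
        v = node.value
        return lambda ctx: v
    if isinstance(node, Ref):
        name = node.name
        return lambda ctx: ctx.values[name]
    if isinstance(node, JointRef):
        name = node.name
        return lambda ctx: ctx.positions[name]
    if isinstance(node, Prev):
        name = node.name

        def prev_fn(ctx: EvalContext):
            if ctx.prev_values is not None:
                return ctx.prev_values[name]
            return ctx.values[name]
        return prev_fn
    if isinstance(node, Call):
        impl = _IMPLS[node.func]
        args = [compile_expr(a) for a in node.args]
        if len(args) == 1:
            a0 = args[0]
            return lambda ctx: impl(a0(ctx))
        if len(args) == 2:
            a0, a1 = args
            return lambda ctx: impl(a0(ctx), a1(ctx))
        if len(args) == 3:
            a0, a1, a2 = args
            return lambda ctx: impl(a0(ctx), a1(ctx), a2(ctx))
        return lambda ctx: impl(*[a(ctx) for a in args])
    if isinstance(node, UnOp):
        inner = compile_expr(node.operand)
        if node.op == "not":
            return lambda ctx: not inner(ctx)
        return lambda ctx: -inner(ctx)
    if isinstance(node, BinOp):
        lf = compile_expr(node.left)
        rf = compile_expr(node.right)
        op = node.op
        if op == "and":
            return lambda ctx: lf(ctx) and rf(ctx)
        if op == "or":
            return lambda ctx: lf(ctx) or rf(ctx)
        if op == "<":
            return lambda ctx: lf(ctx) < rf(ctx)
        if op == "<=":
            return lambda ctx: lf(ctx) <= rf(ctx)
        if op == ">":
            return lambda ctx: lf(ctx) > rf(ctx)
        if op == ">=":
            return lambda ctx: lf(ctx) >= rf(ctx)
        if op == "==":
            return lambda ctx: lf(ctx) == rf(ctx)
        if op == "!=":
            return lambda ctx: lf(ctx) != rf(ctx)
        if op == "+":
            return lambda ctx: lf(ctx) + rf(ctx)
        if op == "-":
            return lambda ctx: lf(ctx) - rf(ctx)
        if op == "*":
            return lambda ctx: lf(ctx) * rf(ctx)
        if op == "/":
            return lambda ctx: lf(ctx) / rf(ctx)
    raise TypeError(f"unknown node {node!r}")  # pragma: no cover
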