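"""Expression trees for kinetic-law mathematics.

Expressions are immutable trees (:class:`MathExpr`) that can be built from
infix text (:func:`parse_infix`) or content MathML (:func:`parse_mathml`),
evaluated against a name->value context (:func:`evaluate`), serialized back
to MathML (:func:`to_mathml`), and translated to Python source for the
compiled fast path (:func:`to_python`).
"""

from __future__ import annotations

import math
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

__all__ = [
    "MathExpr",
    "MathParseError",
    "const",
    "name",
    "unary",
    "binary",
    "call",
    "piecewise",
    "parse_infix",
    "parse_mathml",
    "to_mathml",
    "to_infix",
    "evaluate",
    "to_python",
    "free_names",
    "substitute",
]

MATHML_NS = "http://www.w3.org/1998/Math/MathML"
TIME_CSYMBOL = "http://www.sbml.org/sbml/symbols/time"
AVOGADRO_CSYMBOL = "http://www.sbml.org/sbml/symbols/avogadro"

#: reserved identifier bound to the current simulation time
TIME_NAME = "time"

UNARY_OPS = ("neg", "not")
ARITH_OPS = ("+", "-", "*", "/", "^")
REL_OPS = ("==", "!=", "<", ">", "<=", ">=")
BOOL_OPS = ("and", "or", "xor")

BUILTIN_FUNCS = {
    "exp", "ln", "log", "log10", "pow", "sqrt", "abs", "floor", "ceil",
    "min", "max", "sin", "cos", "tan", "asin", "acos", "atan",
    "sinh", "cosh", "tanh", "root",
}


class MathParseError(ValueError):
    """Raised when infix text or MathML cannot be parsed."""


@dataclass(frozen=True)
class MathExpr:
    """A node in an expression tree.

    ``kind`` is one of ``const``, ``name``, ``unary``, ``binary``, ``call``
    or ``piecewise``.  Relational and boolean operators are ``binary`` nodes
    whose ``op`` is drawn from the relational/boolean operator sets.
    """

    kind: str
    op: str = ""
    value: float = 0.0
    args: tuple["MathExpr", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind == "name" and not self.op:
            raise ValueError("identifier node requires a non-empty name")

    @property
    def name(self) -> str:
        return self.op


def const(v: float) -> MathExpr:
    return MathExpr("const", value=float(v))


def name(n: str) -> MathExpr:
    return MathExpr("name", op=n)


def unary(op: str, a: MathExpr) -> MathExpr:
    if op not in UNARY_OPS:
        raise ValueError(f"unknown unary operator {op!r}")
    return MathExpr("unary", op=op, args=(a,))


def binary(op: str, a: MathExpr, b: MathExpr) -> MathExpr:
    if op not in ARITH_OPS + REL_OPS + BOOL_OPS:
        raise ValueError(f"unknown binary operator {op!r}")
    return MathExpr("binary", op=op, args=(a, b))


def call(fn: str, *args: MathExpr) -> MathExpr:
    return MathExpr("call", op=fn, args=tuple(args))


def piecewise(*args: MathExpr) -> MathExpr:
    """piecewise(v1, cond1, v2, cond2, ..., [otherwise])"""
    return MathExpr("piecewise", args=tuple(args))


# ---------------------------------------------------------------------------
# infix parser

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+\.\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?"
    r"|\d+(?:[eE][+-]?\d+)?)"
    r"|(?P<id>[A-Za-z_][A-Za-z0-9_.]*)"
    r"|(?P<op><=|>=|==|!=|\|\||&&|[-+*/^()<>,!]))"
)


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            rest = text[pos:].strip()
            if not rest:
                break
            raise MathParseError(f"unexpected character {rest[0]!r} in {text!r}")
        tokens.append(m.group(0).strip())
        pos = m.end()
    return tokens


class _InfixParser:
    def __init__(self, text: str):
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise MathParseError("unexpected end of expression")
        self.pos += 1
        return tok

    def expect(self, tok: str) -> None:
        got = self.next()
        if got != tok:
            raise MathParseError(f"expected {tok!r}, got {got!r}")

    def parse(self) -> MathExpr:
        e = self.or_expr()
        if self.peek() is not None:
            raise MathParseError(f"trailing tokens starting at {self.peek()!r}")
        return e

    def or_expr(self) -> MathExpr:
        e = self.and_expr()
        while self.peek() in ("||", "or"):
            self.next()
            e = binary("or", e, self.and_expr())
        return e

    def and_expr(self) -> MathExpr:
        e = self.cmp_expr()
        while self.peek() in ("&&", "and"):
            self.next()
            e = binary("and", e, self.cmp_expr())
        return e

    def cmp_expr(self) -> MathExpr:
        e = self.add_expr()
        if self.peek() in REL_OPS:
            op = self.next()
            e = binary(op, e, self.add_expr())
        return e

    def add_expr(self) -> MathExpr:
        e = self.mul_expr()
        while self.peek() in ("+", "-"):
            op = self.next()
            e = binary(op, e, self.mul_expr())
        return e

    def mul_expr(self) -> MathExpr:
        e = self.unary_expr()
        while self.peek() in ("*", "/"):
            op = self.next()
            e = binary(op, e, self.unary_expr())
        return e

    def unary_expr(self) -> MathExpr:
        tok = self.peek()
        if tok == "-":
            self.next()
            return unary("neg", self.unary_expr())
        if tok == "+":
            self.next()
            return self.unary_expr()
        if tok in ("!", "not"):
            self.next()
            return unary("not", self.unary_expr())
        return self.pow_expr()

    def pow_expr(self) -> MathExpr:
        base = self.atom()
        if self.peek() == "^":
            self.next()
            return binary("^", base, self.unary_expr())
        return base

    def atom(self) -> MathExpr:
        tok = self.next()
        if tok == "(":
            e = self.or_expr()
            self.expect(")")
            return e
        if re.match(r"^[\d.]", tok):
            return const(float(tok))
        if re.match(r"^[A-Za-z_]", tok):
            if tok in ("true", "false"):
                return const(1.0 if tok == "true" else 0.0)
            if tok == "pi":
                return const(math.pi)
            if self.peek() == "(":
                self.next()
                args: list[MathExpr] = []
                if self.peek() != ")":
                    args.append(self.or_expr())
                    while self.peek() == ",":
                        self.next()
                        args.append(self.or_expr())
                self.expect(")")
                if tok == "piecewise":
                    return piecewise(*args)
                return call(tok, *args)
            return name(tok)
        raise MathParseError(f"unexpected token {tok!r}")


def parse_infix(text: str) -> MathExpr:
    """Parse readable infix rate-law text into a :class:`MathExpr`."""
    return _InfixParser(text).parse()


# ---------------------------------------------------------------------------
# MathML

_MATHML_BINOPS = {
    "plus": "+", "minus": "-", "times": "*", "divide": "/", "power": "^",
    "eq": "==", "neq": "!=", "lt": "<", "gt": ">", "leq": "<=", "geq": ">=",
    "and": "and", "or": "or", "xor": "xor",
}
_MATHML_FUNCS = {
    "exp", "ln", "log", "abs", "floor", "sin", "cos", "tan",
    "arcsin", "arccos", "arctan", "sinh", "cosh", "tanh", "root",
    "min", "max",
}
_ARC_MAP = {"arcsin": "asin", "arccos": "acos", "arctan": "atan"}
_ARC_MAP_INV = {v: k for k, v in _ARC_MAP.items()}


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _parse_mathml_elem(el: ET.Element) -> MathExpr:
    tag = _local(el.tag)
    if tag == "math":
        kids = list(el)
        if len(kids) != 1:
            raise MathParseError("<math> must contain exactly one child")
        return _parse_mathml_elem(kids[0])
    if tag == "cn":
        cn_type = el.get("type", "real")
        if cn_type == "e-notation":
            parts = [t.strip() for t in _cn_parts(el)]
            return const(float(parts[0]) * 10.0 ** float(parts[1]))
        if cn_type == "rational":
            parts = [t.strip() for t in _cn_parts(el)]
            return const(float(parts[0]) / float(parts[1]))
        return const(float((el.text or "").strip()))
    if tag == "ci":
        ident = (el.text or "").strip()
        if not ident:
            raise MathParseError("<ci> with empty identifier")
        return name(ident)
    if tag == "csymbol":
        url = el.get("definitionURL", "")
        if url == TIME_CSYMBOL:
            return name(TIME_NAME)
        if url == AVOGADRO_CSYMBOL:
            return const(6.02214179e23)
        raise MathParseError(f"unknown csymbol {url!r}")
    if tag == "true":
        return const(1.0)
    if tag == "false":
        return const(0.0)
    if tag == "pi":
        return const(math.pi)
    if tag == "exponentiale":
        return const(math.e)
    if tag == "infinity":
        return const(math.inf)
    if tag == "notanumber":
        return const(math.nan)
    if tag == "piecewise":
        args: list[MathExpr] = []
        otherwise: MathExpr | None = None
        for child in el:
            ctag = _local(child.tag)
            kids = list(child)
            if ctag == "piece":
                if len(kids) != 2:
                    raise MathParseError("<piece> needs value and condition")
                args.append(_parse_mathml_elem(kids[0]))
                args.append(_parse_mathml_elem(kids[1]))
            elif ctag == "otherwise":
                otherwise = _parse_mathml_elem(kids[0])
            else:
                raise MathParseError(f"unexpected element <{ctag}> in piecewise")
        if otherwise is not None:
            args.append(otherwise)
        return piecewise(*args)
    if tag == "apply":
        kids = list(el)
        if not kids:
            raise MathParseError("empty <apply>")
        head = kids[0]
        htag = _local(head.tag)
        logbase: MathExpr | None = None
        degree: MathExpr | None = None
        operands: list[MathExpr] = []
        for k in kids[1:]:
            ktag = _local(k.tag)
            if ktag == "logbase":
                logbase = _parse_mathml_elem(list(k)[0])
            elif ktag == "degree":
                degree = _parse_mathml_elem(list(k)[0])
            else:
                operands.append(_parse_mathml_elem(k))

        if htag == "ci":
            fn = (head.text or "").strip()
            return call(fn, *operands)
        if htag == "minus" and len(operands) == 1:
            return unary("neg", operands[0])
        if htag == "not":
            return unary("not", operands[0])
        if htag in _MATHML_BINOPS:
            op = _MATHML_BINOPS[htag]
            if not operands:
                raise MathParseError(f"<{htag}> with no operands")
            if len(operands) == 1:
                return operands[0]
            e = operands[0]
            for nxt in operands[1:]:
                e = binary(op, e, nxt)
            return e
        if htag == "log":
            if logbase is not None:
                return call("log", logbase, operands[0])
            return call("log", operands[0])
        if htag == "root":
            if degree is not None:
                return call("root", degree, operands[0])
            return call("sqrt", operands[0])
        if htag == "ceiling":
            return call("ceil", operands[0])
        if htag in _ARC_MAP:
            return call(_ARC_MAP[htag], operands[0])
        if htag in _MATHML_FUNCS:
            return call(htag, *operands)
        raise MathParseError(f"unknown MathML operator <{htag}>")
    raise MathParseError(f"unknown MathML element <{tag}>")


def _cn_parts(el: ET.Element) -> list[str]:
    # <cn>a<sep/>b</cn> — text is split around the <sep/> child
    parts = [el.text or ""]
    for child in el:
        parts.append(child.tail or "")
    return [p for p in parts if p.strip()]


def parse_mathml(source: str | ET.Element) -> MathExpr:
    """Parse a content-MathML fragment (string or element) into a tree."""
    if isinstance(source, str):
        try:
            el = ET.fromstring(source)
        except ET.ParseError as exc:
            raise MathParseError(f"malformed MathML: {exc}") from exc
    else:
        el = source
    return _parse_mathml_elem(el)


def _q(tag: str) -> str:
    return f"{{{MATHML_NS}}}{tag}"


_BINOP_TO_MATHML = {v: k for k, v in _MATHML_BINOPS.items() if v not in ("-",)}
_BINOP_TO_MATHML["-"] = "minus"


def _emit(e: MathExpr, parent: ET.Element) -> None:
    if e.kind == "const":
        v = e.value
        if v == math.pi:
            ET.SubElement(parent, _q("pi"))
            return
        cn = ET.SubElement(parent, _q("cn"))
        if math.isfinite(v) and v == int(v) and abs(v) < 1e15:
            cn.text = str(int(v))
            cn.set("type", "integer")
        else:
            cn.text = repr(v)
        return
    if e.kind == "name":
        if e.op == TIME_NAME:
            cs = ET.SubElement(parent, _q("csymbol"))
            cs.set("encoding", "text")
            cs.set("definitionURL", TIME_CSYMBOL)
            cs.text = "time"
            return
        ci = ET.SubElement(parent, _q("ci"))
        ci.text = f" {e.op} "
        return
    if e.kind == "unary":
        ap = ET.SubElement(parent, _q("apply"))
        ET.SubElement(ap, _q("minus" if e.op == "neg" else "not"))
        _emit(e.args[0], ap)
        return
    if e.kind == "binary":
        ap = ET.SubElement(parent, _q("apply"))
        ET.SubElement(ap, _q(_BINOP_TO_MATHML[e.op]))
        _emit(e.args[0], ap)
        _emit(e.args[1], ap)
        return
    if e.kind == "call":
        fn = e.op
        ap = ET.SubElement(parent, _q("apply"))
        if fn == "log" and len(e.args) == 2:
            ET.SubElement(ap, _q("log"))
            lb = ET.SubElement(ap, _q("logbase"))
            _emit(e.args[0], lb)
            _emit(e.args[1], ap)
            return
        if fn == "root" and len(e.args) == 2:
            ET.SubElement(ap, _q("root"))
            dg = ET.SubElement(ap, _q("degree"))
            _emit(e.args[0], dg)
            _emit(e.args[1], ap)
            return
        if fn == "pow":
            ET.SubElement(ap, _q("power"))
        elif fn == "sqrt":
            ET.SubElement(ap, _q("root"))
        elif fn == "ceil":
            ET.SubElement(ap, _q("ceiling"))
        elif fn == "log10":
            ET.SubElement(ap, _q("log"))
        elif fn in _ARC_MAP_INV:
            ET.SubElement(ap, _q(_ARC_MAP_INV[fn]))
        elif fn in _MATHML_FUNCS or fn == "exp":
            ET.SubElement(ap, _q(fn))
        else:
            ci = ET.SubElement(ap, _q("ci"))
            ci.text = f" {fn} "
        for a in e.args:
            _emit(a, ap)
        return
    if e.kind == "piecewise":
        pw = ET.SubElement(parent, _q("piecewise"))
        args = e.args
        npairs = len(args) // 2
        for i in range(npairs):
            piece = ET.SubElement(pw, _q("piece"))
            _emit(args[2 * i], piece)
            _emit(args[2 * i + 1], piece)
        if len(args) % 2 == 1:
            other = ET.SubElement(pw, _q("otherwise"))
            _emit(args[-1], other)
        return
    raise ValueError(f"cannot serialize node kind {e.kind!r}")


def to_mathml(e: MathExpr) -> ET.Element:
    """Serialize to a ``<math>`` element in the MathML namespace."""
    root = ET.Element(_q("math"))
    _emit(e, root)
    return root


def to_mathml_str(e: MathExpr) -> str:
    return ET.tostring(to_mathml(e), encoding="unicode")


# ---------------------------------------------------------------------------
# evaluation

def _as_bool(v: float) -> bool:
    return bool(v)


_FUNC_IMPL: dict[str, Callable[..., float]] = {
    "exp": math.exp,
    "ln": math.log,
    "log10": math.log10,
    "pow": lambda a, b: a ** b,
    "sqrt": math.sqrt,
    "abs": abs,
    "floor": math.floor,
    "ceil": math.ceil,
    "min": min,
    "max": max,
    "sin": math.sin, "cos": math.cos, "tan": math.tan,
    "asin": math.asin, "acos": math.acos, "atan": math.atan,
    "sinh": math.sinh, "cosh": math.cosh, "tanh": math.tanh,
}


def evaluate(
    e: MathExpr,
    ctx: Mapping[str, float],
    functions: Mapping[str, tuple[Sequence[str], MathExpr]] | None = None,
) -> float:
    """Evaluate a tree against ``ctx``; booleans are 1.0/0.0.

    ``functions`` maps user function ids to ``(argnames, body)``.
    """
    k = e.kind
    if k == "const":
        return e.value
    if k == "name":
        try:
            return float(ctx[e.op])
        except KeyError:
            raise KeyError(f"unbound identifier {e.op!r}") from None
    if k == "unary":
        v = evaluate(e.args[0], ctx, functions)
        return -v if e.op == "neg" else float(not _as_bool(v))
    if k == "binary":
        op = e.op
        if op == "and":
            return float(_as_bool(evaluate(e.args[0], ctx, functions))
                         and _as_bool(evaluate(e.args[1], ctx, functions)))
        if op == "or":
            return float(_as_bool(evaluate(e.args[0], ctx, functions))
                         or _as_bool(evaluate(e.args[1], ctx, functions)))
        a = evaluate(e.args[0], ctx, functions)
        b = evaluate(e.args[1], ctx, functions)
        if op == "+":
            return a + b
        if op == "-":
            return a - b
        if op == "*":
            return a * b
        if op == "/":
            return a / b
        if op == "^":
            return a ** b
        if op == "xor":
            return float(_as_bool(a) != _as_bool(b))
        if op == "==":
            return float(a == b)
        if op == "!=":
            return float(a != b)
        if op == "<":
            return float(a < b)
        if op == ">":
            return float(a > b)
        if op == "<=":
            return float(a <= b)
        if op == ">=":
            return float(a >= b)
        raise ValueError(f"unknown operator {op!r}")
    if k == "call":
        fn = e.op
        if fn == "log":
            if len(e.args) == 2:
                base = evaluate(e.args[0], ctx, functions)
                return math.log(evaluate(e.args[1], ctx, functions)) / math.log(base)
            return math.log10(evaluate(e.args[0], ctx, functions))
        if fn == "root":
            deg = evaluate(e.args[0], ctx, functions)
            return evaluate(e.args[1], ctx, functions) ** (1.0 / deg)
        if fn in _FUNC_IMPL:
            vals = [evaluate(a, ctx, functions) for a in e.args]
            return float(_FUNC_IMPL[fn](*vals))
        if functions and fn in functions:
            argnames, body = functions[fn]
            if len(argnames) != len(e.args):
                raise ValueError(
                    f"function {fn!r} expects {len(argnames)} args, got {len(e.args)}")
            inner = dict(ctx)
            for an, av in zip(argnames, e.args):
                inner[an] = evaluate(av, ctx, functions)
            return evaluate(body, inner, functions)
        raise ValueError(f"unknown function {fn!r}")
    if k == "piecewise":
        args = e.args
        npairs = len(args) // 2
        for i in range(npairs):
            if _as_bool(evaluate(args[2 * i + 1], ctx, functions)):
                return evaluate(args[2 * i], ctx, functions)
        if len(args) % 2 == 1:
            return evaluate(args[-1], ctx, functions)
        return math.nan
    raise ValueError(f"unknown node kind {k!r}")


def free_names(e: MathExpr) -> set[str]:
    """All identifiers referenced anywhere in the tree."""
    out: set[str] = set()

    def walk(node: MathExpr) -> None:
        if node.kind == "name":
            out.add(node.op)
        for a in node.args:
            walk(a)

    walk(e)
    return out


def substitute(e: MathExpr, mapping: Mapping[str, MathExpr]) -> MathExpr:
    """Replace identifier nodes by expressions (used to inline functions)."""
    if e.kind == "name":
        return mapping.get(e.op, e)
    if not e.args:
        return e
    new_args = tuple(substitute(a, mapping) for a in e.args)
    return MathExpr(e.kind, op=e.op, value=e.value, args=new_args)


def inline_calls(
    e: MathExpr,
    functions: Mapping[str, tuple[Sequence[str], MathExpr]],
) -> MathExpr:
    """Expand user-defined function calls by argument substitution."""
    if e.kind == "call" and e.op in functions:
        argnames, body = functions[e.op]
        if len(argnames) != len(e.args):
            raise ValueError(
                f"function {e.op!r} expects {len(argnames)} args, got {len(e.args)}")
        args = tuple(inline_calls(a, functions) for a in e.args)
        body = inline_calls(body, functions)
        return substitute(body, dict(zip(argnames, args)))
    if not e.args:
        return e
    return MathExpr(e.kind, op=e.op, value=e.value,
                    args=tuple(inline_calls(a, functions) for a in e.args))


# ---------------------------------------------------------------------------
# code generation (python expression source, numba-compatible)

_PY_FUNCS = {
    "exp": "math.exp", "ln": "math.log", "log10": "math.log10",
    "sqrt": "math.sqrt", "abs": "abs", "floor": "math.floor",
    "ceil": "math.ceil", "min": "min", "max": "max",
    "sin": "math.sin", "cos": "math.cos", "tan": "math.tan",
    "asin": "math.asin", "acos": "math.acos", "atan": "math.atan",
    "sinh": "math.sinh", "cosh": "math.cosh", "tanh": "math.tanh",
}

_PY_BINOP = {"+": "+", "-": "-", "*": "*", "/": "/",
             "==": "==", "!=": "!=", "<": "<", ">": ">", "<=": "<=", ">=": ">="}


def to_python(e: MathExpr, resolve: Callable[[str], str]) -> str:
    """Render the tree as a Python expression string.

    ``resolve`` maps an identifier to the code that yields its value
    (e.g. ``"y[3]"`` or ``"p[0]"``).  User function calls must already be
    inlined (see :func:`inline_calls`).
    """
    k = e.kind
    if k == "const":
        return repr(e.value)
    if k == "name":
        return resolve(e.op)
    if k == "unary":
        inner = to_python(e.args[0], resolve)
        return f"(-({inner}))" if e.op == "neg" else f"(not ({inner}))"
    if k == "binary":
        a = to_python(e.args[0], resolve)
        b = to_python(e.args[1], resolve)
        if e.op == "^":
            return f"(({a}) ** ({b}))"
        if e.op in ("and", "or"):
            return f"(({a}) {e.op} ({b}))"
        if e.op == "xor":
            return f"(bool({a}) != bool({b}))"
        return f"(({a}) {_PY_BINOP[e.op]} ({b}))"
    if k == "call":
        fn = e.op
        if fn == "log":
            if len(e.args) == 2:
                base = to_python(e.args[0], resolve)
                arg = to_python(e.args[1], resolve)
                return f"(math.log({arg}) / math.log({base}))"
            return f"math.log10({to_python(e.args[0], resolve)})"
        if fn == "pow":
            a = to_python(e.args[0], resolve)
            b = to_python(e.args[1], resolve)
            return f"(({a}) ** ({b}))"
        if fn == "root":
            deg = to_python(e.args[0], resolve)
            arg = to_python(e.args[1], resolve)
            return f"(({arg}) ** (1.0 / ({deg})))"
        if fn in _PY_FUNCS:
            args = ", ".join(to_python(a, resolve) for a in e.args)
            return f"{_PY_FUNCS[fn]}({args})"
        raise ValueError(f"cannot compile call to {fn!r} (not inlined?)")
    if k == "piecewise":
        args = e.args
        npairs = len(args) // 2
        out = to_python(args[-1], resolve) if len(args) % 2 == 1 else "math.nan"
        for i in reversed(range(npairs)):
            val = to_python(args[2 * i], resolve)
            cond = to_python(args[2 * i + 1], resolve)
            out = f"(({val}) if ({cond}) else ({out}))"
        return out
    raise ValueError(f"unknown node kind {k!r}")


# ---------------------------------------------------------------------------
# infix rendering (diagnostics)

def to_infix(e: MathExpr) -> str:
    k = e.kind
    if k == "const":
        return repr(e.value)
    if k == "name":
        return e.op
    if k == "unary":
        sym = "-" if e.op == "neg" else "!"
        return f"{sym}({to_infix(e.args[0])})"
    if k == "binary":
        op = {"and": "&&", "or": "||"}.get(e.op, e.op)
        return f"({to_infix(e.args[0])} {op} {to_infix(e.args[1])})"
    if k == "call":
        return f"{e.op}({', '.join(to_infix(a) for a in e.args)})"
    if k == "piecewise":
        return f"piecewise({', '.join(to_infix(a) for a in e.args)})"
    raise ValueError(k)
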