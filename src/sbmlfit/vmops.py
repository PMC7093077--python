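"""Stack-machine encoding of model mathematics.

The compiled ODE right-hand side is lowered to a flat opcode program so a
single jitted interpreter (see :mod:`sbmlfit.fastpath`) can evaluate any
model without per-model compilation.  Each instruction is an ``(op, arg)``
pair; operands live on a float stack, named intermediates (assignment
variables, reaction rates) in a scratch array, and state derivatives are
written to ``dy``.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .expr import MathExpr

# opcode numbers (mirrored in fastpath._vm_eval)
CONST = 0
LOAD_T = 1
LOAD_Y = 2
LOAD_P = 3
LOAD_S = 4
STORE_S = 5
ADD = 6
SUB = 7
MUL = 8
DIV = 9
POW = 10
NEG = 11
EXP = 12
LN = 13
LOG10 = 14
SQRT = 15
ABS = 16
FLOOR = 17
CEIL = 18
MIN = 19
MAX = 20
EQ = 21
NE = 22
LT = 23
GT = 24
LE = 25
GE = 26
AND = 27
OR = 28
NOT = 29
XOR = 30
SELECT = 31  # pop cond, value, accum -> push value if cond else accum
STORE_DY = 32
SIN = 33
COS = 34
TAN = 35
ASIN = 36
ACOS = 37
ATAN = 38
SINH = 39
COSH = 40
TANH = 41

_UNARY_CALLS = {
    "exp": EXP, "ln": LN, "log10": LOG10, "sqrt": SQRT, "abs": ABS,
    "floor": FLOOR, "ceil": CEIL, "sin": SIN, "cos": COS, "tan": TAN,
    "asin": ASIN, "acos": ACOS, "atan": ATAN, "sinh": SINH, "cosh": COSH,
    "tanh": TANH,
}
_BINARY_OPS = {
    "+": ADD, "-": SUB, "*": MUL, "/": DIV, "^": POW,
    "==": EQ, "!=": NE, "<": LT, ">": GT, "<=": LE, ">=": GE,
    "and": AND, "or": OR, "xor": XOR,
}


class VMLoweringError(ValueError):
    pass


class ProgramBuilder:
    """Accumulates instructions and the constant pool."""

    def __init__(self) -> None:
        self.ops: list[tuple[int, int]] = []
        self.consts: list[float] = []
        self._const_index: dict[float, int] = {}
        self._depth = 0
        self.max_depth = 0

    # -- low-level emission -------------------------------------------------
    def _push(self, n: int = 1) -> None:
        self._depth += n
        self.max_depth = max(self.max_depth, self._depth)

    def _pop(self, n: int = 1) -> None:
        self._depth -= n
        if self._depth < 0:
            raise VMLoweringError("stack underflow during lowering")

    def op(self, opcode: int, arg: int = 0) -> None:
        self.ops.append((opcode, arg))
        if opcode in (CONST, LOAD_T, LOAD_Y, LOAD_P, LOAD_S):
            self._push()
        elif opcode in (ADD, SUB, MUL, DIV, POW, MIN, MAX, EQ, NE, LT, GT,
                        LE, GE, AND, OR, XOR):
            self._pop(2)
            self._push()
        elif opcode == SELECT:
            self._pop(3)
            self._push()
        elif opcode in (STORE_S, STORE_DY):
            self._pop()
        # unary opcodes leave the depth unchanged

    def const(self, value: float) -> None:
        key = float(value)
        idx = self._const_index.get(key)
        if idx is None:
            idx = len(self.consts)
            self.consts.append(key)
            self._const_index[key] = idx
        self.op(CONST, idx)

    # -- expression lowering ------------------------------------------------
    def expr(self, e: MathExpr,
             resolve: Callable[[str, "ProgramBuilder"], None]) -> None:
        """Lower one expression; ``resolve`` emits the load sequence for an
        identifier."""
        k = e.kind
        if k == "const":
            self.const(e.value)
            return
        if k == "name":
            resolve(e.op, self)
            return
        if k == "unary":
            self.expr(e.args[0], resolve)
            self.op(NEG if e.op == "neg" else NOT)
            return
        if k == "binary":
            self.expr(e.args[0], resolve)
            self.expr(e.args[1], resolve)
            self.op(_BINARY_OPS[e.op])
            return
        if k == "call":
            fn = e.op
            if fn in _UNARY_CALLS and len(e.args) == 1:
                self.expr(e.args[0], resolve)
                self.op(_UNARY_CALLS[fn])
                return
            if fn in ("min", "max") and len(e.args) == 2:
                self.expr(e.args[0], resolve)
                self.expr(e.args[1], resolve)
                self.op(MIN if fn == "min" else MAX)
                return
            if fn == "pow" and len(e.args) == 2:
                self.expr(e.args[0], resolve)
                self.expr(e.args[1], resolve)
                self.op(POW)
                return
            if fn == "log":
                if len(e.args) == 1:
                    self.expr(e.args[0], resolve)
                    self.op(LOG10)
                    return
                # log_b(x) = ln(x) / ln(b)
                self.expr(e.args[1], resolve)
                self.op(LN)
                self.expr(e.args[0], resolve)
                self.op(LN)
                self.op(DIV)
                return
            if fn == "root" and len(e.args) == 2:
                self.expr(e.args[1], resolve)
                self.const(1.0)
                self.expr(e.args[0], resolve)
                self.op(DIV)
                self.op(POW)
                return
            raise VMLoweringError(f"cannot lower call to {fn!r}")
        if k == "piecewise":
            # evaluated eagerly: otherwise first, then SELECT per pair
            args = e.args
            npairs = len(args) // 2
            if len(args) % 2 == 1:
                self.expr(args[-1], resolve)
            else:
                self.const(float("nan"))
            for i in reversed(range(npairs)):
                self.expr(args[2 * i], resolve)
                self.expr(args[2 * i + 1], resolve)
                self.op(SELECT)
            return
        raise VMLoweringError(f"cannot lower node kind {k!r}")

    def finish(self) -> tuple[np.ndarray, np.ndarray, int]:
        code = np.asarray(self.ops, dtype=np.int64).reshape(-1, 2)
        consts = np.asarray(self.consts, dtype=np.float64)
        return code, consts, self.max_depth
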