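"""Jitted Rosenbrock integration of the stack-machine model encoding.

One numba-compiled interpreter/integrator pair serves every model (the
model itself is data: opcode + constant arrays), so the JIT cost is paid
once per process and cached on disk afterwards.  This path powers repeated
fitness evaluations during estimation; the interpreter path in
:mod:`sbmlfit.solvers` remains the reference implementation and handles
events, which the fast path does not support.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

from .compile import CompiledSystem, build_p, initial_state
from .quality import FAILURE_SENTINEL, QualitySpec, evaluate_quality
from .solvers import SolverSettings, Trajectory

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    NUMBA_AVAILABLE = True
except Exception:  # pragma: no cover
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(fn):
            return fn
        return deco if not (args and callable(args[0])) else args[0]


class FastPathUnavailable(RuntimeError):
    pass


# Rosenbrock 4(3), Kaps-Rentrop / Shampine set (mirrors solvers.py)
_GAM = 0.5
_A21 = 2.0
_A31, _A32 = 48.0 / 25.0, 6.0 / 25.0
_C21 = -8.0
_C31, _C32 = 372.0 / 25.0, 12.0 / 5.0
_C41, _C42, _C43 = -112.0 / 125.0, -54.0 / 125.0, -2.0 / 5.0
_B1, _B2, _B3, _B4 = 19.0 / 9.0, 0.5, 25.0 / 108.0, 125.0 / 108.0
_E1, _E2, _E3, _E4 = 17.0 / 54.0, 7.0 / 36.0, 0.0, 125.0 / 108.0
_C1X, _C2X, _C3X, _C4X = 0.5, -1.5, 121.0 / 50.0, 29.0 / 250.0
_A2X, _A3X = 1.0, 3.0 / 5.0


@njit(cache=True)
def _vm_eval(code, consts, t, y, p, scratch, stack, dy):
    """Run one opcode program; writes scratch and dy in place."""
    sp = 0
    for i in range(code.shape[0]):
        op = code[i, 0]
        arg = code[i, 1]
        if op == 0:  # CONST
            stack[sp] = consts[arg]
            sp += 1
        elif op == 1:  # LOAD_T
            stack[sp] = t
            sp += 1
        elif op == 2:  # LOAD_Y
            stack[sp] = y[arg]
            sp += 1
        elif op == 3:  # LOAD_P
            stack[sp] = p[arg]
            sp += 1
        elif op == 4:  # LOAD_S
            stack[sp] = scratch[arg]
            sp += 1
        elif op == 5:  # STORE_S
            sp -= 1
            scratch[arg] = stack[sp]
        elif op == 6:
            sp -= 1
            stack[sp - 1] = stack[sp - 1] + stack[sp]
        elif op == 7:
            sp -= 1
            stack[sp - 1] = stack[sp - 1] - stack[sp]
        elif op == 8:
            sp -= 1
            stack[sp - 1] = stack[sp - 1] * stack[sp]
        elif op == 9:
            sp -= 1
            stack[sp - 1] = stack[sp - 1] / stack[sp]
        elif op == 10:
            sp -= 1
            stack[sp - 1] = stack[sp - 1] ** stack[sp]
        elif op == 11:
            stack[sp - 1] = -stack[sp - 1]
        elif op == 12:
            stack[sp - 1] = math.exp(stack[sp - 1])
        elif op == 13:
            stack[sp - 1] = math.log(stack[sp - 1])
        elif op == 14:
            stack[sp - 1] = math.log10(stack[sp - 1])
        elif op == 15:
            stack[sp - 1] = math.sqrt(stack[sp - 1])
        elif op == 16:
            stack[sp - 1] = abs(stack[sp - 1])
        elif op == 17:
            stack[sp - 1] = math.floor(stack[sp - 1])
        elif op == 18:
            stack[sp - 1] = math.ceil(stack[sp - 1])
        elif op == 19:
            sp -= 1
            stack[sp - 1] = min(stack[sp - 1], stack[sp])
        elif op == 20:
            sp -= 1
            stack[sp - 1] = max(stack[sp - 1], stack[sp])
        elif op == 21:
            sp -= 1
            stack[sp - 1] = 1.0 if stack[sp - 1] == stack[sp] else 0.0
        elif op == 22:
            sp -= 1
            stack[sp - 1] = 1.0 if stack[sp - 1] != stack[sp] else 0.0
        elif op == 23:
            sp -= 1
            stack[sp - 1] = 1.0 if stack[sp - 1] < stack[sp] else 0.0
        elif op == 24:
            sp -= 1
            stack[sp - 1] = 1.0 if stack[sp - 1] > stack[sp] else 0.0
        elif op == 25:
            sp -= 1
            stack[sp - 1] = 1.0 if stack[sp - 1] <= stack[sp] else 0.0
        elif op == 26:
            sp -= 1
            stack[sp - 1] = 1.0 if stack[sp - 1] >= stack[sp] else 0.0
        elif op == 27:
            sp -= 1
            stack[sp - 1] = 1.0 if (stack[sp - 1] != 0.0 and stack[sp] != 0.0) else 0.0
        elif op == 28:
            sp -= 1
            stack[sp - 1] = 1.0 if (stack[sp - 1] != 0.0 or stack[sp] != 0.0) else 0.0
        elif op == 29:
            stack[sp - 1] = 0.0 if stack[sp - 1] != 0.0 else 1.0
        elif op == 30:
            sp -= 1
            stack[sp - 1] = 1.0 if ((stack[sp - 1] != 0.0) != (stack[sp] != 0.0)) else 0.0
        elif op == 31:  # SELECT
            sp -= 2
            if stack[sp + 1] != 0.0:
                stack[sp - 1] = stack[sp]
        elif op == 32:  # STORE_DY
            sp -= 1
            dy[arg] = stack[sp]
        elif op == 33:
            stack[sp - 1] = math.sin(stack[sp - 1])
        elif op == 34:
            stack[sp - 1] = math.cos(stack[sp - 1])
        elif op == 35:
            stack[sp - 1] = math.tan(stack[sp - 1])
        elif op == 36:
            stack[sp - 1] = math.asin(stack[sp - 1])
        elif op == 37:
            stack[sp - 1] = math.acos(stack[sp - 1])
        elif op == 38:
            stack[sp - 1] = math.atan(stack[sp - 1])
        elif op == 39:
            stack[sp - 1] = math.sinh(stack[sp - 1])
        elif op == 40:
            stack[sp - 1] = math.cosh(stack[sp - 1])
        elif op == 41:
            stack[sp - 1] = math.tanh(stack[sp - 1])


@njit(cache=True)
def _lu_factor_ip(A, piv):
    """In-place LU with partial pivoting; returns False if singular."""
    n = A.shape[0]
    for k in range(n):
        pk = k
        amax = abs(A[k, k])
        for i in range(k + 1, n):
            if abs(A[i, k]) > amax:
                amax = abs(A[i, k])
                pk = i
        if amax == 0.0 or not np.isfinite(amax):
            return False
        piv[k] = pk
        if pk != k:
            for j in range(n):
                tmp = A[k, j]
                A[k, j] = A[pk, j]
                A[pk, j] = tmp
        akk = A[k, k]
        for i in range(k + 1, n):
            A[i, k] /= akk
            lik = A[i, k]
            for j in range(k + 1, n):
                A[i, j] -= lik * A[k, j]
    return True


@njit(cache=True)
def _lu_solve_ip(A, piv, b):
    n = A.shape[0]
    for k in range(n):
        pk = piv[k]
        if pk != k:
            tmp = b[k]
            b[k] = b[pk]
            b[pk] = tmp
        for i in range(k + 1, n):
            b[i] -= A[i, k] * b[k]
    for i in range(n - 1, -1, -1):
        s = b[i]
        for j in range(i + 1, n):
            s -= A[i, j] * b[j]
        b[i] = s / A[i, i]


@njit(cache=True)
def _integrate_vm(code, consts, n_scratch, stack_size,
                  t0, t_end, y0, p, out_times,
                  atol, rtol, max_steps, h_init, time_dep):
    """Adaptive Rosenbrock 4(3) over the VM-encoded system.

    Returns (status, Y) with status 0 on success, 1 on failure; Y holds the
    state vector at each requested output time (cubic Hermite interpolation
    between accepted steps).
    """
    n = y0.shape[0]
    n_out = out_times.shape[0]
    Y = np.zeros((n_out, n))
    scratch = np.zeros(n_scratch + 1)
    stack = np.zeros(stack_size + 2)
    sqrt_eps = 1.4901161193847656e-08

    y = y0.copy()
    t = t0
    out_idx = 0
    if n_out > 0 and out_times[0] <= t + 1e-15:
        for i in range(n):
            Y[0, i] = y[i]
        out_idx = 1

    f_t = np.zeros(n)
    _vm_eval(code, consts, t, y, p, scratch, stack, f_t)
    for i in range(n):
        if not np.isfinite(f_t[i]):
            return 1, Y

    # initial step heuristic
    if h_init > 0.0:
        h = h_init
    else:
        d0 = 0.0
        d1 = 0.0
        for i in range(n):
            sc = atol + rtol * abs(y[i])
            d0 += (y[i] / sc) ** 2
            d1 += (f_t[i] / sc) ** 2
        d0 = math.sqrt(d0 / n)
        d1 = math.sqrt(d1 / n)
        if d0 < 1e-5 or d1 < 1e-5:
            h = 1e-6
        else:
            h = 0.01 * d0 / d1
        if h > (t_end - t0) / 10.0:
            h = (t_end - t0) / 10.0

    h_min = 1e-14 * (t_end - t0)
    jac = np.zeros((n, n))
    A = np.zeros((n, n))
    piv = np.zeros(n, dtype=np.int64)
    ftmp = np.zeros(n)
    dfdt = np.zeros(n)
    g1 = np.zeros(n)
    g2 = np.zeros(n)
    g3 = np.zeros(n)
    g4 = np.zeros(n)
    y_new = np.zeros(n)
    f_new = np.zeros(n)

    n_steps = 0
    while t < t_end - 1e-12 * (t_end - t0):
        if n_steps >= max_steps:
            return 1, Y
        if h > t_end - t:
            h = t_end - t
        if h < h_min:
            return 1, Y
        n_steps += 1

        # finite-difference Jacobian
        for j in range(n):
            step = sqrt_eps * abs(y[j])
            if step < sqrt_eps:
                step = sqrt_eps
            tmp = y[j]
            y[j] = tmp + step
            _vm_eval(code, consts, t, y, p, scratch, stack, ftmp)
            y[j] = tmp
            for i in range(n):
                jac[i, j] = (ftmp[i] - f_t[i]) / step
        if time_dep:
            tstep = sqrt_eps * abs(t)
            if tstep < sqrt_eps:
                tstep = sqrt_eps
            _vm_eval(code, consts, t + tstep, y, p, scratch, stack, ftmp)
            for i in range(n):
                dfdt[i] = (ftmp[i] - f_t[i]) / tstep

        inv_gh = 1.0 / (_GAM * h)
        for i in range(n):
            for j in range(n):
                A[i, j] = -jac[i, j]
            A[i, i] += inv_gh
        if not _lu_factor_ip(A, piv):
            h *= 0.5
            continue

        for i in range(n):
            g1[i] = f_t[i] + h * _C1X * dfdt[i]
        _lu_solve_ip(A, piv, g1)

        for i in range(n):
            y_new[i] = y[i] + _A21 * g1[i]
        _vm_eval(code, consts, t + _A2X * h, y_new, p, scratch, stack, ftmp)
        for i in range(n):
            g2[i] = ftmp[i] + h * _C2X * dfdt[i] + _C21 * g1[i] / h
        _lu_solve_ip(A, piv, g2)

        for i in range(n):
            y_new[i] = y[i] + _A31 * g1[i] + _A32 * g2[i]
        _vm_eval(code, consts, t + _A3X * h, y_new, p, scratch, stack, ftmp)
        for i in range(n):
            g3[i] = ftmp[i] + h * _C3X * dfdt[i] \
                + (_C31 * g1[i] + _C32 * g2[i]) / h
        _lu_solve_ip(A, piv, g3)

        for i in range(n):
            g4[i] = ftmp[i] + h * _C4X * dfdt[i] \
                + (_C41 * g1[i] + _C42 * g2[i] + _C43 * g3[i]) / h
        _lu_solve_ip(A, piv, g4)

        finite = True
        err_norm = 0.0
        for i in range(n):
            y_new[i] = y[i] + _B1 * g1[i] + _B2 * g2[i] \
                + _B3 * g3[i] + _B4 * g4[i]
            if not np.isfinite(y_new[i]):
                finite = False
                break
            e = _E1 * g1[i] + _E2 * g2[i] + _E3 * g3[i] + _E4 * g4[i]
            ymax = abs(y[i])
            if abs(y_new[i]) > ymax:
                ymax = abs(y_new[i])
            sc = atol + rtol * ymax
            err_norm += (e / sc) ** 2
        if not finite:
            h *= 0.5
            continue
        err_norm = math.sqrt(err_norm / n)

        if err_norm == 0.0:
            factor = 5.0
        else:
            factor = 0.9 * err_norm ** (-0.25)
            if factor > 5.0:
                factor = 5.0
            elif factor < 0.2:
                factor = 0.2
        if err_norm > 1.0:
            h *= factor
            continue

        t_new = t + h
        _vm_eval(code, consts, t_new, y_new, p, scratch, stack, f_new)
        fn_finite = True
        for i in range(n):
            if not np.isfinite(f_new[i]):
                fn_finite = False
        if not fn_finite:
            return 1, Y

        while out_idx < n_out and out_times[out_idx] <= t_new + 1e-15:
            to = out_times[out_idx]
            s = (to - t) / h
            h00 = (1 + 2 * s) * (1 - s) ** 2
            h10 = s * (1 - s) ** 2
            h01 = s * s * (3 - 2 * s)
            h11 = s * s * (s - 1)
            for i in range(n):
                Y[out_idx, i] = h00 * y[i] + h10 * h * f_t[i] \
                    + h01 * y_new[i] + h11 * h * f_new[i]
            out_idx += 1

        t = t_new
        for i in range(n):
            y[i] = y_new[i]
            f_t[i] = f_new[i]
        h *= factor

    while out_idx < n_out:
        for i in range(n):
            Y[out_idx, i] = y[i]
        out_idx += 1
    return 0, Y


def integrate_states(
    sys: CompiledSystem,
    settings: SolverSettings,
    p: np.ndarray,
    y0: np.ndarray,
) -> tuple[int, np.ndarray]:
    """Jitted integration returning the raw state matrix on the output
    grid.  Raises :class:`FastPathUnavailable` if the model cannot use the
    fast path (events, failed lowering, numba missing, non-Rosenbrock)."""
    if not NUMBA_AVAILABLE:
        raise FastPathUnavailable("numba is not importable")
    if sys.vm_code is None:
        raise FastPathUnavailable("model could not be lowered")
    if sys.events:
        raise FastPathUnavailable("events require the interpreter path")
    if settings.method != "rosenbrock":
        raise FastPathUnavailable("fast path implements rosenbrock only")
    settings.validate()
    grid = settings.grid()
    status, Y = _integrate_vm(
        sys.vm_code, sys.vm_consts, sys.vm_n_scratch, sys.vm_stack_size,
        float(settings.t_start), float(settings.t_end),
        np.asarray(y0, dtype=float), np.asarray(p, dtype=float),
        grid, float(settings.abs_tol), float(settings.rel_tol),
        int(settings.max_steps),
        float(settings.initial_step or 0.0), bool(sys.time_dependent))
    return int(status), Y


class FastFitness:
    """Precompiled fitness evaluator used by the estimation loop."""

    def __init__(self, sys: CompiledSystem, settings: SolverSettings,
                 data, mapping, quality: QualitySpec, param_ids: list[str]):
        if not NUMBA_AVAILABLE:
            raise FastPathUnavailable("numba is not importable")
        if sys.vm_code is None or sys.events:
            raise FastPathUnavailable("model not fast-path capable")
        if settings.method != "rosenbrock":
            raise FastPathUnavailable("fast path implements rosenbrock only")
        self.sys = sys
        self.settings = settings
        self.data = data
        self.mapping = mapping
        self.quality = quality
        self.grid = settings.grid()
        # trajectory columns limited to mapped targets; each must be a state
        self.targets = sorted(set(mapping.pairs.values()))
        self.target_cols: list[tuple[int, int]] = []  # (state idx, comp p-idx)
        for target in self.targets:
            sidx = sys._state_index.get(target)
            if sidx is None:
                raise FastPathUnavailable(
                    f"mapped quantity {target!r} is not a state variable")
            comp_pidx = -1
            try:
                sp = sys.doc.get_species(target)
                if not sp.has_only_substance_units:
                    comp_pidx = sys.param_index(sp.compartment)
            except KeyError:
                pass
            self.target_cols.append((sidx, comp_pidx))

        # Precompiled relative-squared-error plan: the output grid contains
        # every data time, so simulated values are picked by row index and
        # the RSE denominators depend only on the data.
        self._rse_plan = None
        if quality.kind == "relative_squared_error":
            plan = []
            ok = True
            from .quality import EPSILON_DENOMINATOR
            target_pos = {t: k for k, t in enumerate(self.targets)}
            for col, target in mapping.pairs.items():
                d = np.asarray(data.columns[col], dtype=float)
                keep = ~np.isnan(d)
                if not np.any(keep):
                    continue
                t_data = data.times[keep]
                rows = np.searchsorted(self.grid, t_data)
                if np.any(rows >= len(self.grid)) or \
                        not np.allclose(self.grid[rows], t_data, atol=1e-12):
                    ok = False
                    break
                dk = d[keep]
                nonzero = np.abs(dk) > EPSILON_DENOMINATOR
                if np.any(nonzero):
                    fallback = float(np.mean(np.abs(dk[nonzero])))
                    denom = np.where(nonzero, np.abs(dk), fallback)
                else:
                    denom = np.ones_like(dk)
                plan.append((target_pos[target], rows, dk, denom))
            if ok:
                self._rse_plan = plan
        # warm the jit so the first fitness call is not special
        p0 = np.full(len(sys.param_ids), 1.0)
        y00 = np.zeros(sys.n_state)
        warm = SolverSettings(
            method="rosenbrock", t_start=0.0, t_end=1e-6, output_step=1e-6,
            abs_tol=settings.abs_tol, rel_tol=settings.rel_tol, max_steps=50)
        try:
            integrate_states(sys, warm, p0, y00)
        except FastPathUnavailable:
            raise
        except Exception:
            pass

    def __call__(self, overrides: Mapping[str, float]) -> float:
        sys = self.sys
        try:
            p = build_p(sys, overrides)
            y0 = initial_state(sys, overrides)
        except Exception:
            return FAILURE_SENTINEL
        status, Y = integrate_states(sys, self.settings, p, y0)
        if status != 0:
            return FAILURE_SENTINEL
        if self._rse_plan is not None:
            total = 0.0
            for k, rows, dk, denom in self._rse_plan:
                sidx, comp_pidx = self.target_cols[k]
                sim = Y[rows, sidx]
                if comp_pidx >= 0:
                    sim = sim / p[comp_pidx]
                total += float(np.sum(((sim - dk) / denom) ** 2))
            return total
        vals = np.empty((len(self.grid), len(self.targets)))
        for k, (sidx, comp_pidx) in enumerate(self.target_cols):
            col = Y[:, sidx]
            if comp_pidx >= 0:
                col = col / p[comp_pidx]
            vals[:, k] = col
        traj = Trajectory(times=self.grid, values=vals,
                          column_ids=list(self.targets))
        return evaluate_quality(self.quality, traj, self.data, self.mapping)
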