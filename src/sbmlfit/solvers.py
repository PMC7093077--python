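"""Adaptive-step ODE integration.

Two methods share one adaptive loop:

* ``rosenbrock`` — a 4-stage linearly-implicit Rosenbrock method of order
  4 with an embedded order-3 error estimate (Kaps–Rentrop scheme with
  Shampine's parameter set).  The stage systems solve ``(I/(γh) − J)``
  with a finite-difference Jacobian, making the method suitable for stiff
  systems: the stability function is bounded (|R| ≤ 1) along the whole
  negative real axis with strong damping at infinity.
* ``rk45`` — the explicit Dormand–Prince 5(4) embedded Runge–Kutta pair.

Output values are produced on the requested grid by cubic Hermite
interpolation between accepted internal steps.  Integration failures
(step-size underflow, non-finite states, step budget exhausted) are
reported in the trajectory status instead of raising, so estimation can
penalize them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import scipy.linalg

from .compile import (
    CompiledSystem,
    build_p,
    initial_state,
    locate_and_fire_events,
    trigger_values,
)

__all__ = [
    "ConfigurationError",
    "SolverSettings",
    "Trajectory",
    "integrate",
    "rosenbrock_step",
    "rk45_step",
    "numerical_jacobian",
    "step_controller",
]

_SQRT_EPS = math.sqrt(np.finfo(float).eps)

# controller bounds
_FAC_MIN = 0.2
_FAC_MAX = 5.0
_SAFETY = 0.9
_H_UNDERFLOW_REL = 1e-14


class ConfigurationError(ValueError):
    pass


@dataclass
class SolverSettings:
    """Integration settings; tolerances default to the stiff-study values."""

    method: str = "rosenbrock"
    abs_tol: float = 1e-12
    rel_tol: float = 1e-6
    t_start: float = 0.0
    t_end: float = 1.0
    output_step: float = 0.1
    initial_step: float | None = None
    max_steps: int = 100_000
    output_times: np.ndarray | None = None

    def validate(self) -> None:
        if self.method not in ("rosenbrock", "rk45"):
            raise ConfigurationError(f"unknown method {self.method!r}")
        if self.abs_tol <= 0 or self.rel_tol <= 0:
            raise ConfigurationError("tolerances must be positive")
        if self.t_end <= self.t_start:
            raise ConfigurationError("t_end must exceed t_start")
        if self.output_times is None and self.output_step <= 0:
            raise ConfigurationError("outputStep must be positive")
        if self.max_steps < 1:
            raise ConfigurationError("maxSteps must be at least 1")

    def grid(self) -> np.ndarray:
        if self.output_times is not None:
            t = np.asarray(self.output_times, dtype=float)
            if t.ndim != 1 or len(t) == 0 or np.any(np.diff(t) <= 0):
                raise ConfigurationError("output_times must be strictly increasing")
            if t[0] < self.t_start - 1e-12 or t[-1] > self.t_end + 1e-12:
                raise ConfigurationError("output_times outside [t_start, t_end]")
            return t
        n = int(math.floor((self.t_end - self.t_start) / self.output_step + 1e-9))
        t = self.t_start + self.output_step * np.arange(n + 1)
        if t[-1] < self.t_end - 1e-9 * self.output_step:
            t = np.append(t, self.t_end)
        t[-1] = min(t[-1], self.t_end)
        return t


@dataclass
class Trajectory:
    times: np.ndarray
    values: np.ndarray  # (len(times), n_columns)
    column_ids: list[str]
    status: str = "success"  # "success" | "failure"
    failure_reason: str = ""
    t_fail: float = math.nan
    stats: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "success"

    def column(self, cid: str) -> np.ndarray:
        try:
            return self.values[:, self.column_ids.index(cid)]
        except ValueError:
            raise KeyError(f"no trajectory column {cid!r}") from None


# ---------------------------------------------------------------------------
# Rosenbrock 4(3): Kaps–Rentrop scheme, Shampine parameter set

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

ROSENBROCK_ORDER = 4
RK45_ORDER = 5


def _rosenbrock_core(
    f: Callable[[float, np.ndarray], np.ndarray],
    t: float,
    y: np.ndarray,
    h: float,
    jac: np.ndarray,
    dfdt: np.ndarray,
    f0: np.ndarray,
) -> tuple[np.ndarray | None, np.ndarray | None]:
    n = len(y)
    A = np.eye(n) / (_GAM * h) - jac
    try:
        lu, piv = scipy.linalg.lu_factor(A)
    except (scipy.linalg.LinAlgError, ValueError):
        return None, None
    if not np.all(np.isfinite(lu)):
        return None, None
    solve = lambda b: scipy.linalg.lu_solve((lu, piv), b)

    g1 = solve(f0 + h * _C1X * dfdt)
    f2 = f(t + _A2X * h, y + _A21 * g1)
    g2 = solve(f2 + h * _C2X * dfdt + _C21 * g1 / h)
    y3 = y + _A31 * g1 + _A32 * g2
    f3 = f(t + _A3X * h, y3)
    g3 = solve(f3 + h * _C3X * dfdt + (_C31 * g1 + _C32 * g2) / h)
    f4 = f(t + _A3X * h, y3)
    g4 = solve(f4 + h * _C4X * dfdt + (_C41 * g1 + _C42 * g2 + _C43 * g3) / h)

    y_new = y + _B1 * g1 + _B2 * g2 + _B3 * g3 + _B4 * g4
    err = _E1 * g1 + _E2 * g2 + _E3 * g3 + _E4 * g4
    return y_new, err


def rosenbrock_step(
    sys_or_f,
    t: float,
    y: np.ndarray,
    h: float,
    jac: np.ndarray | None = None,
    p: np.ndarray | None = None,
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """One Rosenbrock step; returns ``(y_new, error_estimate)``.

    ``sys_or_f`` is a :class:`CompiledSystem` or a callable ``f(t, y)``.
    A singular stage matrix yields ``(None, None)`` — the caller is
    expected to reject the step and halve ``h``.
    """
    if h <= 0:
        raise ConfigurationError("step size must be positive")
    f = _as_rhs(sys_or_f, p)
    y = np.asarray(y, dtype=float)
    f0 = f(t, y)
    if jac is None:
        jac = numerical_jacobian(sys_or_f, t, y, p)
    dfdt = _numerical_dfdt(f, t, y, f0)
    return _rosenbrock_core(f, t, y, h, jac, dfdt, f0)


# ---------------------------------------------------------------------------
# Dormand–Prince 5(4)

_DP_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_DP_A = [
    [],
    [1 / 5],
    [3 / 40, 9 / 40],
    [44 / 45, -56 / 15, 32 / 9],
    [19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729],
    [9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656],
    [35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84],
]
_DP_B5 = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0.0])
_DP_B4 = np.array([5179 / 57600, 0.0, 7571 / 16695, 393 / 640,
                   -92097 / 339200, 187 / 2100, 1 / 40])


def rk45_step(
    sys_or_f,
    t: float,
    y: np.ndarray,
    h: float,
    p: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One Dormand–Prince 5(4) step; returns ``(y_new, error_estimate)``."""
    if h <= 0:
        raise ConfigurationError("step size must be positive")
    f = _as_rhs(sys_or_f, p)
    y = np.asarray(y, dtype=float)
    k = [f(t, y)]
    for i in range(1, 7):
        yi = y + h * sum(a * ki for a, ki in zip(_DP_A[i], k))
        k.append(f(t + _DP_C[i] * h, yi))
    y_new = y + h * sum(b * ki for b, ki in zip(_DP_B5, k))
    err = h * sum((b5 - b4) * ki for b5, b4, ki in zip(_DP_B5, _DP_B4, k))
    return y_new, err


# ---------------------------------------------------------------------------

def numerical_jacobian(
    sys_or_f,
    t: float,
    y: np.ndarray,
    p: np.ndarray | None = None,
) -> np.ndarray:
    """Forward-difference Jacobian with per-component step
    ``max(sqrt(eps)·|y_i|, sqrt(eps))``."""
    f = _as_rhs(sys_or_f, p)
    y = np.asarray(y, dtype=float)
    f0 = f(t, y)
    n = len(y)
    J = np.empty((n, n))
    for i in range(n):
        step = max(_SQRT_EPS * abs(y[i]), _SQRT_EPS)
        yp = y.copy()
        yp[i] += step
        J[:, i] = (f(t, yp) - f0) / step
    return J


def _numerical_dfdt(f, t: float, y: np.ndarray, f0: np.ndarray) -> np.ndarray:
    step = max(_SQRT_EPS * abs(t), _SQRT_EPS)
    return (f(t + step, y) - f0) / step


def step_controller(error_norm: float, h: float, order: int) -> tuple[float, bool]:
    """Classic I-controller: accept iff ``error_norm <= 1``;
    ``h_next = h * clamp(0.9 * error_norm^(-1/order), 0.2, 5.0)``."""
    if error_norm < 0:
        raise ConfigurationError("error norm must be non-negative")
    accept = error_norm <= 1.0
    if error_norm == 0.0:
        factor = _FAC_MAX
    else:
        factor = _SAFETY * error_norm ** (-1.0 / order)
        factor = min(_FAC_MAX, max(_FAC_MIN, factor))
    return h * factor, accept


def _error_norm(err: np.ndarray, y0: np.ndarray, y1: np.ndarray,
                abs_tol: float, rel_tol: float) -> float:
    scale = abs_tol + rel_tol * np.maximum(np.abs(y0), np.abs(y1))
    return float(np.sqrt(np.mean((err / scale) ** 2)))


def _hermite(t0, y0, f0, t1, y1, f1, t):
    h = t1 - t0
    s = (t - t0) / h
    h00 = (1 + 2 * s) * (1 - s) ** 2
    h10 = s * (1 - s) ** 2
    h01 = s * s * (3 - 2 * s)
    h11 = s * s * (s - 1)
    return h00 * y0 + h10 * h * f0 + h01 * y1 + h11 * h * f1


def _as_rhs(sys_or_f, p: np.ndarray | None):
    if isinstance(sys_or_f, CompiledSystem):
        pp = build_p(sys_or_f) if p is None else p
        rhs = sys_or_f.rhs
        return lambda t, y: rhs(t, y, pp)
    return sys_or_f


def _initial_step(f, t0, y0, t_end, abs_tol, rel_tol, order) -> float:
    # standard h0 heuristic from the norms of y and f
    f0 = f(t0, y0)
    scale = abs_tol + rel_tol * np.abs(y0)
    d0 = np.sqrt(np.mean((y0 / scale) ** 2))
    d1 = np.sqrt(np.mean((f0 / scale) ** 2))
    h0 = 1e-6 if (d0 < 1e-5 or d1 < 1e-5) else 0.01 * d0 / d1
    return min(h0, (t_end - t0) / 10.0)


def integrate(
    sys: CompiledSystem,
    settings: SolverSettings,
    overrides: Mapping[str, float] | None = None,
) -> Trajectory:
    """Integrate a compiled system, producing reported quantities on the
    output grid.

    Events are located with :func:`locate_and_fire_events`; integration
    restarts from the post-event state.  Failures (non-finite states,
    step underflow, budget exhaustion) are returned as a trajectory with
    ``status="failure"`` truncated at the last completed output row.
    """
    settings.validate()
    grid = settings.grid()
    p = build_p(sys, overrides)
    y = initial_state(sys, overrides)

    use_rosenbrock = settings.method == "rosenbrock"
    order = ROSENBROCK_ORDER if use_rosenbrock else RK45_ORDER
    rhs = sys.rhs
    f = lambda t, yy: rhs(t, yy, p)

    t = settings.t_start
    n_cols = len(sys.report_ids)
    out = np.empty((len(grid), n_cols))
    out_idx = 0
    if grid[0] <= t + 1e-15:
        out[0] = sys.report_fn(t, y, p)
        out_idx = 1

    trig_state = trigger_values(sys, t, y, p) if sys.events else []
    # events whose trigger is true at t0 but initialValue=false fire at start
    if sys.events:
        initial_assumed = [ev.initial_trigger_value for ev in sys.events]
        res = locate_and_fire_events(sys, t, y, t, y.copy(), p, initial_assumed)
        if res is not None:
            _, y = res
            if out_idx == 1:
                out[0] = sys.report_fn(t, y, p)
        trig_state = trigger_values(sys, t, y, p)

    h = settings.initial_step or _initial_step(
        f, t, y, settings.t_end, settings.abs_tol, settings.rel_tol, order)
    h_min = _H_UNDERFLOW_REL * (settings.t_end - settings.t_start)

    n_steps = n_accept = n_reject = 0
    f_t = f(t, y)

    def fail(reason: str) -> Trajectory:
        return Trajectory(
            times=grid[:out_idx].copy(),
            values=out[:out_idx].copy(),
            column_ids=list(sys.report_ids),
            status="failure",
            failure_reason=reason,
            t_fail=t,
            stats={"n_steps": n_steps, "n_accepted": n_accept,
                   "n_rejected": n_reject},
        )

    while t < settings.t_end - 1e-12 * (settings.t_end - settings.t_start):
        if n_steps >= settings.max_steps:
            return fail(f"maximum step count {settings.max_steps} exceeded")
        h = min(h, settings.t_end - t)
        if h < h_min:
            return fail("step size underflow")
        n_steps += 1

        if use_rosenbrock:
            jac = numerical_jacobian(sys, t, y, p)
            dfdt = (_numerical_dfdt(f, t, y, f_t) if sys.time_dependent
                    else np.zeros(len(y)))
            y_new, err = _rosenbrock_core(f, t, y, h, jac, dfdt, f_t)
            if y_new is None:
                h *= 0.5
                n_reject += 1
                continue
        else:
            y_new, err = rk45_step(f, t, y, h)

        if not np.all(np.isfinite(y_new)):
            h *= 0.5
            n_reject += 1
            if h < h_min:
                return fail("non-finite state")
            continue

        err_norm = _error_norm(err, y, y_new, settings.abs_tol, settings.rel_tol)
        h_next, accept = step_controller(err_norm, h, order)
        if not accept:
            n_reject += 1
            h = h_next
            continue

        t_new = t + h
        f_new = f(t_new, y_new)

        event_hit = None
        if sys.events:
            event_hit = locate_and_fire_events(
                sys, t, y, t_new, y_new.copy(), p, trig_state)
        if event_hit is not None:
            t_star, y_star = event_hit
            while out_idx < len(grid) and grid[out_idx] <= t_star + 1e-15:
                yo = _hermite(t, y, f_t, t_new, y_new, f_new, grid[out_idx])
                out[out_idx] = sys.report_fn(grid[out_idx], yo, p)
                out_idx += 1
            t, y = t_star, y_star
            f_t = f(t, y)
            trig_state = trigger_values(sys, t, y, p)
            h = h_next
            n_accept += 1
            continue

        while out_idx < len(grid) and grid[out_idx] <= t_new + 1e-15:
            yo = _hermite(t, y, f_t, t_new, y_new, f_new, grid[out_idx])
            out[out_idx] = sys.report_fn(grid[out_idx], yo, p)
            out_idx += 1

        t, y, f_t = t_new, y_new, f_new
        if sys.events:
            trig_state = trigger_values(sys, t, y, p)
        h = h_next
        n_accept += 1

    while out_idx < len(grid):  # numerical shortfall at the right endpoint
        out[out_idx] = sys.report_fn(grid[out_idx], y, p)
        out_idx += 1

    return Trajectory(
        times=grid.copy(),
        values=out,
        column_ids=list(sys.report_ids),
        status="success",
        stats={"n_steps": n_steps, "n_accepted": n_accept,
               "n_rejected": n_reject},
    )
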