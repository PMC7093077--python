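"""Nature-inspired optimizers minimizing a quality function over a box.

All algorithms consume a *problem* — either a full
:class:`~sbmlfit.dataio.EstimationProblem` (model + data + mapping) or a
plain :class:`BoxProblem` wrapping an objective callable for benchmarks —
plus an :class:`OptimizerConfig`, and return an :class:`EstimationResult`
whose best-so-far trace is monotone non-increasing and fully reproducible
from the seed.
"""

from __future__ import annotations

import sys as _sys
import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .compile import compile_system
from .dataio import ColumnMapping, EstimationProblem, ParameterSpec
from .quality import FAILURE_SENTINEL, evaluate_quality
from .solvers import ConfigurationError, integrate

__all__ = [
    "BoxProblem",
    "OptimizerConfig",
    "EstimationResult",
    "fitness_of",
    "differential_evolution",
    "evolution_strategy",
    "particle_swarm",
    "hill_climbing",
    "simulated_annealing",
    "estimate",
    "ALGORITHMS",
]


@dataclass
class BoxProblem:
    """A bare objective over a parameter box (used for benchmark functions)."""

    objective: Callable[[np.ndarray], float]
    parameters: list[ParameterSpec]


@dataclass
class OptimizerConfig:
    algorithm: str = "de"
    population_size: int | None = None  # default: 10 * dimension, capped 100
    max_evaluations: int = 20_000
    seed: int = 0
    log_every: int = 0
    target_fitness: float | None = None  # optional early stop
    # DE
    de_f: float = 0.7
    de_cr: float = 0.9
    # ES
    es_mu: int = 5
    es_lambda: int = 35
    es_sigma0: float = 0.1  # fraction of box width
    # PSO
    pso_w: float = 0.729
    pso_c1: float = 1.49445
    pso_c2: float = 1.49445
    # HC / SA
    hc_sigma0: float = 0.1
    sa_t0: float = 1.0
    sa_alpha: float = 0.95  # applied every 100 evaluations


@dataclass
class EstimationResult:
    best_x: np.ndarray
    best_fitness: float
    trace: list[tuple[int, float]]  # (evaluation count, best-so-far)
    evaluations: int
    seed: int
    algorithm: str
    parameter_ids: list[str] = field(default_factory=list)
    wall_time: float = 0.0

    @property
    def best(self) -> dict[str, float]:
        return dict(zip(self.parameter_ids, map(float, self.best_x)))


# ---------------------------------------------------------------------------
# fitness

class _CompiledProblem:
    """Caches the compiled system and solver grid for repeated evaluations."""

    def __init__(self, problem: EstimationProblem):
        self.problem = problem
        self.system = compile_system(problem.model)
        self.param_ids = [s.id for s in problem.parameters]
        settings = problem.solver
        # evaluate the simulation exactly on the data grid (plus t_start)
        data_times = problem.data.times
        grid = np.unique(np.concatenate(
            [[settings.t_start], np.asarray(data_times, dtype=float)]))
        grid = grid[(grid >= settings.t_start) & (grid <= settings.t_end)]
        self.settings = type(settings)(
            method=settings.method,
            abs_tol=settings.abs_tol,
            rel_tol=settings.rel_tol,
            t_start=settings.t_start,
            t_end=settings.t_end,
            output_step=settings.output_step,
            initial_step=settings.initial_step,
            max_steps=settings.max_steps,
            output_times=grid,
        )
        self._fast = None
        self._fast_failed = False

    def _get_fast(self):
        if self._fast is None and not self._fast_failed:
            try:
                from .fastpath import FastFitness
                self._fast = FastFitness(
                    self.system, self.settings, self.problem.data,
                    self.problem.mapping, self.problem.quality,
                    self.param_ids)
            except Exception:
                self._fast_failed = True
        return self._fast

    def fitness(self, x: Sequence[float]) -> float:
        fast = self._get_fast()
        overrides = dict(zip(self.param_ids, map(float, x)))
        if fast is not None:
            return fast(overrides)
        traj = integrate(self.system, self.settings, overrides)
        return evaluate_quality(self.problem.quality, traj,
                                self.problem.data, self.problem.mapping)


def _compiled(problem) -> _CompiledProblem:
    cp = getattr(problem, "_compiled_cache", None)
    if cp is None:
        cp = _CompiledProblem(problem)
        problem._compiled_cache = cp
    return cp


def fitness_of(problem, x: Sequence[float]) -> float:
    """Objective value at ``x`` (order follows the problem's parameter
    list); integration failure maps to the finite 1e300 sentinel."""
    x = np.asarray(x, dtype=float)
    if isinstance(problem, BoxProblem):
        v = float(problem.objective(x))
        return FAILURE_SENTINEL if not np.isfinite(v) else v
    cp = _compiled(problem)  # setup errors (bad mapping etc.) propagate
    try:
        v = cp.fitness(x)
    except Exception:
        return FAILURE_SENTINEL
    if not np.isfinite(v):
        return FAILURE_SENTINEL
    return float(v)


# ---------------------------------------------------------------------------
# shared optimizer plumbing

def _boxes(problem) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    specs = problem.parameters
    lo = np.array([s.min for s in specs], dtype=float)
    hi = np.array([s.max for s in specs], dtype=float)
    ilo = np.array([s.init_min for s in specs], dtype=float)
    ihi = np.array([s.init_max for s in specs], dtype=float)
    return lo, hi, ilo, ihi, [s.id for s in specs]


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Reflect out-of-box components back into [lo, hi]."""
    x = x.copy()
    for _ in range(50):
        below = x < lo
        above = x > hi
        if not (below.any() or above.any()):
            return x
        x[below] = 2 * lo[below] - x[below]
        x[above] = 2 * hi[above] - x[above]
    return np.clip(x, lo, hi)


class _Recorder:
    def __init__(self, objective, max_evaluations: int, log_every: int,
                 target_fitness: float | None = None):
        self.objective = objective
        self.max_evaluations = max_evaluations
        self.log_every = log_every
        self.target_fitness = target_fitness
        self.evals = 0
        self.best_f = np.inf
        self.best_x: np.ndarray | None = None
        self.trace: list[tuple[int, float]] = []

    @property
    def exhausted(self) -> bool:
        if self.target_fitness is not None \
                and self.best_f <= self.target_fitness:
            return True
        return self.evals >= self.max_evaluations

    def __call__(self, x: np.ndarray) -> float:
        f = self.objective(x)
        self.evals += 1
        if f < self.best_f or self.best_x is None:
            self.best_f = f
            self.best_x = x.copy()
            self.trace.append((self.evals, self.best_f))
        if self.log_every and self.evals % self.log_every == 0:
            print(f"evals={self.evals} best={self.best_f}", file=_sys.stderr)
        return f

    def result(self, algorithm: str, seed: int, param_ids: list[str],
               t0: float) -> EstimationResult:
        if not self.trace or self.trace[-1][0] != self.evals:
            self.trace.append((self.evals, self.best_f))
        return EstimationResult(
            best_x=self.best_x,
            best_fitness=self.best_f,
            trace=self.trace,
            evaluations=self.evals,
            seed=seed,
            algorithm=algorithm,
            parameter_ids=param_ids,
            wall_time=time.perf_counter() - t0,
        )


def _setup(problem, config: OptimizerConfig):
    lo, hi, ilo, ihi, ids = _boxes(problem)
    rec = _Recorder(lambda x: fitness_of(problem, x),
                    config.max_evaluations, config.log_every,
                    config.target_fitness)
    rng = np.random.Generator(np.random.PCG64(config.seed))
    return lo, hi, ilo, ihi, ids, rec, rng


def _pop_size(config: OptimizerConfig, dim: int) -> int:
    if config.population_size is not None:
        return config.population_size
    return min(100, 10 * dim)


# ---------------------------------------------------------------------------
# algorithms

def differential_evolution(problem, config: OptimizerConfig) -> EstimationResult:
    """DE/rand/1/bin with reflection box repair and greedy selection."""
    t0 = time.perf_counter()
    lo, hi, ilo, ihi, ids, rec, rng = _setup(problem, config)
    dim = len(lo)
    np_ = _pop_size(config, dim)
    if np_ < 4:
        raise ConfigurationError("differential evolution needs a population "
                                 "of at least 4")
    if config.max_evaluations < np_:
        raise ConfigurationError("maxEvaluations must cover at least one "
                                 "population")
    F, CR = config.de_f, config.de_cr

    pop = rng.uniform(ilo, ihi, size=(np_, dim))
    fit = np.array([rec(ind) for ind in pop])

    while not rec.exhausted:
        for i in range(np_):
            if rec.exhausted:
                break
            a = int(rng.integers(np_))
            while a == i:
                a = int(rng.integers(np_))
            b = int(rng.integers(np_))
            while b == i or b == a:
                b = int(rng.integers(np_))
            c = int(rng.integers(np_))
            while c == i or c == a or c == b:
                c = int(rng.integers(np_))
            v = pop[a] + F * (pop[b] - pop[c])
            v = _reflect(v, lo, hi)
            cross = rng.random(dim) < CR
            cross[rng.integers(dim)] = True  # forced index
            trial = np.where(cross, v, pop[i])
            f_trial = rec(trial)
            if f_trial <= fit[i]:
                pop[i] = trial
                fit[i] = f_trial
    return rec.result("de", config.seed, ids, t0)


def evolution_strategy(problem, config: OptimizerConfig) -> EstimationResult:
    """(μ, λ)-ES with global log-normal step-size self-adaptation
    (τ = 1/sqrt(2n)) and clipping box repair."""
    t0 = time.perf_counter()
    lo, hi, ilo, ihi, ids, rec, rng = _setup(problem, config)
    dim = len(lo)
    mu, lam = config.es_mu, config.es_lambda
    if lam < mu:
        raise ConfigurationError("evolution strategy requires lambda >= mu")
    tau = 1.0 / np.sqrt(2.0 * dim)
    width = hi - lo

    parents = rng.uniform(ilo, ihi, size=(mu, dim))
    sigmas = np.full(mu, config.es_sigma0)
    for ind in parents:
        if rec.exhausted:
            break
        rec(ind)

    while not rec.exhausted:
        offspring = np.empty((lam, dim))
        off_sigma = np.empty(lam)
        off_fit = np.full(lam, np.inf)
        n_done = 0
        for k in range(lam):
            if rec.exhausted:
                break
            j = rng.integers(mu)
            s = sigmas[j] * np.exp(tau * rng.standard_normal())
            x = parents[j] + s * width * rng.standard_normal(dim)
            x = np.clip(x, lo, hi)
            offspring[k] = x
            off_sigma[k] = s
            off_fit[k] = rec(x)
            n_done = k + 1
        if n_done == 0:
            break
        order = np.argsort(off_fit[:n_done], kind="stable")[:mu]
        if len(order) < mu:
            order = np.concatenate([order] * mu)[:mu]
        parents = offspring[order]
        sigmas = np.maximum(off_sigma[order], 1e-12)
    return rec.result("es", config.seed, ids, t0)


def particle_swarm(problem, config: OptimizerConfig) -> EstimationResult:
    """Inertia-weight PSO; velocities clamped to 20% of box width,
    positions clipped to the box."""
    t0 = time.perf_counter()
    lo, hi, ilo, ihi, ids, rec, rng = _setup(problem, config)
    dim = len(lo)
    n = _pop_size(config, dim)
    w, c1, c2 = config.pso_w, config.pso_c1, config.pso_c2
    width = hi - lo
    v_max = 0.2 * width

    x = rng.uniform(ilo, ihi, size=(n, dim))
    v = rng.uniform(-v_max, v_max, size=(n, dim))
    p_best = x.copy()
    p_fit = np.array([rec(xi) for xi in x[:min(n, config.max_evaluations)]])
    if len(p_fit) < n:
        p_fit = np.concatenate([p_fit, np.full(n - len(p_fit), np.inf)])
    g = int(np.argmin(p_fit))

    while not rec.exhausted:
        for i in range(n):
            if rec.exhausted:
                break
            r1 = rng.random(dim)
            r2 = rng.random(dim)
            v[i] = (w * v[i]
                    + c1 * r1 * (p_best[i] - x[i])
                    + c2 * r2 * (p_best[g] - x[i]))
            v[i] = np.clip(v[i], -v_max, v_max)
            x[i] = np.clip(x[i] + v[i], lo, hi)
            f = rec(x[i])
            if f < p_fit[i]:
                p_fit[i] = f
                p_best[i] = x[i].copy()
                if f < p_fit[g]:
                    g = i
    return rec.result("pso", config.seed, ids, t0)


def hill_climbing(problem, config: OptimizerConfig) -> EstimationResult:
    """(1+1) Gaussian climber with 1/5-success step-size adaptation."""
    t0 = time.perf_counter()
    lo, hi, ilo, ihi, ids, rec, rng = _setup(problem, config)
    dim = len(lo)
    width = hi - lo
    sigma = config.hc_sigma0

    x = rng.uniform(ilo, ihi)
    fx = rec(x)
    while not rec.exhausted:
        cand = np.clip(x + sigma * width * rng.standard_normal(dim), lo, hi)
        fc = rec(cand)
        if fc <= fx:
            x, fx = cand, fc
            sigma *= np.exp(0.2)
        else:
            sigma *= np.exp(-0.05)
        sigma = min(max(sigma, 1e-12), 1.0)
    return rec.result("hill_climbing", config.seed, ids, t0)


def simulated_annealing(problem, config: OptimizerConfig) -> EstimationResult:
    """Metropolis acceptance exp(−Δ/T) with a geometric schedule
    ``T_k = T0 · α^(evals // 100)`` and the hill-climbing proposal."""
    t0 = time.perf_counter()
    lo, hi, ilo, ihi, ids, rec, rng = _setup(problem, config)
    dim = len(lo)
    width = hi - lo
    sigma = config.hc_sigma0

    x = rng.uniform(ilo, ihi)
    fx = rec(x)
    while not rec.exhausted:
        T = config.sa_t0 * config.sa_alpha ** (rec.evals // 100)
        cand = np.clip(x + sigma * width * rng.standard_normal(dim), lo, hi)
        fc = rec(cand)
        delta = fc - fx
        if delta <= 0 or (T > 0 and rng.random() < np.exp(-min(delta / T, 700))):
            x, fx = cand, fc
    return rec.result("simulated_annealing", config.seed, ids, t0)


ALGORITHMS = {
    "de": differential_evolution,
    "es": evolution_strategy,
    "pso": particle_swarm,
    "hill_climbing": hill_climbing,
    "simulated_annealing": simulated_annealing,
}


def estimate(problem, config: OptimizerConfig) -> EstimationResult:
    """Dispatch to the configured algorithm."""
    try:
        algo = ALGORITHMS[config.algorithm]
    except KeyError:
        raise ConfigurationError(
            f"unknown algorithm {config.algorithm!r}; choose from "
            f"{sorted(ALGORITHMS)}") from None
    return algo(problem, config)
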