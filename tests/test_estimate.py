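from __future__ import annotations

import numpy as np
import pytest

from sbmlfit.dataio import ColumnMapping, DataSet, EstimationProblem, ParameterSpec
from sbmlfit.estimate import (
    ALGORITHMS,
    BoxProblem,
    OptimizerConfig,
    differential_evolution,
    estimate,
    evolution_strategy,
    fitness_of,
    hill_climbing,
    particle_swarm,
    simulated_annealing,
)
from sbmlfit.quality import FAILURE_SENTINEL, QualitySpec
from sbmlfit.solvers import ConfigurationError, SolverSettings

from conftest import make_decay_model


def sphere_problem(dim: int = 5, lo: float = -5.0, hi: float = 5.0,
                   record: list | None = None) -> BoxProblem:
    def objective(x):
        if record is not None:
            record.append(x.copy())
        return float(np.sum(x * x))
    return BoxProblem(objective, [
        ParameterSpec(f"x{i}", lo, hi, lo, hi) for i in range(dim)])


def corner_quadratic() -> BoxProblem:
    # optimum at the box corner x = 1 (unconstrained optimum outside box)
    return BoxProblem(lambda x: float((x[0] - 3.0) ** 2),
                      [ParameterSpec("x", -1.0, 1.0, -1.0, 1.0)])


def double_well() -> BoxProblem:
    # global minimum near x = -1, shallower local minimum near x = +1;
    # initialization box sits inside the wrong basin
    return BoxProblem(
        lambda x: float((x[0] ** 2 - 1.0) ** 2 + 0.3 * x[0]),
        [ParameterSpec("x", 0.8, 1.2, -2.0, 2.0)])


class TestFitnessOf:
    def test_true_parameters_fit_noise_free_data(self, study_fixture):
        problem = study_fixture.problem()
        x = [study_fixture.truth[s.id] for s in study_fixture.parameters]
        assert fitness_of(problem, x) < 1e-6

    def test_blowup_maps_to_sentinel(self):
        model = make_decay_model()
        data = DataSet(times=np.array([0.5, 1.0]),
                       columns={"A": np.array([0.6, 0.37])})
        problem = EstimationProblem(
            model=model, data=data, mapping=ColumnMapping({"A": "A"}),
            parameters=[ParameterSpec("k", -5000.0, 1.0, -5000.0, 1.0)],
            quality=QualitySpec(), solver=SolverSettings(
                t_start=0.0, t_end=1.0, output_step=0.01, max_steps=2000))
        assert fitness_of(problem, [-5000.0]) == FAILURE_SENTINEL
        assert fitness_of(problem, [1.0]) < 1.0

    def test_deterministic(self, study_fixture):
        problem = study_fixture.problem()
        x = np.array([s.max * 0.5 for s in study_fixture.parameters])
        assert fitness_of(problem, x) == fitness_of(problem, x)


class TestDifferentialEvolution:
    def test_sphere_benchmark(self):
        hits = 0
        for seed in range(10):
            res = differential_evolution(sphere_problem(), OptimizerConfig(
                algorithm="de", population_size=40, max_evaluations=20_000,
                seed=seed))
            if res.best_fitness < 1e-6:
                hits += 1
        assert hits >= 9

    def test_corner_optimum_reflection(self):
        res = differential_evolution(corner_quadratic(), OptimizerConfig(
            population_size=10, max_evaluations=2_000, seed=1))
        assert res.best_x[0] == pytest.approx(1.0, abs=1e-6)

    def test_seed_determinism_bitwise(self):
        cfg = OptimizerConfig(population_size=12, max_evaluations=600, seed=7)
        r1 = differential_evolution(sphere_problem(), cfg)
        r2 = differential_evolution(sphere_problem(), cfg)
        assert r1.trace == r2.trace
        np.testing.assert_array_equal(r1.best_x, r2.best_x)
        assert r1.best_fitness == r2.best_fitness

    def test_population_too_small(self):
        with pytest.raises(ConfigurationError):
            differential_evolution(sphere_problem(), OptimizerConfig(
                population_size=3, max_evaluations=100))

    def test_init_box_vs_search_box_semantics(self):
        record: list[np.ndarray] = []

        def objective(x):
            record.append(x.copy())
            return float((x[0] - 2.0) ** 2)

        problem = BoxProblem(
            objective,
            [ParameterSpec("x", 0.5, 0.5, -5.0, 5.0)])  # initMin == initMax
        pop = 8
        differential_evolution(problem, OptimizerConfig(
            population_size=pop, max_evaluations=200, seed=3))
        gen0 = record[:pop]
        assert all(x[0] == 0.5 for x in gen0)

        # Gaussian-mutation optimizers leave the degenerate init point while
        # still respecting the search box
        record.clear()
        hill_climbing(problem, OptimizerConfig(max_evaluations=50, seed=3))
        assert record[0][0] == 0.5
        assert any(x[0] != 0.5 for x in record[1:])
        assert all(-5.0 <= x[0] <= 5.0 for x in record)


class TestEvolutionStrategy:
    def test_sphere_benchmark(self):
        hits = 0
        for seed in range(10):
            res = evolution_strategy(sphere_problem(), OptimizerConfig(
                algorithm="es", max_evaluations=20_000, seed=seed))
            if res.best_fitness < 1e-4:
                hits += 1
        assert hits >= 9

    def test_one_plus_one_degenerate(self):
        cfg = OptimizerConfig(es_mu=1, es_lambda=1, max_evaluations=200,
                              seed=0)
        res = evolution_strategy(sphere_problem(dim=2), cfg)
        assert res.evaluations == 200
        assert np.all(np.isfinite(res.best_x))

    def test_lambda_less_than_mu(self):
        with pytest.raises(ConfigurationError):
            evolution_strategy(sphere_problem(), OptimizerConfig(
                es_mu=10, es_lambda=5, max_evaluations=100))

    def test_seed_determinism(self):
        cfg = OptimizerConfig(max_evaluations=500, seed=11)
        r1 = evolution_strategy(sphere_problem(), cfg)
        r2 = evolution_strategy(sphere_problem(), cfg)
        assert r1.trace == r2.trace


class TestParticleSwarm:
    def test_sphere_benchmark(self):
        hits = 0
        for seed in range(10):
            res = particle_swarm(sphere_problem(), OptimizerConfig(
                algorithm="pso", population_size=30,
                max_evaluations=20_000, seed=seed))
            if res.best_fitness < 1e-4:
                hits += 1
        assert hits >= 9

    def test_single_particle_no_crash(self):
        res = particle_swarm(sphere_problem(dim=2), OptimizerConfig(
            population_size=1, max_evaluations=300, seed=2))
        assert np.isfinite(res.best_fitness)

    def test_seed_determinism(self):
        cfg = OptimizerConfig(population_size=10, max_evaluations=500, seed=5)
        r1 = particle_swarm(sphere_problem(), cfg)
        r2 = particle_swarm(sphere_problem(), cfg)
        assert r1.trace == r2.trace


class TestHillClimbing:
    def test_quadratic_convergence(self):
        res = hill_climbing(corner_quadratic(), OptimizerConfig(
            max_evaluations=2_000, seed=4))
        assert res.best_x[0] == pytest.approx(1.0, abs=1e-3)

    def test_minimal_budget_returns_initial_point(self):
        res = hill_climbing(sphere_problem(), OptimizerConfig(
            max_evaluations=1, seed=0))
        assert res.evaluations == 1
        assert np.all(np.isfinite(res.best_x))

    def test_seed_determinism(self):
        cfg = OptimizerConfig(max_evaluations=400, seed=9)
        r1 = hill_climbing(sphere_problem(), cfg)
        r2 = hill_climbing(sphere_problem(), cfg)
        assert r1.trace == r2.trace


class TestSimulatedAnnealing:
    def test_escapes_wrong_basin_more_than_hill_climbing(self):
        n_seeds = 30
        budget = 3_000
        sa_hits = hc_hits = 0
        for seed in range(n_seeds):
            sa = simulated_annealing(double_well(), OptimizerConfig(
                max_evaluations=budget, seed=seed))
            hc = hill_climbing(double_well(), OptimizerConfig(
                max_evaluations=budget, seed=seed))
            if sa.best_x[0] < 0:
                sa_hits += 1
            if hc.best_x[0] < 0:
                hc_hits += 1
        assert sa_hits >= n_seeds // 2
        assert hc_hits <= n_seeds // 10

    def test_zero_temperature_limit_is_greedy(self):
        cfg = OptimizerConfig(max_evaluations=500, seed=1, sa_t0=1e-300)
        res = simulated_annealing(corner_quadratic(), cfg)
        assert res.best_x[0] == pytest.approx(1.0, abs=1e-2)

    def test_seed_determinism(self):
        cfg = OptimizerConfig(max_evaluations=400, seed=13)
        r1 = simulated_annealing(sphere_problem(), cfg)
        r2 = simulated_annealing(sphere_problem(), cfg)
        assert r1.trace == r2.trace


class TestEstimateDispatch:
    def test_dispatch_equals_direct_call(self):
        cfg = OptimizerConfig(algorithm="de", population_size=10,
                              max_evaluations=300, seed=2)
        assert estimate(sphere_problem(), cfg).trace == \
            differential_evolution(sphere_problem(), cfg).trace

    def test_unknown_algorithm(self):
        with pytest.raises(ConfigurationError, match="unknown algorithm"):
            estimate(sphere_problem(), OptimizerConfig(algorithm="cma"))

    def test_sentinel_only_landscape(self):
        problem = BoxProblem(lambda x: float("inf"),
                             [ParameterSpec("x", 0, 1, 0, 1)])
        res = estimate(problem, OptimizerConfig(
            algorithm="de", population_size=5, max_evaluations=100, seed=0))
        assert res.best_fitness == FAILURE_SENTINEL

    @pytest.mark.parametrize("algorithm", sorted(ALGORITHMS))
    def test_trace_monotone_and_box_respected(self, algorithm):
        cfg = OptimizerConfig(algorithm=algorithm, population_size=8,
                              es_mu=3, es_lambda=9,
                              max_evaluations=400, seed=6)
        res = estimate(sphere_problem(dim=3), cfg)
        fits = [f for _, f in res.trace]
        assert all(b <= a for a, b in zip(fits, fits[1:]))
        assert res.best_fitness == fits[-1]
        assert np.all(res.best_x >= -5.0) and np.all(res.best_x <= 5.0)


class TestParameterRecovery:
    """Reduced-scale version of the headline recovery property; the
    acceptance suite runs the full repeated-fit study."""

    def test_single_run_recovers_within_5_percent(self, study_fixture):
        problem = study_fixture.problem()
        res = differential_evolution(problem, OptimizerConfig(
            algorithm="de", population_size=50, max_evaluations=15_000,
            seed=0))
        for pid in res.parameter_ids:
            ratio = res.best[pid] / study_fixture.truth[pid]
            assert abs(ratio - 1.0) < 0.05, (pid, ratio)
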