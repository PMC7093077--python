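from __future__ import annotations

import math

import numpy as np
import pytest

from sbmlfit.compile import build_p, compile_system, initial_state
from sbmlfit.expr import parse_infix
from sbmlfit.model import (
    Compartment,
    ModelDocument,
    Parameter,
    Reaction,
    Species,
    SpeciesRef,
)
from sbmlfit.solvers import (
    ConfigurationError,
    SolverSettings,
    integrate,
    numerical_jacobian,
    rk45_step,
    rosenbrock_step,
    step_controller,
)

from conftest import make_decay_model, make_linear_chain_model


def _stiff_model(k_fast: float = 1e5, k_slow: float = 1.0) -> ModelDocument:
    """Two independent first-order decays with a 10^5 rate separation."""
    doc = ModelDocument(model_id="stiff")
    doc.compartments.append(Compartment("c", 1.0))
    doc.species.append(Species("F", "c", initial_amount=1.0))
    doc.species.append(Species("S", "c", initial_amount=1.0))
    doc.parameters.append(Parameter("kf", value=k_fast))
    doc.parameters.append(Parameter("ks", value=k_slow))
    doc.reactions.append(Reaction(
        "rf", reactants=[SpeciesRef("F")],
        kinetic_law=parse_infix("kf * F"), reversible=False))
    doc.reactions.append(Reaction(
        "rs", reactants=[SpeciesRef("S")],
        kinetic_law=parse_infix("ks * S"), reversible=False))
    return doc


class TestIntegrateBasics:
    @pytest.mark.parametrize("method", ["rosenbrock", "rk45"])
    def test_exponential_decay(self, method):
        sys = compile_system(make_decay_model())
        settings = SolverSettings(method=method, abs_tol=1e-12, rel_tol=1e-6,
                                  t_start=0.0, t_end=1.0, output_step=0.1)
        traj = integrate(sys, settings)
        assert traj.ok
        assert traj.column("A")[-1] == pytest.approx(math.exp(-1),
                                                     abs=10 * 1e-6)

    @pytest.mark.parametrize("method", ["rosenbrock", "rk45"])
    def test_linear_chain_matrix_exponential_oracle(self, method):
        k1, k2, a0 = 1.3, 0.4, 2.0
        sys = compile_system(make_linear_chain_model(k1, k2, a0))
        settings = SolverSettings(method=method, abs_tol=1e-12, rel_tol=1e-8,
                                  t_start=0.0, t_end=5.0, output_step=0.5)
        traj = integrate(sys, settings)
        assert traj.ok
        import scipy.linalg
        A = np.array([[-k1, 0.0], [k1, -k2]])
        for i, t in enumerate(traj.times):
            exact = scipy.linalg.expm(A * t) @ np.array([a0, 0.0])
            assert traj.column("A")[i] == pytest.approx(exact[0], abs=1e-6)
            assert traj.column("B")[i] == pytest.approx(exact[1], abs=1e-6)

    def test_trajectory_grid(self):
        sys = compile_system(make_decay_model())
        traj = integrate(sys, SolverSettings(t_start=0.0, t_end=1.0,
                                             output_step=0.25))
        np.testing.assert_allclose(traj.times, [0, 0.25, 0.5, 0.75, 1.0])
        assert np.all(np.isfinite(traj.values))

    def test_invalid_settings(self):
        sys = compile_system(make_decay_model())
        with pytest.raises(ConfigurationError):
            integrate(sys, SolverSettings(t_start=1.0, t_end=0.0,
                                          output_step=0.1))
        with pytest.raises(ConfigurationError):
            integrate(sys, SolverSettings(abs_tol=-1.0))
        with pytest.raises(ConfigurationError):
            integrate(sys, SolverSettings(method="bdf"))

    def test_failure_is_status_not_exception(self):
        sys = compile_system(make_decay_model(k=1.0))
        settings = SolverSettings(method="rk45", t_start=0.0, t_end=1.0,
                                  output_step=0.1, max_steps=2)
        traj = integrate(sys, settings)
        assert not traj.ok
        assert "step count" in traj.failure_reason
        assert np.isfinite(traj.t_fail)


class TestStiffness:
    def test_rosenbrock_beats_rk45_on_stiff_system(self):
        sys = compile_system(_stiff_model())
        base = dict(abs_tol=1e-12, rel_tol=1e-6, t_start=0.0, t_end=10.0,
                    output_step=1.0, max_steps=10_000)
        ros = integrate(sys, SolverSettings(method="rosenbrock", **base))
        rk = integrate(sys, SolverSettings(method="rk45", **base))
        assert ros.ok
        assert ros.stats["n_steps"] < 10_000
        assert not rk.ok  # explicit method exhausts the step budget
        # rosenbrock solution is accurate for the slow component
        assert ros.column("S")[-1] == pytest.approx(math.exp(-10.0), rel=1e-4)

    def test_stability_at_negative_infinity(self):
        """|R(h*lambda)| <= 1 for h*lambda -> -inf (single step on y'=ly)."""
        lam = -1.0
        f = lambda t, y: lam * y
        for h in (1e2, 1e4, 1e8, 1e12):
            y_new, _ = rosenbrock_step(f, 0.0, np.array([1.0]), h,
                                       jac=np.array([[lam]]))
            assert abs(y_new[0]) <= 1.0 + 1e-9, f"unstable at h*lam={h*lam}"

    def test_strong_damping_at_infinity(self):
        lam = -1.0
        f = lambda t, y: lam * y
        y_new, _ = rosenbrock_step(f, 0.0, np.array([1.0]), 1e12,
                                   jac=np.array([[lam]]))
        assert abs(y_new[0]) < 0.5  # R(-inf) = 1/3 for this tableau


class TestRosenbrockStep:
    def test_convergence_order_at_least_3(self):
        """Global error on y'=-y over [0,1] scales as O(h^p), p >= 3."""
        f = lambda t, y: -y
        errors = []
        steps = [0.1, 0.05, 0.025]
        for h in steps:
            y = np.array([1.0])
            t = 0.0
            n = round(1.0 / h)
            for _ in range(n):
                y, _ = rosenbrock_step(f, t, y, h, jac=np.array([[-1.0]]))
                t += h
            errors.append(abs(y[0] - math.exp(-1.0)))
        rates = [math.log(errors[i] / errors[i + 1]) / math.log(2)
                 for i in range(len(errors) - 1)]
        assert min(rates) >= 3.0, rates

    def test_error_estimate_within_factor_10(self):
        # the embedded estimate measures the lower-order solution's local
        # error, so compare against the order-3 solution y_new - err
        f = lambda t, y: -y
        h = 0.05
        y_new, err = rosenbrock_step(f, 0.0, np.array([1.0]), h,
                                     jac=np.array([[-1.0]]))
        embedded = y_new[0] - err[0]
        true_local = abs(embedded - math.exp(-h))
        assert abs(err[0]) <= 10 * max(true_local, 1e-16)
        assert abs(err[0]) >= true_local / 10
        # and the order-4 solution is strictly more accurate than the bound
        assert abs(y_new[0] - math.exp(-h)) < abs(err[0])

    def test_invalid_step_size(self):
        with pytest.raises(ConfigurationError):
            rosenbrock_step(lambda t, y: -y, 0.0, np.array([1.0]), -0.1,
                            jac=np.array([[-1.0]]))


class TestJacobian:
    def test_linear_system(self):
        A = np.array([[-1.0, 0.5], [0.25, -2.0]])
        f = lambda t, y: A @ y
        J = numerical_jacobian(f, 0.0, np.array([1.0, 2.0]))
        np.testing.assert_allclose(J, A, atol=1e-6)

    def test_mm_hand_derivative(self, mm_model):
        sys = compile_system(mm_model)
        # at S = Km: d(dS/dt)/dS = -Vmax*Km/(Km+S)^2 = -Vmax/(4 Km)
        J = numerical_jacobian(sys, 0.0, np.array([1.0, 0.0]), build_p(sys))
        i = sys.state_ids.index("S")
        assert J[i, i] == pytest.approx(-100.0 / 4.0, rel=1e-5)

    def test_polynomial_vs_symbolic(self, rng):
        import sympy

        x0, x1 = sympy.symbols("x0 x1")
        exprs = [x0 ** 2 * x1 + 3 * x0, x1 ** 3 - x0 * x1]
        f_np = lambda t, y: np.array(
            [y[0] ** 2 * y[1] + 3 * y[0], y[1] ** 3 - y[0] * y[1]])
        J_sym = sympy.Matrix(exprs).jacobian([x0, x1])
        for _ in range(10):
            y = rng.uniform(0.5, 2.0, size=2)
            J_num = numerical_jacobian(f_np, 0.0, y)
            J_ref = np.array(J_sym.subs({x0: y[0], x1: y[1]}), dtype=float)
            np.testing.assert_allclose(J_num, J_ref, rtol=1e-5, atol=1e-6)


class TestStepController:
    def test_error_norm_one(self):
        h_next, accept = step_controller(1.0, 1.0, 4)
        assert accept
        assert h_next == pytest.approx(0.9)

    def test_error_norm_zero_clamped(self):
        h_next, accept = step_controller(0.0, 1.0, 4)
        assert accept
        assert h_next == 5.0

    def test_reject_above_one(self):
        h_next, accept = step_controller(16.0, 1.0, 4)
        assert not accept
        assert h_next < 1.0

    def test_clamps(self):
        h_next, _ = step_controller(1e12, 1.0, 4)
        assert h_next == pytest.approx(0.2)
        h_next, _ = step_controller(1e-12, 1.0, 4)
        assert h_next == pytest.approx(5.0)

    def test_deterministic_replay(self):
        seq = [(0.5, 0.1), (2.0, 0.09), (0.0, 0.01), (1.0, 0.05)]
        replay1 = [step_controller(e, h, 4) for e, h in seq]
        replay2 = [step_controller(e, h, 4) for e, h in seq]
        assert replay1 == replay2

    def test_negative_error_rejected(self):
        with pytest.raises(ConfigurationError):
            step_controller(-0.1, 1.0, 4)


class TestProperties:
    def test_tolerance_monotonicity(self):
        sys = compile_system(make_linear_chain_model())
        import scipy.linalg
        A = np.array([[-1.0, 0.0], [1.0, -2.0]])
        exact = scipy.linalg.expm(A * 3.0) @ np.array([1.0, 0.0])
        errs = []
        for rel in (1e-4, 1e-5, 1e-6, 1e-7):
            traj = integrate(sys, SolverSettings(
                method="rosenbrock", abs_tol=1e-12, rel_tol=rel,
                t_start=0.0, t_end=3.0, output_step=3.0))
            err = abs(traj.column("A")[-1] - exact[0]) \
                + abs(traj.column("B")[-1] - exact[1])
            errs.append(err)
        for a, b in zip(errs, errs[1:]):
            assert b <= a * 1.5 + 1e-14  # tightening never hurts materially

    @pytest.mark.parametrize("method", ["rosenbrock", "rk45"])
    def test_grid_invariance(self, method):
        sys = compile_system(make_linear_chain_model())
        rel = 1e-6
        t1 = integrate(sys, SolverSettings(
            method=method, rel_tol=rel, t_start=0.0, t_end=2.0,
            output_step=0.5))
        t2 = integrate(sys, SolverSettings(
            method=method, rel_tol=rel, t_start=0.0, t_end=2.0,
            output_step=0.25))
        shared = np.isin(t2.times, t1.times)
        np.testing.assert_allclose(
            t2.values[shared], t1.values, atol=10 * rel)

    def test_closed_network_conservation(self, chain_model_and_truth):
        doc, _ = chain_model_and_truth
        # knock out transport: keep only the conversion reactions
        import copy
        closed = copy.deepcopy(doc)
        closed.reactions = [r for r in closed.reactions
                            if r.id.startswith("Conv_")]
        closed.species[1].initial_amount = 50.0  # put mass inside the cell
        sys = compile_system(closed)
        abs_tol = 1e-12
        traj = integrate(sys, SolverSettings(
            method="rosenbrock", abs_tol=abs_tol, rel_tol=1e-6,
            t_start=0.0, t_end=120.0, output_step=10.0))
        assert traj.ok
        amounts = np.zeros(len(traj.times))
        for s in closed.species:
            conc = traj.column(s.id)
            size = next(c.size for c in closed.compartments
                        if c.id == s.compartment)
            amounts += conc * size
        drift = np.max(np.abs(amounts - amounts[0]))
        assert drift < 1e3 * abs_tol


class TestFastPathEquivalence:
    def test_fast_integration_matches_interpreter(self, chain_model_and_truth):
        pytest.importorskip("numba")
        from sbmlfit.fastpath import integrate_states

        doc, _ = chain_model_and_truth
        sys = compile_system(doc)
        times = np.geomspace(1.2, 120.0, 12)
        settings = SolverSettings(method="rosenbrock", abs_tol=1e-12,
                                  rel_tol=1e-6, t_start=0.0, t_end=120.0,
                                  output_times=times)
        status, Y = integrate_states(sys, settings, build_p(sys),
                                     initial_state(sys))
        assert status == 0
        traj = integrate(sys, settings)
        # report columns are concentrations; states are amounts
        for i, sid in enumerate(sys.state_ids):
            sp = doc.get_species(sid)
            size = next(c.size for c in doc.compartments
                        if c.id == sp.compartment)
            np.testing.assert_allclose(Y[:, i] / size, traj.column(sid),
                                       rtol=1e-6, atol=1e-9)
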