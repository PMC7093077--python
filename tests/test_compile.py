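from __future__ import annotations

import numpy as np
import pytest

from sbmlfit.compile import (
    CompileError,
    IntegrationStateError,
    build_p,
    compile_system,
    context_at,
    derivatives,
    initial_state,
    locate_and_fire_events,
)
from sbmlfit.expr import parse_infix
from sbmlfit.model import (
    Compartment,
    Event,
    EventAssignment,
    ModelDocument,
    Parameter,
    Reaction,
    Rule,
    Species,
    SpeciesRef,
)

from oracles import naive_derivatives


class TestCompile:
    def test_unit_stoichiometry(self, decay_model):
        decay_model.species.append(Species("B", "c", initial_amount=0.0))
        decay_model.reactions[0].products.append(SpeciesRef("B"))
        sys = compile_system(decay_model)
        assert sys.state_ids == ["A", "B"]
        np.testing.assert_array_equal(sys.stoichiometry, [[-1.0], [1.0]])

    def test_reversible_single_column(self):
        doc = ModelDocument()
        doc.compartments.append(Compartment("c", 1.0))
        doc.species.append(Species("A", "c", initial_amount=2.0))
        doc.species.append(Species("B", "c", initial_amount=0.0))
        doc.parameters.append(Parameter("kf", value=3.0))
        doc.parameters.append(Parameter("kr", value=1.0))
        doc.reactions.append(Reaction(
            "r", reactants=[SpeciesRef("A")], products=[SpeciesRef("B")],
            kinetic_law=parse_infix("kf * A - kr * B"), reversible=True))
        sys = compile_system(doc)
        assert sys.stoichiometry.shape == (2, 1)
        dy = derivatives(sys, 0.0, np.array([2.0, 1.0]))
        # net rate 3*2 - 1*1 = 5
        np.testing.assert_allclose(dy, [-5.0, 5.0])

    def test_boundary_species_excluded(self, decay_model):
        decay_model.species.append(
            Species("X", "c", initial_amount=1.0, boundary_condition=True))
        sys = compile_system(decay_model)
        assert "X" not in sys.state_ids
        assert "X" in sys.param_ids

    def test_closed_network_columns_sum_zero(self, chain_model_and_truth):
        doc, _ = chain_model_and_truth
        sys = compile_system(doc)
        # conversion and transport columns conserve total amount (1:1
        # transfers); only the terminal clearance removes mass
        for j, rid in enumerate(sys.reaction_ids):
            expected = -1.0 if rid.startswith("Clear_") else 0.0
            assert sys.stoichiometry[:, j].sum() == expected, rid

    def test_cyclic_assignment_rules_error(self):
        doc = ModelDocument()
        doc.parameters.append(Parameter("a", constant=False))
        doc.parameters.append(Parameter("b", constant=False))
        doc.rules.append(Rule("assignment", "a", parse_infix("b")))
        doc.rules.append(Rule("assignment", "b", parse_infix("a")))
        with pytest.raises(CompileError, match="cyclic|validation"):
            compile_system(doc)

    def test_local_parameter_shadowing(self):
        doc = ModelDocument()
        doc.compartments.append(Compartment("c", 1.0))
        doc.species.append(Species("A", "c", initial_amount=1.0))
        doc.parameters.append(Parameter("k", value=100.0))
        doc.reactions.append(Reaction(
            "r", reactants=[SpeciesRef("A")],
            kinetic_law=parse_infix("k * A"), reversible=False,
            local_parameters=[Parameter("k", value=2.0)]))
        sys = compile_system(doc)
        dy = derivatives(sys, 0.0, np.array([1.0]))
        assert dy[0] == pytest.approx(-2.0)  # local k=2 shadows global 100


class TestDerivatives:
    def test_linear_decay(self, decay_model):
        sys = compile_system(decay_model)
        assert derivatives(sys, 0.0, np.array([2.0]))[0] == -2.0

    def test_mm_at_km(self, mm_model):
        sys = compile_system(mm_model)
        dy = derivatives(sys, 0.0, np.array([1.0, 0.0]))  # S at Km
        assert dy[sys.state_ids.index("S")] == pytest.approx(-50.0)
        assert dy[sys.state_ids.index("P")] == pytest.approx(50.0)

    def test_nonfinite_rate_raises(self, mm_model):
        mm_model.parameters[1].value = 0.0  # Km = 0 and S = 0 -> 0/0
        sys = compile_system(mm_model)
        with pytest.raises(IntegrationStateError):
            derivatives(sys, 0.0, np.array([0.0, 0.0]))

    def test_matches_naive_interpreter(self, fixture_models, rng):
        for name, doc in fixture_models.items():
            sys = compile_system(doc)
            y0 = initial_state(sys)
            for _ in range(100):
                y = y0 * rng.uniform(0.1, 2.0, size=len(y0)) + rng.uniform(
                    0.0, 1.0, size=len(y0))
                t = float(rng.uniform(0, 10))
                dy = derivatives(sys, t, y, build_p(sys))
                amounts = dict(zip(sys.state_ids, y))
                ref = naive_derivatives(doc, t, amounts)
                for i, sid in enumerate(sys.state_ids):
                    assert dy[i] == pytest.approx(ref[sid], rel=1e-12,
                                                  abs=1e-12), (name, sid)

    def test_pure_no_side_effects(self, mm_model):
        sys = compile_system(mm_model)
        y = np.array([3.0, 1.0])
        y_copy = y.copy()
        d1 = derivatives(sys, 0.0, y)
        d2 = derivatives(sys, 0.0, y)
        np.testing.assert_array_equal(y, y_copy)
        np.testing.assert_array_equal(d1, d2)


class TestInitialState:
    def test_concentration_times_size(self):
        doc = ModelDocument()
        doc.compartments.append(Compartment("c", 3.0))
        doc.species.append(Species("A", "c", initial_concentration=2.0))
        sys = compile_system(doc)
        np.testing.assert_allclose(initial_state(sys), [6.0])

    def test_assignment_rule_at_t0(self):
        doc = ModelDocument()
        doc.parameters.append(Parameter("p", value=5.0))
        doc.parameters.append(Parameter("x", constant=False))
        doc.rules.append(Rule("assignment", "x", parse_infix("2 * p")))
        sys = compile_system(doc)
        y0 = initial_state(sys)
        ctx = context_at(sys, 0.0, y0)
        assert ctx["x"] == 10.0

    def test_missing_initial_value(self):
        doc = ModelDocument()
        doc.compartments.append(Compartment("c", 1.0))
        doc.species.append(Species("A", "c"))
        doc.species[0].initial_amount = None
        with pytest.raises(Exception):  # validation or state error
            sys = compile_system(doc)
            initial_state(sys)

    def test_missing_parameter_named(self, decay_model):
        decay_model.parameters[0].value = None
        sys = compile_system(decay_model)
        with pytest.raises(IntegrationStateError, match="k"):
            build_p(sys)
        assert build_p(sys, {"k": 4.0})[sys.param_index("k")] == 4.0

    def test_synthetic_initials_match_generator(self, study_fixture):
        from sbmlfit.synthetic import ChainModelSpec, generate_chain_model
        doc, truth = generate_chain_model(ChainModelSpec(n_pairs=3, seed=1))
        sys = compile_system(doc)
        y0 = initial_state(sys)
        expected = {sid: 0.0 for sid in sys.state_ids}
        expected["M1_out"] = 100.0
        for i, sid in enumerate(sys.state_ids):
            assert y0[i] == expected[sid]


def _event_model(initial_trigger_value: bool = True) -> ModelDocument:
    doc = ModelDocument()
    doc.compartments.append(Compartment("c", 1.0))
    doc.species.append(
        Species("x", "c", initial_amount=1.0, has_only_substance_units=True))
    doc.events.append(Event(
        "e", trigger=parse_infix("time >= 5"),
        assignments=[EventAssignment("x", parse_infix("0"))],
        initial_trigger_value=initial_trigger_value))
    return doc


class TestEvents:
    def test_no_crossing_returns_none(self):
        sys = compile_system(_event_model())
        y = np.array([1.0])
        assert locate_and_fire_events(sys, 0.0, y, 1.0, y.copy()) is None

    def test_linear_trigger_crossing(self):
        sys = compile_system(_event_model())
        y0 = np.array([1.0])
        res = locate_and_fire_events(sys, 4.0, y0, 6.0, y0.copy())
        assert res is not None
        t_star, y_star = res
        assert t_star == pytest.approx(5.0, abs=1e-8)
        assert y_star[0] == 0.0

    def test_true_at_t0_with_initial_true_does_not_fire(self):
        sys = compile_system(_event_model(initial_trigger_value=True))
        y0 = np.array([1.0])
        # trigger already true on [6, 7]: no false->true transition
        res = locate_and_fire_events(sys, 6.0, y0, 7.0, y0.copy())
        assert res is None

    def test_integration_applies_event(self):
        from sbmlfit.solvers import SolverSettings, integrate
        sys = compile_system(_event_model())
        traj = integrate(sys, SolverSettings(
            t_start=0.0, t_end=10.0, output_step=1.0, method="rk45"))
        assert traj.ok
        x = traj.column("x")
        assert np.all(x[traj.times < 5.0 - 1e-9] == 1.0)
        assert np.all(x[traj.times >= 5.0 + 1e-9] == 0.0)

    def test_document_order_simultaneous(self):
        doc = _event_model()
        doc.events.append(Event(
            "e2", trigger=parse_infix("time >= 5"),
            assignments=[EventAssignment("x", parse_infix("7"))],
            initial_trigger_value=True))
        sys = compile_system(doc)
        y0 = np.array([1.0])
        res = locate_and_fire_events(sys, 4.0, y0, 6.0, y0.copy())
        t_star, y_star = res
        assert y_star[0] == 7.0  # e fires first, e2 overwrites


class TestVMEquivalence:
    """The stack-machine lowering must agree with the generated Python rhs."""

    def test_vm_matches_rhs(self, fixture_models, rng):
        pytest.importorskip("numba")
        from sbmlfit.fastpath import _vm_eval

        for name, doc in fixture_models.items():
            sys = compile_system(doc)
            assert sys.vm_code is not None, name
            p = build_p(sys)
            scratch = np.zeros(sys.vm_n_scratch + 1)
            stack = np.zeros(sys.vm_stack_size + 2)
            dy_vm = np.zeros(sys.n_state)
            for _ in range(20):
                y = rng.uniform(0.1, 5.0, size=sys.n_state)
                t = float(rng.uniform(0, 10))
                _vm_eval(sys.vm_code, sys.vm_consts, t, y, p,
                         scratch, stack, dy_vm)
                np.testing.assert_allclose(
                    dy_vm, sys.rhs(t, y, p), rtol=1e-13, atol=1e-300,
                    err_msg=name)
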