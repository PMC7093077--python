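"""Compile a :class:`ModelDocument` into an executable ODE system.

The compiler flattens the document into
  * a *state vector* ``y`` of amounts (dynamic species) and rate-rule
    variables,
  * a *parameter vector* ``p`` holding every remaining numeric symbol
    (compartment sizes, global/local parameters, clamped species amounts),
  * generated Python source for ``rhs(t, y, p) -> dy`` with assignment
    rules evaluated in topological order, reaction rates, and
    ``dy = N·v`` plus rate-rule contributions.

The generated source is plain scalar Python (``math`` + ``numpy`` only) so
the same text can be exec-compiled for the interpreter path or handed to
numba for the estimation fast path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from . import expr as ex
from . import vmops
from .model import ModelDocument, Rule, Species, validate_model

__all__ = [
    "CompileError",
    "IntegrationStateError",
    "CompiledSystem",
    "compile_system",
    "derivatives",
    "initial_state",
    "build_p",
    "context_at",
    "locate_and_fire_events",
]

EVENT_BISECT_REL_TOL = 1e-9


class CompileError(ValueError):
    pass


class IntegrationStateError(ValueError):
    """Non-finite rate or missing initial value, carrying the culprit id."""


@dataclass
class CompiledEvent:
    event_id: str
    trigger: Callable[[float, np.ndarray, np.ndarray], bool]
    initial_trigger_value: bool
    # (kind, index, needs_conc_scale, value_fn); kind: "y" | "p"
    assignments: list[tuple[str, int, str | None,
                            Callable[[float, np.ndarray, np.ndarray], float]]]


@dataclass
class CompiledSystem:
    doc: ModelDocument
    state_ids: list[str]
    species_state_count: int  # leading entries of state that are species
    stoichiometry: np.ndarray  # (species_state_count, n_reactions)
    reaction_ids: list[str]
    param_ids: list[str]
    param_defaults: np.ndarray
    assignment_order: list[str]
    report_ids: list[str]
    rhs: Callable[[float, np.ndarray, np.ndarray], np.ndarray]
    rhs_source: str
    rates_fn: Callable[[float, np.ndarray, np.ndarray], np.ndarray]
    report_fn: Callable[[float, np.ndarray, np.ndarray], np.ndarray]
    events: list[CompiledEvent] = field(default_factory=list)
    time_dependent: bool = False
    # stack-machine lowering for the jitted fast path (None if unavailable)
    vm_code: np.ndarray | None = None
    vm_consts: np.ndarray | None = None
    vm_stack_size: int = 0
    vm_n_scratch: int = 0
    _state_index: dict[str, int] = field(default_factory=dict)
    _param_index: dict[str, int] = field(default_factory=dict)

    @property
    def n_state(self) -> int:
        return len(self.state_ids)

    def param_index(self, name: str) -> int:
        return self._param_index[name]


def _species_in_state(doc: ModelDocument, s: Species) -> bool:
    if s.constant:
        return False
    rule = doc.rule_for(s.id)
    if rule is not None and rule.kind == "assignment":
        return False
    if s.boundary_condition and (rule is None or rule.kind != "rate"):
        return False
    return True


def _topo_order_assignments(doc: ModelDocument) -> list[str]:
    assign = {r.variable: r for r in doc.rules if r.kind == "assignment"}
    order: list[str] = []
    state = {v: 0 for v in assign}
    doc_pos = {r.variable: i for i, r in enumerate(doc.rules)
               if r.kind == "assignment"}

    def visit(v: str, stack: list[str]) -> None:
        state[v] = 1
        stack.append(v)
        deps = sorted(
            (d for d in ex.free_names(assign[v].math) if d in assign),
            key=lambda d: doc_pos[d])
        for dep in deps:
            if state[dep] == 1:
                cycle = stack[stack.index(dep):] + [dep]
                raise CompileError(
                    f"cyclic assignment rules: {' -> '.join(cycle)}")
            if state[dep] == 0:
                visit(dep, stack)
        stack.pop()
        state[v] = 2
        order.append(v)

    for v in sorted(assign, key=lambda d: doc_pos[d]):
        if state[v] == 0:
            visit(v, [])
    return order


def compile_system(model: ModelDocument) -> CompiledSystem:
    """Build the executable system; raises :class:`CompileError` on cyclic
    assignment rules or validation errors."""
    errors = [f for f in validate_model(model) if f.severity == "error"]
    if errors:
        raise CompileError("model has validation errors: "
                           + "; ".join(f.message for f in errors))

    functions = {fd.id: (fd.arguments, fd.body) for fd in model.function_defs}

    # ---- state layout -----------------------------------------------------
    state_species = [s for s in model.species if _species_in_state(model, s)]
    state_ids = [s.id for s in state_species]
    species_state_count = len(state_ids)
    rate_rules: dict[str, Rule] = {r.variable: r for r in model.rules
                                   if r.kind == "rate"}
    for r in model.rules:
        if r.kind == "rate" and r.variable not in state_ids:
            state_ids.append(r.variable)
    state_index = {sid: i for i, sid in enumerate(state_ids)}

    assignment_order = _topo_order_assignments(model)
    assigned = set(assignment_order)

    # ---- parameter vector layout ------------------------------------------
    param_ids: list[str] = []
    defaults: list[float] = []

    def add_p(pid: str, value: float | None) -> None:
        param_ids.append(pid)
        defaults.append(math.nan if value is None else float(value))

    for c in model.compartments:
        if c.id not in state_index and c.id not in assigned:
            add_p(c.id, c.size)
    for s in model.species:
        if s.id not in state_index and s.id not in assigned:
            add_p(s.id, _initial_amount_of(model, s))
    for p in model.parameters:
        if p.id not in state_index and p.id not in assigned:
            add_p(p.id, p.value)
    for rxn in model.reactions:
        for lp in rxn.local_parameters:
            add_p(f"{rxn.id}.{lp.id}", lp.value)
    param_index = {pid: i for i, pid in enumerate(param_ids)}

    species_by_id = {s.id: s for s in model.species}
    comp_by_id = {c.id: c for c in model.compartments}
    assign_var = {v: f"a{i}" for i, v in enumerate(assignment_order)}

    def symbol_code(ident: str, local_scope: Mapping[str, str]) -> str:
        if ident in local_scope:
            return local_scope[ident]
        if ident == ex.TIME_NAME:
            return "t"
        if ident in assign_var:
            return assign_var[ident]
        sp = species_by_id.get(ident)
        if sp is not None:
            if ident in state_index:
                amount = f"y[{state_index[ident]}]"
            else:
                amount = f"p[{param_index[ident]}]"
            if sp.has_only_substance_units:
                return amount
            return f"({amount} / {symbol_code(sp.compartment, {})})"
        if ident in state_index:
            return f"y[{state_index[ident]}]"
        if ident in param_index:
            return f"p[{param_index[ident]}]"
        raise CompileError(f"unresolvable identifier {ident!r}")

    def gen(e: ex.MathExpr, local_scope: Mapping[str, str] | None = None) -> str:
        scope = local_scope or {}
        inlined = ex.inline_calls(e, functions)
        return ex.to_python(inlined, lambda n: symbol_code(n, scope))

    # assignment-ruled species hold their value in species units; rules give
    # that value directly, so no unit conversion is applied here.
    assign_lines = []
    assign_rules = {r.variable: r for r in model.rules if r.kind == "assignment"}
    for v in assignment_order:
        assign_lines.append(f"    {assign_var[v]} = {gen(assign_rules[v].math)}")

    rate_lines = []
    reaction_ids = [r.id for r in model.reactions]
    for j, rxn in enumerate(model.reactions):
        if rxn.kinetic_law is None:
            rate_lines.append(f"    v{j} = 0.0")
            continue
        local_scope = {lp.id: f"p[{param_index[f'{rxn.id}.{lp.id}']}]"
                       for lp in rxn.local_parameters}
        rate_lines.append(f"    v{j} = {gen(rxn.kinetic_law, local_scope)}")

    # stoichiometry over species states; rate-ruled species get zero rows
    N = np.zeros((species_state_count, len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for ref in rxn.reactants:
            i = state_index.get(ref.species)
            if i is not None and i < species_state_count \
                    and ref.species not in rate_rules:
                N[i, j] -= ref.stoichiometry
        for ref in rxn.products:
            i = state_index.get(ref.species)
            if i is not None and i < species_state_count \
                    and ref.species not in rate_rules:
                N[i, j] += ref.stoichiometry

    dy_lines = []
    for i, sid in enumerate(state_ids):
        terms: list[str] = []
        if i < species_state_count and sid not in rate_rules:
            for j in range(len(model.reactions)):
                coeff = N[i, j]
                if coeff == 1.0:
                    terms.append(f"+ v{j}")
                elif coeff == -1.0:
                    terms.append(f"- v{j}")
                elif coeff != 0.0:
                    terms.append(f"+ ({coeff!r}) * v{j}")
        if sid in rate_rules:
            rr_code = gen(rate_rules[sid].math)
            sp = species_by_id.get(sid)
            if sp is not None and not sp.has_only_substance_units:
                # rate rule gives d(concentration)/dt; state is amount
                rr_code = f"({rr_code}) * {symbol_code(sp.compartment, {})}"
            terms.append(f"+ ({rr_code})")
        expr_src = " ".join(terms).lstrip("+ ").strip() or "0.0"
        if terms and terms[0].startswith("- "):
            expr_src = "-" + terms[0][2:] + " " + " ".join(terms[1:])
            expr_src = expr_src.strip()
        dy_lines.append(f"    dy[{i}] = {expr_src}")

    n_state = len(state_ids)
    n_rxn = len(model.reactions)
    rhs_src = "\n".join(
        ["def rhs(t, y, p):"]
        + assign_lines
        + rate_lines
        + [f"    dy = np.zeros({n_state})"]
        + dy_lines
        + ["    return dy", ""])
    rates_src = "\n".join(
        ["def rates(t, y, p):"]
        + assign_lines
        + rate_lines
        + [f"    v = np.zeros({n_rxn})"]
        + [f"    v[{j}] = v{j}" for j in range(n_rxn)]
        + ["    return v", ""])

    # ---- reported quantities ---------------------------------------------
    report_ids: list[str] = []
    report_codes: list[str] = []
    for s in model.species:
        report_ids.append(s.id)
        report_codes.append(symbol_code(s.id, {}))
    for c in model.compartments:
        if not c.constant or c.id in assigned or c.id in state_index:
            report_ids.append(c.id)
            report_codes.append(symbol_code(c.id, {}))
    for p in model.parameters:
        if not p.constant or p.id in assigned or p.id in state_index:
            report_ids.append(p.id)
            report_codes.append(symbol_code(p.id, {}))
    report_src = "\n".join(
        ["def report(t, y, p):"]
        + assign_lines
        + [f"    out = np.zeros({len(report_ids)})"]
        + [f"    out[{i}] = {code}" for i, code in enumerate(report_codes)]
        + ["    return out", ""])

    namespace: dict = {"math": math, "np": np}
    exec(rhs_src, namespace)
    exec(rates_src, namespace)
    exec(report_src, namespace)

    # ---- stack-machine lowering (fast path) -------------------------------
    vm_code = vm_consts = None
    vm_stack = vm_scratch = 0
    try:
        scratch_index = {v: i for i, v in enumerate(assignment_order)}
        rate_scratch_base = len(assignment_order)

        def resolve_ops(ident: str, pb: vmops.ProgramBuilder,
                        local_scope: Mapping[str, int] | None = None) -> None:
            if local_scope and ident in local_scope:
                pb.op(vmops.LOAD_P, local_scope[ident])
                return
            if ident == ex.TIME_NAME:
                pb.op(vmops.LOAD_T)
                return
            if ident in scratch_index:
                pb.op(vmops.LOAD_S, scratch_index[ident])
                return
            sp = species_by_id.get(ident)
            if sp is not None:
                if ident in state_index:
                    pb.op(vmops.LOAD_Y, state_index[ident])
                else:
                    pb.op(vmops.LOAD_P, param_index[ident])
                if not sp.has_only_substance_units:
                    resolve_ops(sp.compartment, pb)
                    pb.op(vmops.DIV)
                return
            if ident in state_index:
                pb.op(vmops.LOAD_Y, state_index[ident])
                return
            pb.op(vmops.LOAD_P, param_index[ident])

        pb = vmops.ProgramBuilder()
        for v in assignment_order:
            pb.expr(ex.inline_calls(assign_rules[v].math, functions),
                    lambda n, b: resolve_ops(n, b))
            pb.op(vmops.STORE_S, scratch_index[v])
        for j, rxn in enumerate(model.reactions):
            if rxn.kinetic_law is None:
                pb.const(0.0)
            else:
                lp_scope = {lp.id: param_index[f"{rxn.id}.{lp.id}"]
                            for lp in rxn.local_parameters}
                pb.expr(ex.inline_calls(rxn.kinetic_law, functions),
                        lambda n, b, s=lp_scope: resolve_ops(n, b, s))
            pb.op(vmops.STORE_S, rate_scratch_base + j)
        for i, sid in enumerate(state_ids):
            pb.const(0.0)
            if i < species_state_count and sid not in rate_rules:
                for j in range(len(model.reactions)):
                    coeff = N[i, j]
                    if coeff == 0.0:
                        continue
                    pb.op(vmops.LOAD_S, rate_scratch_base + j)
                    if coeff == -1.0:
                        pb.op(vmops.SUB)
                        continue
                    if coeff != 1.0:
                        pb.const(abs(coeff))
                        pb.op(vmops.MUL)
                    pb.op(vmops.SUB if coeff < 0 else vmops.ADD)
            if sid in rate_rules:
                pb.expr(ex.inline_calls(rate_rules[sid].math, functions),
                        lambda n, b: resolve_ops(n, b))
                sp = species_by_id.get(sid)
                if sp is not None and not sp.has_only_substance_units:
                    resolve_ops(sp.compartment, pb)
                    pb.op(vmops.MUL)
                pb.op(vmops.ADD)
            pb.op(vmops.STORE_DY, i)
        vm_code, vm_consts, vm_stack = pb.finish()
        vm_scratch = rate_scratch_base + len(model.reactions)
    except vmops.VMLoweringError:
        vm_code = vm_consts = None

    sys_ = CompiledSystem(
        doc=model,
        state_ids=state_ids,
        species_state_count=species_state_count,
        stoichiometry=N,
        reaction_ids=reaction_ids,
        param_ids=param_ids,
        param_defaults=np.array(defaults),
        assignment_order=assignment_order,
        report_ids=report_ids,
        rhs=namespace["rhs"],
        rhs_source=rhs_src,
        rates_fn=namespace["rates"],
        report_fn=namespace["report"],
        time_dependent=_uses_time(model),
        vm_code=vm_code,
        vm_consts=vm_consts,
        vm_stack_size=vm_stack,
        vm_n_scratch=vm_scratch,
        _state_index=state_index,
        _param_index=param_index,
    )

    for event in model.events:
        trig_src = f"def trig(t, y, p):\n" \
            + "\n".join(assign_lines) \
            + f"\n    return bool({gen(event.trigger)})\n"
        ns: dict = {"math": math, "np": np}
        exec(trig_src, ns)
        compiled_assignments = []
        for ea in event.assignments:
            val_src = f"def val(t, y, p):\n" \
                + "\n".join(assign_lines) \
                + f"\n    return float({gen(ea.math)})\n"
            ns_v: dict = {"math": math, "np": np}
            exec(val_src, ns_v)
            sp = species_by_id.get(ea.variable)
            conc_comp = None
            if sp is not None and not sp.has_only_substance_units:
                conc_comp = sp.compartment  # assigned value is a concentration
            if ea.variable in state_index:
                compiled_assignments.append(
                    ("y", state_index[ea.variable], conc_comp, ns_v["val"]))
            elif ea.variable in param_index:
                compiled_assignments.append(
                    ("p", param_index[ea.variable], conc_comp, ns_v["val"]))
            else:
                raise CompileError(
                    f"event {event.id!r} assigns non-assignable variable "
                    f"{ea.variable!r}")
        sys_.events.append(CompiledEvent(
            event_id=event.id,
            trigger=ns["trig"],
            initial_trigger_value=event.initial_trigger_value,
            assignments=compiled_assignments,
        ))
    return sys_


def _uses_time(model: ModelDocument) -> bool:
    exprs: list[ex.MathExpr] = []
    for rxn in model.reactions:
        if rxn.kinetic_law is not None:
            exprs.append(rxn.kinetic_law)
    exprs += [r.math for r in model.rules]
    for fd in model.function_defs:
        exprs.append(fd.body)
    return any(ex.TIME_NAME in ex.free_names(e) for e in exprs)


def _initial_amount_of(model: ModelDocument, s: Species) -> float | None:
    if s.initial_amount is not None:
        return s.initial_amount
    if s.initial_concentration is not None:
        comp = model.compartment(s.compartment)
        return s.initial_concentration * comp.size
    return None


def build_p(sys: CompiledSystem,
            overrides: Mapping[str, float] | None = None) -> np.ndarray:
    """Parameter vector from defaults plus overrides; NaN entries (unset
    values not overridden) raise naming the quantity."""
    p = sys.param_defaults.copy()
    if overrides:
        for key, val in overrides.items():
            idx = sys._param_index.get(key)
            if idx is not None:
                p[idx] = float(val)
    missing = [sys.param_ids[i] for i in np.flatnonzero(np.isnan(p))]
    if missing:
        raise IntegrationStateError(
            f"missing value for {', '.join(missing)}")
    return p


def initial_state(sys: CompiledSystem,
                  overrides: Mapping[str, float] | None = None) -> np.ndarray:
    """Initial amounts vector (state layout order).

    ``overrides`` may supply values for unset species initial values or
    rate-rule variables, keyed by id.
    """
    model = sys.doc
    overrides = overrides or {}
    y0 = np.empty(sys.n_state)
    for i, sid in enumerate(sys.state_ids):
        if sid in overrides and i >= sys.species_state_count:
            y0[i] = float(overrides[sid])
            continue
        try:
            sp = model.get_species(sid)
        except KeyError:
            sp = None
        if sp is not None:
            if sid in overrides:
                # override is given in the species' declared units
                comp = model.compartment(sp.compartment)
                v = float(overrides[sid])
                y0[i] = v if sp.has_only_substance_units or \
                    sp.initial_amount is not None else v * comp.size
                continue
            amount = _initial_amount_of(model, sp)
            if amount is None:
                raise IntegrationStateError(
                    f"missing initial value for species {sid!r}")
            y0[i] = amount
            continue
        # rate-rule variable: compartment or parameter
        val: float | None = None
        for c in model.compartments:
            if c.id == sid:
                val = c.size
        for par in model.parameters:
            if par.id == sid:
                val = par.value
        if val is None:
            raise IntegrationStateError(f"missing initial value for {sid!r}")
        y0[i] = val
    return y0


def derivatives(sys: CompiledSystem, t: float, y: np.ndarray,
                p: np.ndarray | None = None) -> np.ndarray:
    """dy/dt at ``(t, y)``; pure.  Raises on non-finite rates."""
    if p is None:
        p = build_p(sys)
    dy = sys.rhs(t, np.asarray(y, dtype=float), p)
    if not np.all(np.isfinite(dy)):
        bad = int(np.flatnonzero(~np.isfinite(dy))[0])
        raise IntegrationStateError(
            f"non-finite derivative for {sys.state_ids[bad]!r} at t={t}")
    return dy


def context_at(sys: CompiledSystem, t: float, y: np.ndarray,
               p: np.ndarray | None = None) -> dict[str, float]:
    """Full name->value map (species in their declared units, parameters,
    compartments, assignment variables, reaction rates and time)."""
    if p is None:
        p = build_p(sys)
    ctx: dict[str, float] = {ex.TIME_NAME: float(t)}
    rep = sys.report_fn(t, y, p)
    for rid, val in zip(sys.report_ids, rep):
        ctx[rid] = float(val)
    for pid, val in zip(sys.param_ids, p):
        if pid not in ctx:
            ctx[pid] = float(val)
    for sid, val in zip(sys.state_ids, y):
        ctx.setdefault(sid, float(val))
    rates = sys.rates_fn(t, y, p)
    for rid, val in zip(sys.reaction_ids, rates):
        ctx[rid] = float(val)
    return ctx


def trigger_values(sys: CompiledSystem, t: float, y: np.ndarray,
                   p: np.ndarray) -> list[bool]:
    return [ev.trigger(t, y, p) for ev in sys.events]


def locate_and_fire_events(
    sys: CompiledSystem,
    t0: float,
    y0: np.ndarray,
    t1: float,
    y1: np.ndarray,
    p: np.ndarray | None = None,
    prev_triggers: Sequence[bool] | None = None,
) -> tuple[float, np.ndarray] | None:
    """Earliest trigger false->true crossing in ``(t0, t1]``.

    Crossing time is located by bisection (linear interpolation of the
    state) to ``1e-9 * (t1 - t0)``; all events newly true at that time fire
    in document order and the post-assignment state is returned.  Event
    assignments targeting parameters mutate ``p`` in place.
    """
    if not sys.events:
        return None
    if p is None:
        p = build_p(sys)
    if prev_triggers is None:
        prev_triggers = trigger_values(sys, t0, y0, p)

    def interp(tm: float) -> np.ndarray:
        if t1 == t0:
            return y1.copy()
        w = (tm - t0) / (t1 - t0)
        return y0 + w * (y1 - y0)

    newly = [i for i, ev in enumerate(sys.events)
             if not prev_triggers[i] and ev.trigger(t1, y1, p)]
    if not newly:
        return None

    tol = EVENT_BISECT_REL_TOL * max(t1 - t0, 1e-300)
    lo, hi = t0, t1
    while hi - lo > tol:
        tm = 0.5 * (lo + hi)
        ym = interp(tm)
        if any(not prev_triggers[i] and sys.events[i].trigger(tm, ym, p)
               for i in range(len(sys.events))):
            hi = tm
        else:
            lo = tm
    t_star = hi
    y_star = interp(t_star)

    comp_size = _compartment_size_lookup(sys, p)
    for i, ev in enumerate(sys.events):
        if prev_triggers[i] or not ev.trigger(t_star, y_star, p):
            continue
        values = [(kind, idx, comp, fn(t_star, y_star, p))
                  for kind, idx, comp, fn in ev.assignments]
        for kind, idx, comp, val in values:
            if comp is not None:
                val = val * comp_size(comp)
            if kind == "y":
                y_star[idx] = val
            else:
                p[idx] = val
    return t_star, y_star


def _compartment_size_lookup(sys: CompiledSystem, p: np.ndarray):
    def size(cid: str) -> float:
        idx = sys._param_index.get(cid)
        if idx is not None:
            return float(p[idx])
        sidx = sys._state_index.get(cid)
        if sidx is not None:
            raise CompileError(
                f"event assignment to species in dynamic compartment {cid!r} "
                f"is not supported")
        return float(sys.doc.compartment(cid).size)
    return size
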