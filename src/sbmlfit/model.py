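"""In-memory representation of the supported SBML core subset."""

from __future__ import annotations

from dataclasses import dataclass, field

from .expr import MathExpr, TIME_NAME, free_names

__all__ = [
    "Compartment",
    "Species",
    "Parameter",
    "SpeciesRef",
    "Reaction",
    "Rule",
    "Event",
    "EventAssignment",
    "FunctionDef",
    "ModelDocument",
    "Finding",
    "validate_model",
]


@dataclass
class Compartment:
    id: str
    size: float = 1.0
    constant: bool = True
    name: str = ""


@dataclass
class Species:
    id: str
    compartment: str
    initial_amount: float | None = None
    initial_concentration: float | None = None
    boundary_condition: bool = False
    constant: bool = False
    has_only_substance_units: bool = False
    name: str = ""


@dataclass
class Parameter:
    id: str
    value: float | None = None
    constant: bool = True
    name: str = ""


@dataclass
class SpeciesRef:
    species: str
    stoichiometry: float = 1.0


@dataclass
class Reaction:
    id: str
    reactants: list[SpeciesRef] = field(default_factory=list)
    products: list[SpeciesRef] = field(default_factory=list)
    modifiers: list[str] = field(default_factory=list)
    kinetic_law: MathExpr | None = None
    reversible: bool = True
    local_parameters: list[Parameter] = field(default_factory=list)
    name: str = ""


@dataclass
class Rule:
    kind: str  # "assignment" | "rate"
    variable: str
    math: MathExpr

    def __post_init__(self) -> None:
        if self.kind not in ("assignment", "rate"):
            raise ValueError(f"unsupported rule kind {self.kind!r}")


@dataclass
class EventAssignment:
    variable: str
    math: MathExpr


@dataclass
class Event:
    id: str
    trigger: MathExpr
    assignments: list[EventAssignment] = field(default_factory=list)
    initial_trigger_value: bool = True
    name: str = ""


@dataclass
class FunctionDef:
    id: str
    arguments: list[str]
    body: MathExpr


@dataclass
class ModelDocument:
    model_id: str = "model"
    level: int = 3
    version: int = 2
    name: str = ""
    compartments: list[Compartment] = field(default_factory=list)
    species: list[Species] = field(default_factory=list)
    parameters: list[Parameter] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    rules: list[Rule] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    function_defs: list[FunctionDef] = field(default_factory=list)

    # -- lookup helpers -----------------------------------------------------
    def compartment(self, cid: str) -> Compartment:
        return _get(self.compartments, cid, "compartment")

    def get_species(self, sid: str) -> Species:
        return _get(self.species, sid, "species")

    def parameter(self, pid: str) -> Parameter:
        return _get(self.parameters, pid, "parameter")

    def reaction(self, rid: str) -> Reaction:
        return _get(self.reactions, rid, "reaction")

    @property
    def global_ids(self) -> set[str]:
        ids = {c.id for c in self.compartments}
        ids |= {s.id for s in self.species}
        ids |= {p.id for p in self.parameters}
        ids |= {r.id for r in self.reactions}
        return ids

    def rule_for(self, variable: str) -> Rule | None:
        for r in self.rules:
            if r.variable == variable:
                return r
        return None


def _get(items, item_id: str, what: str):
    for it in items:
        if it.id == item_id:
            return it
    raise KeyError(f"unknown {what} {item_id!r}")


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    entity: str
    message: str


def validate_model(model: ModelDocument) -> list[Finding]:
    """Check cross-reference and uniqueness invariants.

    Returns findings rather than raising; an empty list means the document
    is internally consistent and compilable.
    """
    findings: list[Finding] = []

    def err(entity: str, message: str) -> None:
        findings.append(Finding("error", entity, message))

    def warn(entity: str, message: str) -> None:
        findings.append(Finding("warning", entity, message))

    # id uniqueness across the global namespace
    seen: set[str] = set()
    for kind, items in (
        ("compartment", model.compartments),
        ("species", model.species),
        ("parameter", model.parameters),
        ("reaction", model.reactions),
        ("function definition", model.function_defs),
    ):
        for it in items:
            if it.id in seen:
                err(it.id, f"duplicate id {it.id!r} ({kind})")
            seen.add(it.id)

    comp_ids = {c.id for c in model.compartments}
    species_ids = {s.id for s in model.species}
    func_ids = {f.id for f in model.function_defs}
    known = model.global_ids | {TIME_NAME}

    for c in model.compartments:
        if c.size is not None and c.size <= 0:
            err(c.id, f"compartment {c.id!r} has non-positive size {c.size}")

    for s in model.species:
        if s.compartment not in comp_ids:
            err(s.id, f"species {s.id!r} references unknown compartment "
                      f"{s.compartment!r}")
        n_init = (s.initial_amount is not None) + (s.initial_concentration is not None)
        if n_init != 1:
            err(s.id, f"species {s.id!r} must set exactly one of "
                      f"initialAmount/initialConcentration")
        init = s.initial_amount if s.initial_amount is not None else s.initial_concentration
        if init is not None and init < 0:
            err(s.id, f"species {s.id!r} has negative initial value {init}")

    for fd in model.function_defs:
        extra = free_names(fd.body) - set(fd.arguments)
        if extra:
            err(fd.id, f"function {fd.id!r} body references non-arguments "
                       f"{sorted(extra)}")

    for rxn in model.reactions:
        local_ids = {p.id for p in rxn.local_parameters}
        for ref in rxn.reactants + rxn.products:
            if ref.species not in species_ids:
                err(rxn.id, f"reaction {rxn.id!r} references undeclared species "
                            f"{ref.species!r}")
            if ref.stoichiometry <= 0:
                err(rxn.id, f"reaction {rxn.id!r} has non-positive stoichiometry "
                            f"for {ref.species!r}")
        for mod in rxn.modifiers:
            if mod not in species_ids:
                err(rxn.id, f"reaction {rxn.id!r} modifier {mod!r} is undeclared")
        if rxn.kinetic_law is None:
            warn(rxn.id, f"reaction {rxn.id!r} has no kinetic law")
        else:
            dangling = free_names(rxn.kinetic_law) - known - local_ids - func_ids
            if dangling:
                err(rxn.id, f"kinetic law of {rxn.id!r} references undeclared "
                            f"identifiers {sorted(dangling)}")

    ruled: set[str] = set()
    for rule in model.rules:
        if rule.variable in ruled:
            err(rule.variable, f"variable {rule.variable!r} has more than one rule")
        ruled.add(rule.variable)
        if rule.variable not in known - {TIME_NAME}:
            err(rule.variable, f"rule targets unknown variable {rule.variable!r}")
        else:
            if _is_constant_entity(model, rule.variable):
                err(rule.variable,
                    f"rule targets constant quantity {rule.variable!r}")
        dangling = free_names(rule.math) - known - func_ids
        if dangling:
            err(rule.variable, f"rule for {rule.variable!r} references "
                               f"undeclared identifiers {sorted(dangling)}")

    # assignment-rule dependency cycles
    assign = {r.variable: r for r in model.rules if r.kind == "assignment"}
    state = {v: 0 for v in assign}  # 0 unvisited, 1 in-progress, 2 done

    def visit(v: str, stack: list[str]) -> None:
        state[v] = 1
        stack.append(v)
        for dep in free_names(assign[v].math):
            if dep in assign:
                if state[dep] == 1:
                    cycle = stack[stack.index(dep):] + [dep]
                    err(v, f"cyclic assignment rules: {' -> '.join(cycle)}")
                elif state[dep] == 0:
                    visit(dep, stack)
        stack.pop()
        state[v] = 2

    for v in assign:
        if state[v] == 0:
            visit(v, [])

    for ev in model.events:
        for ea in ev.assignments:
            if ea.variable not in known - {TIME_NAME}:
                err(ev.id, f"event {ev.id!r} assigns unknown variable "
                           f"{ea.variable!r}")
            elif _is_constant_entity(model, ea.variable):
                err(ev.id, f"event {ev.id!r} assigns constant quantity "
                           f"{ea.variable!r}")
        dangling = free_names(ev.trigger) - known - func_ids
        if dangling:
            err(ev.id, f"event trigger of {ev.id!r} references undeclared "
                       f"identifiers {sorted(dangling)}")

    return findings


def _is_constant_entity(model: ModelDocument, ident: str) -> bool:
    for c in model.compartments:
        if c.id == ident:
            return c.constant
    for s in model.species:
        if s.id == ident:
            return s.constant
    for p in model.parameters:
        if p.id == ident:
            return p.constant
    return False
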