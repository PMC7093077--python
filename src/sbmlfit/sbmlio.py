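"""Reading and writing the supported SBML core subset.

Only core constructs needed for ODE interpretation are handled: compartments,
species, parameters (global and reaction-local), reactions with kinetic laws,
assignment/rate rules, discrete events, and function definitions.  Documents
using delays, algebraic rules, constraints, fast reactions or conversion
factors are rejected with :class:`UnsupportedConstructError` naming the
construct.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET

from . import expr as ex
from .model import (
    Compartment,
    Event,
    EventAssignment,
    Finding,
    FunctionDef,
    ModelDocument,
    Parameter,
    Reaction,
    Rule,
    Species,
    SpeciesRef,
    validate_model,
)

__all__ = [
    "SBMLParseError",
    "SBMLValidationError",
    "UnsupportedConstructError",
    "parse_sbml",
    "write_sbml",
]

_L2_NS_PREFIX = "http://www.sbml.org/sbml/level2"
_L3_NS_PREFIX = "http://www.sbml.org/sbml/level3"
SBML_L3V2_NS = "http://www.sbml.org/sbml/level3/version2/core"


class SBMLParseError(ValueError):
    """Malformed XML or non-SBML content."""


class SBMLValidationError(ValueError):
    """Structurally invalid SBML (dangling references, duplicate ids...)."""

    def __init__(self, findings: list[Finding]):
        self.findings = findings
        msgs = "; ".join(f.message for f in findings)
        super().__init__(f"invalid SBML model: {msgs}")


class UnsupportedConstructError(ValueError):
    def __init__(self, construct: str):
        self.construct = construct
        super().__init__(f"unsupported construct: {construct}")


def _local(tag) -> str:
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else str(tag)


def _find(el: ET.Element, name: str) -> ET.Element | None:
    for child in el:
        if _local(child.tag) == name:
            return child
    return None


def _children(el: ET.Element | None, name: str) -> list[ET.Element]:
    if el is None:
        return []
    return [c for c in el if _local(c.tag) == name]


def _bool(el: ET.Element, attr: str, default: bool) -> bool:
    raw = el.get(attr)
    if raw is None:
        return default
    return raw in ("true", "1")


def _float(el: ET.Element, attr: str) -> float | None:
    raw = el.get(attr)
    return None if raw is None else float(raw)


def _math_of(el: ET.Element, what: str) -> ex.MathExpr:
    math_el = _find(el, "math")
    if math_el is None:
        raise SBMLParseError(f"missing <math> in {what}")
    return ex.parse_mathml(math_el)


def parse_sbml(source: str | os.PathLike) -> ModelDocument:
    """Parse an SBML file path or XML text into a :class:`ModelDocument`.

    Raises :class:`SBMLParseError` on malformed input,
    :class:`UnsupportedConstructError` on out-of-subset constructs, and
    :class:`SBMLValidationError` when cross-references do not resolve.
    """
    text: str
    if isinstance(source, os.PathLike) or (
        isinstance(source, str) and not source.lstrip().startswith("<")
    ):
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = source

    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise SBMLParseError(f"malformed XML: {exc}") from exc

    if _local(root.tag) != "sbml":
        raise SBMLParseError(f"root element is <{_local(root.tag)}>, expected <sbml>")
    ns = root.tag[1:].split("}")[0] if root.tag.startswith("{") else ""
    if not (ns.startswith(_L2_NS_PREFIX) or ns.startswith(_L3_NS_PREFIX)):
        raise SBMLParseError(f"unrecognized SBML namespace {ns!r}")

    level = int(root.get("level", "3"))
    version = int(root.get("version", "2"))
    if level == 2 and not 1 <= version <= 5:
        raise SBMLParseError(f"unsupported SBML level/version {level}.{version}")
    if level == 3 and not 1 <= version <= 2:
        raise SBMLParseError(f"unsupported SBML level/version {level}.{version}")
    if level not in (2, 3):
        raise SBMLParseError(f"unsupported SBML level {level}")

    model_el = _find(root, "model")
    if model_el is None:
        raise SBMLParseError("document has no <model>")

    if _find(model_el, "listOfConstraints") is not None:
        raise UnsupportedConstructError("constraint")

    doc = ModelDocument(
        model_id=model_el.get("id", "model"),
        name=model_el.get("name", ""),
        level=level,
        version=version,
    )

    for el in _children(_find(model_el, "listOfFunctionDefinitions"),
                        "functionDefinition"):
        math_el = _find(el, "math")
        if math_el is None:
            raise SBMLParseError("functionDefinition without <math>")
        lam = _find(math_el, "lambda")
        if lam is None:
            raise SBMLParseError("functionDefinition math must be a <lambda>")
        args: list[str] = []
        body: ex.MathExpr | None = None
        for child in lam:
            if _local(child.tag) == "bvar":
                ci = _find(child, "ci")
                if ci is None or not (ci.text or "").strip():
                    raise SBMLParseError("lambda <bvar> without identifier")
                args.append(ci.text.strip())
            else:
                body = ex.parse_mathml(child)
        if body is None:
            raise SBMLParseError("lambda without body")
        doc.function_defs.append(FunctionDef(el.get("id", ""), args, body))

    for el in _children(_find(model_el, "listOfCompartments"), "compartment"):
        size = _float(el, "size")
        if size is None:
            size = _float(el, "volume")  # L1/L2 spelling
        doc.compartments.append(Compartment(
            id=el.get("id", ""),
            size=1.0 if size is None else size,
            constant=_bool(el, "constant", True),
            name=el.get("name", ""),
        ))

    for el in _children(_find(model_el, "listOfSpecies"), "species"):
        if el.get("conversionFactor") is not None:
            raise UnsupportedConstructError("conversionFactor")
        doc.species.append(Species(
            id=el.get("id", ""),
            compartment=el.get("compartment", ""),
            initial_amount=_float(el, "initialAmount"),
            initial_concentration=_float(el, "initialConcentration"),
            boundary_condition=_bool(el, "boundaryCondition", False),
            constant=_bool(el, "constant", False),
            has_only_substance_units=_bool(el, "hasOnlySubstanceUnits", False),
            name=el.get("name", ""),
        ))

    for el in _children(_find(model_el, "listOfParameters"), "parameter"):
        doc.parameters.append(Parameter(
            id=el.get("id", ""),
            value=_float(el, "value"),
            constant=_bool(el, "constant", True),
            name=el.get("name", ""),
        ))

    rules_el = _find(model_el, "listOfRules")
    if rules_el is not None:
        for el in rules_el:  # document order preserved
            tag = _local(el.tag)
            if tag == "algebraicRule":
                raise UnsupportedConstructError("algebraicRule")
            if tag not in ("assignmentRule", "rateRule"):
                raise SBMLParseError(f"unknown rule element <{tag}>")
            variable = el.get("variable")
            if not variable:
                raise SBMLParseError(f"<{tag}> without variable")
            kind = "assignment" if tag == "assignmentRule" else "rate"
            doc.rules.append(Rule(kind, variable, _math_of(el, tag)))

    for el in _children(_find(model_el, "listOfReactions"), "reaction"):
        if _bool(el, "fast", False):
            raise UnsupportedConstructError("fast reaction")
        rxn = Reaction(
            id=el.get("id", ""),
            reversible=_bool(el, "reversible", True),
            name=el.get("name", ""),
        )
        for side, target in (("listOfReactants", rxn.reactants),
                             ("listOfProducts", rxn.products)):
            for ref in _children(_find(el, side), "speciesReference"):
                stoich = _float(ref, "stoichiometry")
                target.append(SpeciesRef(
                    species=ref.get("species", ""),
                    stoichiometry=1.0 if stoich is None else stoich,
                ))
        for ref in _children(_find(el, "listOfModifiers"),
                             "modifierSpeciesReference"):
            rxn.modifiers.append(ref.get("species", ""))
        kl = _find(el, "kineticLaw")
        if kl is not None:
            rxn.kinetic_law = _math_of(kl, f"kineticLaw of {rxn.id}")
            for lp_list in ("listOfLocalParameters", "listOfParameters"):
                for lp in _children(_find(kl, lp_list),
                                    "localParameter" if "Local" in lp_list
                                    else "parameter"):
                    rxn.local_parameters.append(Parameter(
                        id=lp.get("id", ""),
                        value=_float(lp, "value"),
                        constant=True,
                    ))
        doc.reactions.append(rxn)

    for el in _children(_find(model_el, "listOfEvents"), "event"):
        if _find(el, "delay") is not None:
            raise UnsupportedConstructError("delay")
        if _find(el, "priority") is not None:
            raise UnsupportedConstructError("event priority")
        trigger_el = _find(el, "trigger")
        if trigger_el is None:
            raise SBMLParseError(f"event {el.get('id')!r} without trigger")
        ev = Event(
            id=el.get("id", ""),
            trigger=_math_of(trigger_el, "event trigger"),
            initial_trigger_value=_bool(trigger_el, "initialValue", True),
            name=el.get("name", ""),
        )
        for ea in _children(_find(el, "listOfEventAssignments"),
                            "eventAssignment"):
            variable = ea.get("variable")
            if not variable:
                raise SBMLParseError("eventAssignment without variable")
            ev.assignments.append(
                EventAssignment(variable, _math_of(ea, "eventAssignment")))
        doc.events.append(ev)

    findings = [f for f in validate_model(doc) if f.severity == "error"]
    if findings:
        raise SBMLValidationError(findings)
    return doc


# ---------------------------------------------------------------------------
# writer (always emits Level 3 Version 2 core)

def _set_bool(el: ET.Element, attr: str, v: bool) -> None:
    el.set(attr, "true" if v else "false")


def _attach_math(parent: ET.Element, e: ex.MathExpr) -> None:
    parent.append(ex.to_mathml(e))


def write_sbml(model: ModelDocument) -> str:
    """Serialize a :class:`ModelDocument` to SBML Level 3 Version 2 text.

    ``parse_sbml(write_sbml(m))`` reproduces ``m`` field-by-field (with
    level/version normalized to 3.2).
    """
    root = ET.Element("sbml", {
        "xmlns": SBML_L3V2_NS,
        "level": "3",
        "version": "2",
    })
    m = ET.SubElement(root, "model", {"id": model.model_id})
    if model.name:
        m.set("name", model.name)

    if model.function_defs:
        lst = ET.SubElement(m, "listOfFunctionDefinitions")
        for fd in model.function_defs:
            el = ET.SubElement(lst, "functionDefinition", {"id": fd.id})
            math_el = ET.SubElement(el, f"{{{ex.MATHML_NS}}}math")
            lam = ET.SubElement(math_el, f"{{{ex.MATHML_NS}}}lambda")
            for arg in fd.arguments:
                bvar = ET.SubElement(lam, f"{{{ex.MATHML_NS}}}bvar")
                ci = ET.SubElement(bvar, f"{{{ex.MATHML_NS}}}ci")
                ci.text = f" {arg} "
            body_math = ex.to_mathml(fd.body)
            lam.append(body_math[0])

    if model.compartments:
        lst = ET.SubElement(m, "listOfCompartments")
        for c in model.compartments:
            el = ET.SubElement(lst, "compartment", {"id": c.id})
            if c.name:
                el.set("name", c.name)
            el.set("size", repr(float(c.size)))
            el.set("spatialDimensions", "3")
            _set_bool(el, "constant", c.constant)

    if model.species:
        lst = ET.SubElement(m, "listOfSpecies")
        for s in model.species:
            el = ET.SubElement(lst, "species", {
                "id": s.id,
                "compartment": s.compartment,
            })
            if s.name:
                el.set("name", s.name)
            if s.initial_amount is not None:
                el.set("initialAmount", repr(float(s.initial_amount)))
            if s.initial_concentration is not None:
                el.set("initialConcentration", repr(float(s.initial_concentration)))
            _set_bool(el, "hasOnlySubstanceUnits", s.has_only_substance_units)
            _set_bool(el, "boundaryCondition", s.boundary_condition)
            _set_bool(el, "constant", s.constant)

    if model.parameters:
        lst = ET.SubElement(m, "listOfParameters")
        for p in model.parameters:
            el = ET.SubElement(lst, "parameter", {"id": p.id})
            if p.name:
                el.set("name", p.name)
            if p.value is not None:
                el.set("value", repr(float(p.value)))
            _set_bool(el, "constant", p.constant)

    if model.rules:
        lst = ET.SubElement(m, "listOfRules")
        for r in model.rules:
            tag = "assignmentRule" if r.kind == "assignment" else "rateRule"
            el = ET.SubElement(lst, tag, {"variable": r.variable})
            _attach_math(el, r.math)

    if model.reactions:
        lst = ET.SubElement(m, "listOfReactions")
        for rxn in model.reactions:
            el = ET.SubElement(lst, "reaction", {"id": rxn.id})
            if rxn.name:
                el.set("name", rxn.name)
            _set_bool(el, "reversible", rxn.reversible)
            for side, refs in (("listOfReactants", rxn.reactants),
                               ("listOfProducts", rxn.products)):
                if refs:
                    side_el = ET.SubElement(el, side)
                    for ref in refs:
                        r_el = ET.SubElement(side_el, "speciesReference", {
                            "species": ref.species,
                            "stoichiometry": repr(float(ref.stoichiometry)),
                        })
                        _set_bool(r_el, "constant", True)
            if rxn.modifiers:
                mods = ET.SubElement(el, "listOfModifiers")
                for mod in rxn.modifiers:
                    ET.SubElement(mods, "modifierSpeciesReference",
                                  {"species": mod})
            if rxn.kinetic_law is not None:
                kl = ET.SubElement(el, "kineticLaw")
                _attach_math(kl, rxn.kinetic_law)
                if rxn.local_parameters:
                    lp_lst = ET.SubElement(kl, "listOfLocalParameters")
                    for lp in rxn.local_parameters:
                        lp_el = ET.SubElement(lp_lst, "localParameter",
                                              {"id": lp.id})
                        if lp.value is not None:
                            lp_el.set("value", repr(float(lp.value)))

    if model.events:
        lst = ET.SubElement(m, "listOfEvents")
        for ev in model.events:
            el = ET.SubElement(lst, "event", {"id": ev.id})
            _set_bool(el, "useValuesFromTriggerTime", True)
            trig = ET.SubElement(el, "trigger")
            _set_bool(trig, "persistent", True)
            _set_bool(trig, "initialValue", ev.initial_trigger_value)
            _attach_math(trig, ev.trigger)
            if ev.assignments:
                eas = ET.SubElement(el, "listOfEventAssignments")
                for ea in ev.assignments:
                    ea_el = ET.SubElement(eas, "eventAssignment",
                                          {"variable": ea.variable})
                    _attach_math(ea_el, ea.math)

    ET.register_namespace("math", ex.MATHML_NS)
    ET.indent(root)
    body = ET.tostring(root, encoding="unicode")
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + body + "\n"
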