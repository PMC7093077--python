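"""Independent reference implementations used only by the tests.

The naive derivative oracle walks the model document directly with the
tree-walking expression evaluator — no code generation, no stoichiometry
matrix — so it shares no evaluation path with the compiled system.
"""

from __future__ import annotations

import numpy as np

from sbmlfit.expr import TIME_NAME, evaluate
from sbmlfit.model import ModelDocument


def naive_context(doc: ModelDocument, t: float,
                  amounts: dict[str, float],
                  overrides: dict[str, float] | None = None) -> dict[str, float]:
    """Name->value context with species expressed in their declared units."""
    overrides = overrides or {}
    ctx: dict[str, float] = {TIME_NAME: t}
    for c in doc.compartments:
        ctx[c.id] = overrides.get(c.id, c.size)
    for p in doc.parameters:
        val = overrides.get(p.id, p.value)
        if val is not None:
            ctx[p.id] = val
    for s in doc.species:
        if s.id in amounts:
            amount = amounts[s.id]
        elif s.initial_amount is not None:
            amount = overrides.get(s.id, s.initial_amount)
        else:
            amount = overrides.get(s.id, (s.initial_concentration or 0.0)
                                   * ctx[s.compartment])
        if s.has_only_substance_units:
            ctx[s.id] = amount
        else:
            ctx[s.id] = amount / ctx[s.compartment]

    funcs = {fd.id: (fd.arguments, fd.body) for fd in doc.function_defs}
    # fixed-point iteration over assignment rules (no topological sort)
    assign = [r for r in doc.rules if r.kind == "assignment"]
    for _ in range(len(assign) + 1):
        for r in assign:
            try:
                ctx[r.variable] = evaluate(r.math, ctx, funcs)
            except KeyError:
                pass  # dependency not yet available; next pass
    return ctx


def naive_derivatives(doc: ModelDocument, t: float,
                      amounts: dict[str, float],
                      overrides: dict[str, float] | None = None
                      ) -> dict[str, float]:
    """d(amount)/dt per dynamic quantity by direct document walking."""
    ctx = naive_context(doc, t, amounts, overrides)
    funcs = {fd.id: (fd.arguments, fd.body) for fd in doc.function_defs}

    rates: dict[str, float] = {}
    for rxn in doc.reactions:
        local_ctx = dict(ctx)
        for lp in rxn.local_parameters:
            v = (overrides or {}).get(f"{rxn.id}.{lp.id}", lp.value)
            local_ctx[lp.id] = v
        if rxn.kinetic_law is None:
            rates[rxn.id] = 0.0
        else:
            rates[rxn.id] = evaluate(rxn.kinetic_law, local_ctx, funcs)

    rate_ruled = {r.variable for r in doc.rules if r.kind == "rate"}
    dy: dict[str, float] = {}
    for s in doc.species:
        if s.constant or s.id in rate_ruled:
            continue
        if s.boundary_condition:
            continue
        total = 0.0
        for rxn in doc.reactions:
            for ref in rxn.reactants:
                if ref.species == s.id:
                    total -= ref.stoichiometry * rates[rxn.id]
            for ref in rxn.products:
                if ref.species == s.id:
                    total += ref.stoichiometry * rates[rxn.id]
        dy[s.id] = total
    for r in doc.rules:
        if r.kind != "rate":
            continue
        val = evaluate(r.math, ctx, funcs)
        sp = next((s for s in doc.species if s.id == r.variable), None)
        if sp is not None and not sp.has_only_substance_units:
            val *= ctx[sp.compartment]
        dy[r.variable] = val
    return dy


def reference_rse(sim_times, sim_cols: dict[str, np.ndarray],
                  data_times, data_cols: dict[str, np.ndarray],
                  mapping: dict[str, str], epsilon: float = 1e-10) -> float:
    """Brute-force double-loop relative squared error."""
    total = 0.0
    for col, target in mapping.items():
        d = data_cols[col]
        valid = [(tt, dv) for tt, dv in zip(data_times, d)
                 if not np.isnan(dv)]
        if not valid:
            continue
        nonzero_mags = [abs(dv) for _, dv in valid if abs(dv) > epsilon]
        fallback = (sum(nonzero_mags) / len(nonzero_mags)
                    if nonzero_mags else None)
        for tt, dv in valid:
            sv = float(np.interp(tt, sim_times, sim_cols[target]))
            if abs(dv) > epsilon:
                denom = abs(dv)
            elif fallback is not None:
                denom = fallback
            else:
                denom = 1.0
            total += ((sv - dv) / denom) ** 2
    return total
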