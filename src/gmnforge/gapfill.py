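"""Gap-filling: restore biomass-precursor producibility with a minimal set
of reference-model reactions.

Unproducible biomass precursors are found with temporary per-precursor
sinks.  Repair solves a minimal-addition problem: one binary indicator per
candidate reference reaction, minimising the number of additions subject
to steady state and a biomass floor (default 0.1 h⁻¹), with the model's
own bounds respected.  Added reactions are imported gene-free and tagged
``origin="gapfill"``.  An exact MILP (HiGHS) is the default; a greedy
fallback (iteratively add the candidate giving the largest biomass
improvement) is available and results are labelled accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .fluxsim import fba
from .model import MetabolicModel, Reaction

__all__ = ["GapfillResult", "check_biomass_precursors", "fill_gaps"]

PRODUCIBLE_TOL = 1e-6


class GapfillInfeasibleError(RuntimeError):
    """Biomass floor unreachable even with the full reference."""


@dataclass
class GapfillResult:
    unproducible_before: set[str] = field(default_factory=set)
    added_reactions: list[str] = field(default_factory=list)
    growth_after: float = 0.0
    method: str = "exact"


def _apply_medium(model: MetabolicModel, medium) -> MetabolicModel:
    if medium is None:
        return model.copy()
    if hasattr(medium, "apply"):
        return medium.apply(model)
    out = model.copy()
    for rid, max_uptake in medium.items():
        out.reactions[rid].lower_bound = -abs(max_uptake)
    return out


def check_biomass_precursors(model: MetabolicModel, medium=None) -> set[str]:
    """Biomass substrates whose maximal production is ≤ 1e-6 under the
    medium (temporary sinks added and removed per precursor).

    A substrate that fails the plain sink test is retested with temporary
    sources for the biomass products: carrier cofactors consumed by biomass
    and regenerated by it (ATP/ADP-style conserved moieties) cannot be
    net-produced by any model, and only count as unproducible when even
    the discharged partner cannot be recharged.
    """
    if model.biomass_reaction_id is None:
        raise ValueError("model has no biomass reaction")
    work = _apply_medium(model, medium)
    biomass = work.reactions[work.biomass_reaction_id]
    precursors = sorted(m for m, c in biomass.stoichiometry.items() if c < 0)
    products = sorted(m for m, c in biomass.stoichiometry.items() if c > 0)
    unproducible = set()
    for met in precursors:
        sink_id = f"SINK_{met}__tmp"
        work.add_reaction(Reaction(sink_id, stoichiometry={met: -1.0}))
        sol = fba(work, objective=sink_id, sense="max")
        producible = sol.optimal and sol.objective_value > PRODUCIBLE_TOL
        if not producible:
            source_ids = []
            for prod in products:
                src_id = f"SRC_{prod}__tmp"
                work.add_reaction(Reaction(src_id, stoichiometry={prod: 1.0}))
                source_ids.append(src_id)
            sol = fba(work, objective=sink_id, sense="max")
            producible = sol.optimal and sol.objective_value > PRODUCIBLE_TOL
            for src_id in source_ids:
                del work.reactions[src_id]
        if not producible:
            unproducible.add(met)
        del work.reactions[sink_id]
    return unproducible


def fill_gaps(
    model: MetabolicModel,
    reference: MetabolicModel,
    medium=None,
    biomass_min: float = 0.1,
    method: str = "exact",
    tie_break_delta: float = 1e-6,
) -> tuple[MetabolicModel, GapfillResult]:
    """Add a minimal set of reference reactions so biomass ≥ ``biomass_min``.

    Candidates are reference reactions absent from the model (by id).
    Ties among equal-size minimal sets are broken toward lexicographically
    earlier reaction ids via an infinitesimal objective perturbation, so
    the result is deterministic.  Returns the filled model and a result
    record; raises :class:`GapfillInfeasibleError` when even the full
    reference cannot reach the floor, naming the blocked precursors.
    """
    result = GapfillResult(
        unproducible_before=check_biomass_precursors(model, medium),
        method=method,
    )
    work = _apply_medium(model, medium)
    candidates = sorted(set(reference.reactions) - set(work.reactions))

    if method == "greedy":
        added = _greedy_fill(work, reference, candidates, biomass_min)
    else:
        added = _milp_fill(work, reference, candidates, biomass_min, tie_break_delta)
    if added is None:
        raise GapfillInfeasibleError(
            "biomass floor unreachable even with the full reference; "
            f"blocked precursors: {sorted(result.unproducible_before)}"
        )

    filled = model.copy()
    for rid in added:
        rxn = reference.reactions[rid].copy()
        rxn.gpr = None  # imported without gene information
        rxn.origin = "gapfill"
        for met in rxn.stoichiometry:
            if met not in filled.metabolites:
                filled.add_metabolite(reference.metabolites[met].copy())
        filled.add_reaction(rxn)
    result.added_reactions = sorted(added)
    sol = fba(_apply_medium(filled, medium))
    result.growth_after = sol.objective_value if sol.optimal else 0.0
    return filled, result


def _milp_fill(
    work: MetabolicModel,
    reference: MetabolicModel,
    candidates: list[str],
    biomass_min: float,
    delta: float,
) -> Optional[list[str]]:
    union = work.copy()
    for rid in candidates:
        rxn = reference.reactions[rid].copy()
        for met in rxn.stoichiometry:
            if met not in union.metabolites:
                union.add_metabolite(reference.metabolites[met].copy())
        union.add_reaction(rxn)

    rxn_ids = sorted(union.reactions)
    met_ids = sorted(union.metabolites)
    met_index = {m: i for i, m in enumerate(met_ids)}
    n_v = len(rxn_ids)
    n_z = len(candidates)
    cand_index = {rid: k for k, rid in enumerate(candidates)}

    lb = np.array([union.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([union.reactions[r].upper_bound for r in rxn_ids])
    j_bio = rxn_ids.index(work.biomass_reaction_id)
    lb[j_bio] = max(lb[j_bio], biomass_min)

    rows, cols, vals = [], [], []
    for j, rid in enumerate(rxn_ids):
        for met, coef in union.reactions[rid].stoichiometry.items():
            rows.append(met_index[met])
            cols.append(j)
            vals.append(coef)
    S = sparse.csr_matrix((vals, (rows, cols)), shape=(len(met_ids), n_v + n_z))
    constraints = [LinearConstraint(S, 0.0, 0.0)]

    # candidate flux gating: lb_c * z <= v_c <= ub_c * z
    g_rows, g_cols, g_vals, g_lo, g_hi = [], [], [], [], []
    row = 0
    for rid, k in cand_index.items():
        j = rxn_ids.index(rid)
        # v - ub*z <= 0
        g_rows += [row, row]
        g_cols += [j, n_v + k]
        g_vals += [1.0, -ub[j]]
        g_lo.append(-np.inf)
        g_hi.append(0.0)
        row += 1
        # v - lb*z >= 0
        g_rows += [row, row]
        g_cols += [j, n_v + k]
        g_vals += [1.0, -lb[j]]
        g_lo.append(0.0)
        g_hi.append(np.inf)
        row += 1
    if row:
        G = sparse.csr_matrix((g_vals, (g_rows, g_cols)), shape=(row, n_v + n_z))
        constraints.append(LinearConstraint(G, g_lo, g_hi))

    c = np.zeros(n_v + n_z)
    for rid, k in cand_index.items():
        c[n_v + k] = 1.0 + delta * k  # rank perturbation for tie-breaking
    var_lb = np.concatenate([lb, np.zeros(n_z)])
    var_ub = np.concatenate([ub, np.ones(n_z)])
    integrality = np.concatenate([np.zeros(n_v), np.ones(n_z)])

    res = milp(
        c,
        constraints=constraints,
        bounds=Bounds(var_lb, var_ub),
        integrality=integrality,
    )
    if res.status != 0:
        return None
    z = res.x[n_v:]
    return [rid for rid, k in cand_index.items() if z[k] > 0.5]


def _greedy_fill(
    work: MetabolicModel,
    reference: MetabolicModel,
    candidates: list[str],
    biomass_min: float,
) -> Optional[list[str]]:
    current = work.copy()
    added: list[str] = []

    def growth(m: MetabolicModel) -> float:
        sol = fba(m)
        return sol.objective_value if sol.optimal else 0.0

    remaining = list(candidates)
    while growth(current) < biomass_min:
        best_rid, best_growth = None, growth(current)
        for rid in remaining:
            trial = current.copy()
            rxn = reference.reactions[rid].copy()
            for met in rxn.stoichiometry:
                if met not in trial.metabolites:
                    trial.add_metabolite(reference.metabolites[met].copy())
            trial.add_reaction(rxn)
            g = growth(trial)
            if g > best_growth + 1e-9:
                best_rid, best_growth = rid, g
        if best_rid is None:
            return None
        rxn = reference.reactions[best_rid].copy()
        for met in rxn.stoichiometry:
            if met not in current.metabolites:
                current.add_metabolite(reference.metabolites[met].copy())
        current.add_reaction(rxn)
        added.append(best_rid)
        remaining.remove(best_rid)
    return added
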