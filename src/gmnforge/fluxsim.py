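"""Constraint-based flux simulation.

Flux balance analysis (FBA) solves ``max/min c·v`` subject to steady-state
mass balance ``S·v = 0`` and flux bounds ``lb ≤ v ≤ ub``; flux variability
analysis (FVA) minimises and maximises each reaction flux under the same
constraints.  A reaction whose FVA interval satisfies
``|min| + |max| < 1e-5`` is classified as blocked (unable to carry flux in
any feasible steady state).

All linear programs are solved with the HiGHS solver through
:func:`scipy.optimize.linprog`, with deterministic construction so repeated
runs give identical reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .gpr import evaluate_gpr
from .model import MetabolicModel

__all__ = [
    "FluxSolution",
    "FvaResult",
    "build_stoichiometric_matrix",
    "fba",
    "fva",
    "single_gene_deletion",
    "double_reaction_deletion",
]

#: Blocked-reaction threshold on |vmin| + |vmax| from FVA.
BLOCKED_TOL = 1e-5
#: Mass-balance residual tolerance for reported optimal solutions.
BALANCE_TOL = 1e-6


@dataclass
class FluxSolution:
    """Outcome of a single FBA solve."""

    objective_value: float
    fluxes: dict[str, float]
    status: str  # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FvaResult:
    """Per-reaction flux ranges and the derived blocked set."""

    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    blocked: set[str] = field(default_factory=set)


def build_stoichiometric_matrix(
    model: MetabolicModel,
) -> tuple[sparse.csr_matrix, list[str], list[str]]:
    """Return (S, metabolite order, reaction order) for a model."""
    met_ids = sorted(model.metabolites)
    rxn_ids = sorted(model.reactions)
    met_index = {m: i for i, m in enumerate(met_ids)}
    rows, cols, vals = [], [], []
    for j, rid in enumerate(rxn_ids):
        for met, coef in model.reactions[rid].stoichiometry.items():
            rows.append(met_index[met])
            cols.append(j)
            vals.append(coef)
    S = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
    )
    return S, met_ids, rxn_ids


class _LpContext:
    """Reusable LP skeleton for one model (bounds mutated per solve)."""

    def __init__(self, model: MetabolicModel):
        self.model = model
        self.S, self.met_ids, self.rxn_ids = build_stoichiometric_matrix(model)
        self.rxn_index = {r: j for j, r in enumerate(self.rxn_ids)}
        self.lb = np.array([model.reactions[r].lower_bound for r in self.rxn_ids])
        self.ub = np.array([model.reactions[r].upper_bound for r in self.rxn_ids])

    def solve(
        self,
        objective: str,
        sense: str = "max",
        lb: Optional[np.ndarray] = None,
        ub: Optional[np.ndarray] = None,
    ) -> FluxSolution:
        lb = self.lb if lb is None else lb
        ub = self.ub if ub is None else ub
        c = np.zeros(len(self.rxn_ids))
        c[self.rxn_index[objective]] = -1.0 if sense == "max" else 1.0
        res = linprog(
            c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=np.column_stack([lb, ub]),
            method="highs",
        )
        if res.status == 2:
            return FluxSolution(float("nan"), {}, "infeasible")
        if res.status == 3:
            return FluxSolution(float("inf") if sense == "max" else float("-inf"), {}, "unbounded")
        if res.status != 0:
            raise RuntimeError(f"LP solver failure: {res.message}")
        value = -res.fun if sense == "max" else res.fun
        fluxes = dict(zip(self.rxn_ids, res.x))
        return FluxSolution(float(value), fluxes, "optimal")


def fba(
    model: MetabolicModel,
    objective: Optional[str] = None,
    sense: Optional[str] = None,
) -> FluxSolution:
    """Flux balance analysis; defaults to the model's own objective.

    Infeasibility and unboundedness are reported through ``status``, never
    as silent zero fluxes.
    """
    ctx = _LpContext(model)
    return ctx.solve(objective or model.objective, sense or model.objective_sense)


def fva(
    model: MetabolicModel,
    reactions: Optional[Iterable[str]] = None,
    fix_objective_fraction: Optional[float] = None,
) -> FvaResult:
    """Flux variability analysis.

    With ``fix_objective_fraction`` given, the model objective is first
    optimised and constrained to at least that fraction of its optimum
    before ranging each reaction.
    """
    ctx = _LpContext(model)
    lb, ub = ctx.lb.copy(), ctx.ub.copy()
    if fix_objective_fraction is not None:
        wt = ctx.solve(model.objective, model.objective_sense)
        if not wt.optimal:
            raise RuntimeError(f"FVA objective pre-solve status: {wt.status}")
        j = ctx.rxn_index[model.objective]
        if model.objective_sense == "max":
            lb[j] = max(lb[j], fix_objective_fraction * wt.objective_value)
        else:
            ub[j] = min(ub[j], fix_objective_fraction * wt.objective_value)
    targets = sorted(reactions) if reactions is not None else ctx.rxn_ids
    result = FvaResult()
    for rid in targets:
        lo = ctx.solve(rid, "min", lb=lb, ub=ub)
        hi = ctx.solve(rid, "max", lb=lb, ub=ub)
        vmin = lo.objective_value if lo.optimal else float("nan")
        vmax = hi.objective_value if hi.optimal else float("nan")
        result.ranges[rid] = (vmin, vmax)
        if abs(vmin) + abs(vmax) < BLOCKED_TOL:
            result.blocked.add(rid)
    return result


def _knockout_bounds(
    ctx: _LpContext, knocked_out: set[str]
) -> tuple[np.ndarray, np.ndarray]:
    lb, ub = ctx.lb.copy(), ctx.ub.copy()
    for j, rid in enumerate(ctx.rxn_ids):
        gpr = ctx.model.reactions[rid].gpr
        if gpr is not None and not evaluate_gpr(gpr, knocked_out):
            lb[j] = 0.0
            ub[j] = 0.0
    return lb, ub


def single_gene_deletion(
    model: MetabolicModel,
    genes: Optional[Iterable[str]] = None,
) -> dict[str, float]:
    """Maximal growth after each single-gene knockout.

    A knockout suppresses every reaction whose GPR rule evaluates false
    with the gene removed; growth is then re-optimised by FBA.  The
    wild-type growth is recorded under the key ``""``.
    """
    ctx = _LpContext(model)
    objective = model.objective
    wt = ctx.solve(objective, "max")
    results: dict[str, float] = {"": wt.objective_value if wt.optimal else 0.0}
    for gene in sorted(genes if genes is not None else model.genes):
        lb, ub = _knockout_bounds(ctx, {gene})
        sol = ctx.solve(objective, "max", lb=lb, ub=ub)
        results[gene] = sol.objective_value if sol.optimal else 0.0
    return results


def double_reaction_deletion(
    model: MetabolicModel,
    candidates: Iterable[str],
    objective: Optional[str] = None,
    sense: str = "max",
    cap: int = 200,
) -> dict[tuple[str, str], float]:
    """Objective value after jointly zeroing each unordered reaction pair."""
    cand = sorted(candidates)
    if len(cand) > cap:
        raise ValueError(
            f"{len(cand)} candidate reactions exceed the cap of {cap}; "
            "pre-filter candidates (e.g. to reactions with nonzero flux range)"
        )
    ctx = _LpContext(model)
    obj = objective or model.objective
    out: dict[tuple[str, str], float] = {}
    for i, r1 in enumerate(cand):
        for r2 in cand[i + 1:]:
            lb, ub = ctx.lb.copy(), ctx.ub.copy()
            for rid in (r1, r2):
                j = ctx.rxn_index[rid]
                lb[j] = 0.0
                ub[j] = 0.0
            sol = ctx.solve(obj, sense, lb=lb, ub=ub)
            out[(r1, r2)] = sol.objective_value if sol.optimal else 0.0
    return out
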