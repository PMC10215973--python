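"""Expression-guided differential flux analysis (ΔFBA).

Probe-level differential expression is filtered (p < 0.01), aggregated per
gene (max over any up-regulated probe ≥ 1.5, min over any down-regulated
probe ≤ 0.67, mean otherwise or when probes disagree) and mapped onto
reactions through GPR logic (min over AND — a complex is limited by its
scarcest subunit; max over OR — isozymes add up).  The flux-difference
vector Δv between the two conditions is then estimated by a two-step
optimisation: step 1 maximises the number of expression-called reactions
whose Δv is sign-consistent with the call at magnitude ≥ ε; step 2, with
that count fixed, minimises Σ|Δv| over the uncalled reactions
(parsimonious inconsistency).  Regulated reaction sets are thresholded at
|Δv| > 0.1% of the largest flux bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .gpr import GprTree
from .model import DEFAULT_BOUND, MetabolicModel

__all__ = [
    "DeltaFluxSolution",
    "aggregate_gene_fold_changes",
    "map_expression_to_reactions",
    "delta_fba",
    "open_exchanges",
    "regulated_genes",
]

P_CUTOFF = 0.01
UP_FC = 1.5
DOWN_FC = 0.67
#: Regulated-set threshold as a fraction of the largest flux bound.
THRESHOLD_FRACTION = 0.001


def aggregate_gene_fold_changes(
    table: pd.DataFrame,
    p_cutoff: float = P_CUTOFF,
    up_fc: float = UP_FC,
    down_fc: float = DOWN_FC,
) -> dict[str, float]:
    """Per-gene fold change from probe-level rows.

    Probes with p ≥ ``p_cutoff`` are dropped first; a gene with no
    surviving probe is omitted.  Then per gene: probes on both sides of
    the thresholds → mean (ambiguous); any probe ≥ ``up_fc`` → max; any
    probe ≤ ``down_fc`` → min; all moderate → mean.
    """
    significant = table[table["p_value"] < p_cutoff]
    out: dict[str, float] = {}
    for gene, grp in significant.groupby("gene_id"):
        fc = grp["fold_change"].to_numpy()
        has_up = (fc >= up_fc).any()
        has_down = (fc <= down_fc).any()
        if has_up and has_down:
            out[str(gene)] = float(fc.mean())
        elif has_up:
            out[str(gene)] = float(fc.max())
        elif has_down:
            out[str(gene)] = float(fc.min())
        else:
            out[str(gene)] = float(fc.mean())
    return out


def _map_gpr(gpr: Optional[GprTree], gene_fc: dict[str, float]) -> Optional[float]:
    if gpr is None:
        return None
    if gpr.kind == "gene":
        return gene_fc.get(gpr.gene)  # type: ignore[arg-type]
    vals = [_map_gpr(c, gene_fc) for c in gpr.children]
    measured = [v for v in vals if v is not None]
    if not measured:
        return None
    return min(measured) if gpr.kind == "and" else max(measured)


def map_expression_to_reactions(
    model: MetabolicModel,
    gene_fc: dict[str, float],
) -> dict[str, Optional[float]]:
    """Reaction-level fold changes via recursive GPR evaluation.

    AND takes the minimum over measured children, OR the maximum; a
    reaction with no measured gene (or no GPR) maps to ``None``
    (unmeasured) and is never given a numeric value.
    """
    return {rid: _map_gpr(r.gpr, gene_fc) for rid, r in model.reactions.items()}


def open_exchanges(model: MetabolicModel, bound: float = DEFAULT_BOUND) -> MetabolicModel:
    """Copy with unrestricted uptake/secretion for every exchange."""
    out = model.copy()
    for rxn in out.reactions.values():
        if rxn.is_exchange():
            rxn.lower_bound = -bound
            rxn.upper_bound = bound
    return out


@dataclass
class DeltaFluxSolution:
    """Estimated condition-difference fluxes and derived regulated sets."""

    delta_v: dict[str, float] = field(default_factory=dict)
    consistent_set: set[str] = field(default_factory=set)
    up_regulated: set[str] = field(default_factory=set)
    down_regulated: set[str] = field(default_factory=set)
    called_up: set[str] = field(default_factory=set)
    called_down: set[str] = field(default_factory=set)
    n_consistent: int = 0
    threshold: float = 0.0


def delta_fba(
    model: MetabolicModel,
    rxn_fc: dict[str, Optional[float]],
    up_fc: float = UP_FC,
    down_fc: float = DOWN_FC,
    epsilon: Optional[float] = None,
    ngam_fixed: bool = True,
) -> DeltaFluxSolution:
    """Two-step ΔFBA.

    Δv is constrained by steady state (S·Δv = 0, the difference of two
    steady-state flux vectors) and per-reaction difference bounds
    Δv ∈ [lb − ub, ub − lb]; with ``ngam_fixed`` the maintenance flux is
    assumed unchanged between conditions (Δv = 0).  ``epsilon`` defaults
    to the regulated-set threshold (0.1% of the largest bound) so that a
    consistent reaction clears the reporting threshold by construction.
    """
    rxn_ids = sorted(model.reactions)
    index = {r: j for j, r in enumerate(rxn_ids)}
    n = len(rxn_ids)
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    if not np.isfinite(lb).all() or not np.isfinite(ub).all():
        raise ValueError("ΔFBA requires finite flux bounds")
    max_bound = float(np.max(np.abs(np.concatenate([lb, ub]))))
    threshold = THRESHOLD_FRACTION * max_bound
    eps = threshold if epsilon is None else epsilon

    dlb = lb - ub
    dub = ub - lb
    if ngam_fixed and model.ngam_reaction_id:
        j = index[model.ngam_reaction_id]
        dlb[j] = dub[j] = 0.0

    called_up = sorted(
        r for r, fc in rxn_fc.items() if fc is not None and fc >= up_fc and r in index
    )
    called_down = sorted(
        r for r, fc in rxn_fc.items() if fc is not None and fc <= down_fc and r in index
    )
    called = called_up + called_down
    uncalled = [r for r in rxn_ids if r not in set(called)]

    # variable layout: [Δv (n)] [y (len(called), binary)] [t (len(uncalled))]
    n_y = len(called)
    n_t = len(uncalled)

    rows, cols, vals = [], [], []
    met_ids = sorted(model.metabolites)
    met_index = {m: i for i, m in enumerate(met_ids)}
    for j, rid in enumerate(rxn_ids):
        for met, coef in model.reactions[rid].stoichiometry.items():
            rows.append(met_index[met])
            cols.append(j)
            vals.append(coef)
    S = sparse.csr_matrix((vals, (rows, cols)), shape=(len(met_ids), n + n_y + n_t))
    steady = LinearConstraint(S, 0.0, 0.0)

    # consistency indicators: up-called  Δv_i + M_i(1-y_i) >= ε
    #                         down-called Δv_i - M_i(1-y_i) <= -ε
    c_rows, c_cols, c_vals, c_lo, c_hi = [], [], [], [], []
    row = 0
    for k, rid in enumerate(called):
        j = index[rid]
        if rid in set(called_up):
            m_big = eps - dlb[j]
            c_rows += [row, row]
            c_cols += [j, n + k]
            c_vals += [1.0, -m_big]
            c_lo.append(eps - m_big)
            c_hi.append(np.inf)
        else:
            m_big = dub[j] + eps
            c_rows += [row, row]
            c_cols += [j, n + k]
            c_vals += [1.0, m_big]
            c_lo.append(-np.inf)
            c_hi.append(m_big - eps)
        row += 1
    consistency = (
        LinearConstraint(
            sparse.csr_matrix((c_vals, (c_rows, c_cols)), shape=(row, n + n_y + n_t)),
            c_lo,
            c_hi,
        )
        if row
        else None
    )

    # |Δv| linearisation for uncalled reactions: t_j >= ±Δv_j
    a_rows, a_cols, a_vals, a_lo, a_hi = [], [], [], [], []
    row = 0
    for k, rid in enumerate(uncalled):
        j = index[rid]
        for sign in (1.0, -1.0):
            a_rows += [row, row]
            a_cols += [n + n_y + k, j]
            a_vals += [1.0, -sign]
            a_lo.append(0.0)
            a_hi.append(np.inf)
            row += 1
    absval = (
        LinearConstraint(
            sparse.csr_matrix((a_vals, (a_rows, a_cols)), shape=(row, n + n_y + n_t)),
            a_lo,
            a_hi,
        )
        if row
        else None
    )

    var_lb = np.concatenate([dlb, np.zeros(n_y), np.zeros(n_t)])
    var_ub = np.concatenate([dub, np.ones(n_y), np.full(n_t, np.inf)])
    integrality = np.concatenate([np.zeros(n), np.ones(n_y), np.zeros(n_t)])
    base_constraints = [c for c in (steady, consistency, absval) if c is not None]

    solution = DeltaFluxSolution(
        called_up=set(called_up), called_down=set(called_down), threshold=threshold
    )

    # Step 1: maximise the number of sign-consistent called reactions.
    if n_y:
        c1 = np.zeros(n + n_y + n_t)
        c1[n: n + n_y] = -1.0
        res1 = milp(c1, constraints=base_constraints,
                    bounds=Bounds(var_lb, var_ub), integrality=integrality)
        if res1.status != 0:
            raise RuntimeError(
                f"ΔFBA step 1 failed ({res1.message}); check S·Δv=0 with the "
                "fixed-maintenance constraint for an irreducible conflict"
            )
        n_consistent = int(round(-res1.fun))
    else:
        n_consistent = 0
    solution.n_consistent = n_consistent

    # Step 2: with the consistency count fixed, minimise Σ|Δv| off-call.
    c2 = np.zeros(n + n_y + n_t)
    c2[n + n_y:] = 1.0
    constraints2 = list(base_constraints)
    if n_y:
        count_row = sparse.csr_matrix(
            (np.ones(n_y), (np.zeros(n_y, dtype=int), np.arange(n, n + n_y))),
            shape=(1, n + n_y + n_t),
        )
        constraints2.append(LinearConstraint(count_row, n_consistent, n_consistent))
    res2 = milp(c2, constraints=constraints2,
                bounds=Bounds(var_lb, var_ub), integrality=integrality)
    if res2.status != 0:
        raise RuntimeError(f"ΔFBA step 2 failed ({res2.message})")

    dv = res2.x[:n]
    solution.delta_v = {rid: float(dv[index[rid]]) for rid in rxn_ids}
    y = res2.x[n: n + n_y]
    solution.consistent_set = {rid for k, rid in enumerate(called) if y[k] > 0.5}
    for rid in called_up:
        if solution.delta_v[rid] >= threshold - 1e-9:
            solution.up_regulated.add(rid)
    for rid in called_down:
        if solution.delta_v[rid] <= -threshold + 1e-9:
            solution.down_regulated.add(rid)
    return solution


def regulated_genes(
    model: MetabolicModel, solution: DeltaFluxSolution
) -> dict[str, set[str]]:
    """Genes involved in the regulated reactions, via GPR leaf extraction."""
    up: set[str] = set()
    down: set[str] = set()
    for rid in solution.up_regulated:
        up |= model.reactions[rid].genes
    for rid in solution.down_regulated:
        down |= model.reactions[rid].genes
    return {"up": up, "down": down}
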