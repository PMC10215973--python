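"""Energy-leak detection and localisation.

An energy leak is the spurious production of a charged energy metabolite
(ATP, NADH, NADPH, FADH2, GTP, or a proton gradient) with every uptake
closed — the signature of an erroneous cycle, typically an incorrectly
compartmentalised or duplicated reaction pair.  Detection constrains all
exchange reactions to secretion only, adds a dissipation reaction
discharging the metabolite (e.g. ATP + H2O → ADP + Pi + H+), and maximises
its rate; a nonzero optimum indicates leakage.  Localisation then screens
single- and double-reaction deletions for the culprits whose blocking
zeroes the dissipation flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .fluxsim import BLOCKED_TOL, _LpContext, fva
from .model import DEFAULT_BOUND, MetabolicModel, Reaction

__all__ = ["LeakResult", "test_leaks", "localize_leak", "DEFAULT_ENERGY_METABOLITES"]

#: Charging metabolites screened by default.
DEFAULT_ENERGY_METABOLITES = ("atp", "nadh", "nadph", "fadh2", "gtp", "h")

LEAK_TOL = 1e-6

#: Discharge templates: charged base name -> (required partners with
#: coefficients, optional partners with coefficients).  Optional species
#: are included only where present in the same compartment; required
#: partners missing in a compartment skip that compartment.
_DISSIPATION_TEMPLATES: dict[str, tuple[dict[str, float], dict[str, float]]] = {
    "atp": ({"atp": -1.0, "adp": 1.0, "pi": 1.0}, {"h2o": -1.0, "h": 1.0}),
    "gtp": ({"gtp": -1.0, "gdp": 1.0, "pi": 1.0}, {"h2o": -1.0, "h": 1.0}),
    "nadh": ({"nadh": -1.0, "nad": 1.0}, {"h": 1.0}),
    "nadph": ({"nadph": -1.0, "nadp": 1.0}, {"h": 1.0}),
    "fadh2": ({"fadh2": -1.0, "fad": 1.0}, {"h": 2.0}),
}

_ALIASES = {
    "atp": {"atp"}, "adp": {"adp"}, "pi": {"pi", "phosphate"},
    "h2o": {"h2o", "water"}, "h": {"h", "h+", "proton"},
    "gtp": {"gtp"}, "gdp": {"gdp"},
    "nadh": {"nadh"}, "nad": {"nad", "nad+"},
    "nadph": {"nadph"}, "nadp": {"nadp", "nadp+"},
    "fadh2": {"fadh2"}, "fad": {"fad"},
}


@dataclass
class LeakResult:
    """Leak status of one energy metabolite."""

    metabolite: str
    dissipation_flux: float = 0.0
    compartment: Optional[str] = None
    culprit_pairs: list[tuple[str, str]] = field(default_factory=list)
    culprit_singles: list[str] = field(default_factory=list)

    @property
    def leaking(self) -> bool:
        return self.dissipation_flux > LEAK_TOL


def _base_name(model: MetabolicModel, met_id: str) -> str:
    met = model.metabolites[met_id]
    base = met_id
    if base.endswith(f"_{met.compartment}"):
        base = base[: -len(met.compartment) - 1]
    return base.casefold()


def _find(model: MetabolicModel, base: str, comp: str) -> Optional[str]:
    aliases = _ALIASES.get(base, {base})
    for mid, met in model.metabolites.items():
        if met.compartment == comp and _base_name(model, mid) in aliases:
            return mid
    return None


def closed_uptake_model(model: MetabolicModel) -> MetabolicModel:
    """Copy with all exchange uptakes closed (secretion only) and any
    maintenance floor relaxed (a forced drain is meaningless without
    nutrients and would make the closed problem infeasible)."""
    closed = model.copy()
    for rxn in closed.reactions.values():
        if rxn.is_exchange():
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    if closed.ngam_reaction_id:
        ngam = closed.reactions[closed.ngam_reaction_id]
        ngam.lower_bound = min(ngam.lower_bound, 0.0)
    return closed


def _add_dissipation(
    model: MetabolicModel, base: str, comp: str
) -> Optional[str]:
    """Add (or reuse) the discharge reaction for one charged species in one
    compartment; returns its reaction id, or None when partners are
    missing.  A bare proton discharges down the gradient (H+[k] → H+[c])."""
    rid = f"DISSIP_{base}_{comp}"
    if rid in model.reactions:
        return rid
    if base == "h":
        if comp == "c":
            return None
        src = _find(model, "h", comp)
        dst = _find(model, "h", "c")
        if src is None or dst is None:
            return None
        model.add_reaction(
            Reaction(rid, name=f"H+ gradient discharge {comp}->c",
                     stoichiometry={src: -1.0, dst: 1.0},
                     upper_bound=DEFAULT_BOUND)
        )
        return rid
    required, optional = _DISSIPATION_TEMPLATES[base]
    stoich: dict[str, float] = {}
    for partner, coef in required.items():
        mid = _find(model, partner, comp)
        if mid is None:
            return None
        stoich[mid] = coef
    for partner, coef in optional.items():
        mid = _find(model, partner, comp)
        if mid is not None:
            stoich[mid] = stoich.get(mid, 0.0) + coef
    model.add_reaction(
        Reaction(rid, name=f"{base} dissipation ({comp})",
                 stoichiometry=stoich, upper_bound=DEFAULT_BOUND)
    )
    return rid


def _leak_lp(
    model: MetabolicModel, base: str
) -> list[tuple[str, str, MetabolicModel, str]]:
    """Closed-uptake models with a dissipation objective, one per
    compartment where the charged form exists with its partners."""
    out = []
    comps = sorted({
        m.compartment
        for mid, m in model.metabolites.items()
        if _base_name(model, mid) in _ALIASES.get(base, {base})
    })
    for comp in comps:
        closed = closed_uptake_model(model)
        rid = _add_dissipation(closed, base, comp)
        if rid is None:
            continue
        out.append((base, comp, closed, rid))
    return out


def test_leaks(
    model: MetabolicModel,
    energy_metabolites: Iterable[str] = DEFAULT_ENERGY_METABOLITES,
) -> list[LeakResult]:
    """Maximal dissipation rate per energy metabolite with uptakes closed.

    A metabolite absent from the model (or lacking its discharge partners)
    is skipped.  For a metabolite present in several compartments the
    worst (largest) dissipation optimum is reported.
    """
    results = []
    for base in energy_metabolites:
        base = base.casefold()
        lps = _leak_lp(model, base)
        if not lps:
            continue
        result = LeakResult(metabolite=base)
        for _, comp, closed, rid in lps:
            sol = _LpContext(closed).solve(rid, "max")
            flux = sol.objective_value if sol.optimal else (
                float("inf") if sol.status == "unbounded" else 0.0
            )
            if result.compartment is None or flux > result.dissipation_flux:
                result.dissipation_flux = flux
                result.compartment = comp
        results.append(result)
    return results


def localize_leak(
    model: MetabolicModel,
    leak: LeakResult,
    candidate_cap: int = 200,
) -> LeakResult:
    """Fill in the culprit reaction pairs for a detected leak.

    Candidates are the reactions with nonzero flux range on the leak LP
    (flux variability on the closed-uptake model with the dissipation
    objective present); every unordered candidate pair is deleted jointly
    and the pairs driving the dissipation optimum to ≤ 1e-6 are returned.
    Single deletions are screened first, so ``culprit_singles`` lists
    reactions sufficient on their own to stop the leak.
    """
    if not leak.leaking:
        raise ValueError(f"{leak.metabolite}: no leak to localize (flux "
                         f"{leak.dissipation_flux:g} ≤ {LEAK_TOL:g})")
    lps = [t for t in _leak_lp(model, leak.metabolite) if t[1] == leak.compartment]
    if not lps:
        raise ValueError(f"cannot rebuild leak LP for {leak.metabolite}")
    _, _, closed, dissip_rid = lps[0]

    ranges = fva(closed)
    candidates = sorted(
        rid for rid in ranges.ranges
        if rid != dissip_rid and rid not in ranges.blocked
    )
    if len(candidates) > candidate_cap:
        raise ValueError(
            f"{len(candidates)} leak candidates exceed cap {candidate_cap}; "
            "tighten the pre-filter (e.g. restrict to recently merged reactions)"
        )

    ctx = _LpContext(closed)

    def optimum_without(blocked: tuple[str, ...]) -> float:
        lb, ub = ctx.lb.copy(), ctx.ub.copy()
        for rid in blocked:
            j = ctx.rxn_index[rid]
            lb[j] = 0.0
            ub[j] = 0.0
        sol = ctx.solve(dissip_rid, "max", lb=lb, ub=ub)
        return sol.objective_value if sol.optimal else 0.0

    leak.culprit_singles = [
        rid for rid in candidates if optimum_without((rid,)) <= LEAK_TOL
    ]
    leak.culprit_pairs = [
        (r1, r2)
        for i, r1 in enumerate(candidates)
        for r2 in candidates[i + 1:]
        if optimum_without((r1, r2)) <= LEAK_TOL
    ]
    return leak
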