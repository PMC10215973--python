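"""Core domain types for constraint-based metabolic models.

A :class:`MetabolicModel` is a compartmentalised stoichiometric network: a
keyed collection of metabolites and reactions, flux bounds in
mmol·gDW⁻¹·h⁻¹, boolean GPR rules linking genes to reactions, and a biomass
objective.  Reversibility is encoded solely by ``lower_bound < 0``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

from .gpr import (
    GprTree,
    gpr_genes,
    gpr_or,
    gpr_to_string,
    gprs_equivalent,
    normalize_gpr,
)

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelIntegrityError",
    "merge_models",
    "edit_biomass",
    "models_equal",
    "DEFAULT_BOUND",
]

#: Default magnitude for unspecified flux bounds (mmol·gDW⁻¹·h⁻¹), the
#: conventional "unlimited" rate for genome-scale models.
DEFAULT_BOUND = 1000.0


class ModelIntegrityError(ValueError):
    """A structural invariant of a model is violated."""


@dataclass
class Metabolite:
    """A chemical species instance in one compartment.

    ``xrefs`` maps a namespace (``kegg``, ``chebi``, ``pubchem``,
    ``lipidmaps``) to a set of external identifiers; ChEBI entries are kept
    only at curation rank 3 (see :mod:`gmnforge.curation`).
    """

    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None
    xrefs: dict[str, set[str]] = field(default_factory=dict)
    synonyms: set[str] = field(default_factory=set)

    def copy(self) -> "Metabolite":
        return Metabolite(
            id=self.id,
            name=self.name,
            compartment=self.compartment,
            formula=self.formula,
            xrefs={ns: set(v) for ns, v in self.xrefs.items()},
            synonyms=set(self.synonyms),
        )


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds and a GPR rule.

    ``stoichiometry`` maps metabolite id → signed coefficient (negative =
    substrate).  ``origin`` records provenance: ``template``,
    ``kegg_metacyc``, ``gapfill`` or ``manual``.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr: Optional[GprTree] = None
    subsystem: str = ""
    origin: str = "template"

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def genes(self) -> set[str]:
        return gpr_genes(self.gpr)

    @property
    def gene_reaction_rule(self) -> str:
        return gpr_to_string(self.gpr)

    def is_exchange(self) -> bool:
        """Exchange/sink reactions touch exactly one metabolite."""
        return len(self.stoichiometry) == 1

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            name=self.name,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            gpr=self.gpr,
            subsystem=self.subsystem,
            origin=self.origin,
        )

    def validate(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelIntegrityError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        for met, coef in self.stoichiometry.items():
            if coef == 0:
                raise ModelIntegrityError(
                    f"reaction {self.id}: zero coefficient for {met}"
                )


@dataclass
class MetabolicModel:
    """A genome-scale metabolic network.

    The gene set is always derived from the union of GPR leaves.  The
    objective defaults to maximising the biomass reaction; ``ngam_reaction_id``
    optionally names the non-growth-associated maintenance reaction whose
    flux represents baseline ATP expenditure.
    """

    id: str = "model"
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    compartments: dict[str, str] = field(default_factory=dict)
    biomass_reaction_id: Optional[str] = None
    objective_reaction_id: Optional[str] = None
    objective_sense: str = "max"
    ngam_reaction_id: Optional[str] = None

    # -- construction -----------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ModelIntegrityError(f"duplicate metabolite id {met.id}")
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ModelIntegrityError(f"duplicate reaction id {rxn.id}")
        rxn.validate()
        self.reactions[rxn.id] = rxn
        return rxn

    # -- derived views ----------------------------------------------------
    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.genes
        return out

    @property
    def objective(self) -> str:
        rid = self.objective_reaction_id or self.biomass_reaction_id
        if rid is None:
            raise ModelIntegrityError("model has no objective reaction")
        return rid

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange()]

    def reactions_for_gene(self, gene: str) -> list[Reaction]:
        return [r for r in self.reactions.values() if gene in r.genes]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites={k: m.copy() for k, m in self.metabolites.items()},
            reactions={k: r.copy() for k, r in self.reactions.items()},
            compartments=dict(self.compartments),
            biomass_reaction_id=self.biomass_reaction_id,
            objective_reaction_id=self.objective_reaction_id,
            objective_sense=self.objective_sense,
            ngam_reaction_id=self.ngam_reaction_id,
        )

    def validate(self) -> None:
        """Check referential integrity; raise listing all offenders."""
        dangling = []
        for rxn in self.reactions.values():
            rxn.validate()
            for met in rxn.stoichiometry:
                if met not in self.metabolites:
                    dangling.append((rxn.id, met))
        if dangling:
            listing = ", ".join(f"{r}->{m}" for r, m in dangling[:20])
            raise ModelIntegrityError(
                f"{len(dangling)} dangling metabolite reference(s): {listing}"
            )
        for attr in ("biomass_reaction_id", "objective_reaction_id", "ngam_reaction_id"):
            rid = getattr(self, attr)
            if rid is not None and rid not in self.reactions:
                raise ModelIntegrityError(f"{attr} {rid!r} is not a reaction")
        bad_comp = [
            m.id
            for m in self.metabolites.values()
            if self.compartments and m.compartment not in self.compartments
        ]
        if bad_comp:
            raise ModelIntegrityError(
                f"metabolites in undeclared compartments: {bad_comp[:20]}"
            )


# ---------------------------------------------------------------------------
# Model-level operations
# ---------------------------------------------------------------------------

def merge_models(base: MetabolicModel, addition: MetabolicModel) -> MetabolicModel:
    """Union of two models, unifying metabolites on (name, compartment).

    Metabolite naming must already be harmonised across the inputs (see
    :func:`gmnforge.curation.apply_synonym_merge` in ``across`` mode).
    Reaction-id collisions: an identical reaction (same stoichiometry and
    bounds) is kept once with its GPRs OR-combined; a same-id reaction with
    contradictory bounds or stoichiometry raises; otherwise the incoming
    copy is suffixed with its origin tag.
    """
    merged = base.copy()
    # map (name, compartment) -> existing metabolite id
    by_name: dict[tuple[str, str], str] = {
        (m.name or m.id, m.compartment): m.id for m in merged.metabolites.values()
    }
    met_rename: dict[str, str] = {}
    for met in addition.metabolites.values():
        key = (met.name or met.id, met.compartment)
        if key in by_name:
            met_rename[met.id] = by_name[key]
        else:
            new = met.copy()
            if new.id in merged.metabolites:
                new.id = f"{new.id}__{addition.id}"
            merged.add_metabolite(new)
            by_name[key] = new.id
            met_rename[met.id] = new.id

    for comp, name in addition.compartments.items():
        merged.compartments.setdefault(comp, name)

    for rxn in addition.reactions.values():
        new = rxn.copy()
        new.stoichiometry = {
            met_rename.get(m, m): c for m, c in rxn.stoichiometry.items()
        }
        if new.id in merged.reactions:
            existing = merged.reactions[new.id]
            if existing.stoichiometry == new.stoichiometry:
                if (existing.lower_bound, existing.upper_bound) != (
                    new.lower_bound,
                    new.upper_bound,
                ):
                    raise ModelIntegrityError(
                        f"contradictory bounds for shared reaction id {new.id}"
                    )
                if not gprs_equivalent(existing.gpr, new.gpr):
                    combined = [g for g in (existing.gpr, new.gpr) if g is not None]
                    existing.gpr = normalize_gpr(gpr_or(*combined))
                continue
            new.id = f"{rxn.id}__{rxn.origin}"
            if new.id in merged.reactions:
                raise ModelIntegrityError(
                    f"unresolvable reaction id collision for {rxn.id}"
                )
        merged.add_reaction(new)
    merged.validate()
    return merged


def edit_biomass(
    model: MetabolicModel,
    remove: set[str] | frozenset[str] = frozenset(),
    set_coefficients: Optional[dict[str, float]] = None,
) -> MetabolicModel:
    """Return a copy with the biomass stoichiometry edited.

    ``remove`` drops metabolites from the biomass reaction only (they stay in
    the rest of the model); a removal target absent from biomass is a no-op
    recorded as a warning, mirroring hand curation of biomass composition
    (e.g. dropping a nonessential membrane lipid from the demand).
    """
    import warnings

    if model.biomass_reaction_id is None:
        raise ModelIntegrityError("model has no biomass reaction")
    out = model.copy()
    biomass = out.reactions[out.biomass_reaction_id]
    for met in remove:
        if met not in biomass.stoichiometry:
            warnings.warn(
                f"biomass edit: {met} not in biomass reaction, skipped",
                stacklevel=2,
            )
            continue
        del biomass.stoichiometry[met]
    for met, coef in (set_coefficients or {}).items():
        if coef == 0:
            biomass.stoichiometry.pop(met, None)
        else:
            biomass.stoichiometry[met] = coef
    return out


def _canonical_reaction(rxn: Reaction) -> tuple:
    stoich = tuple(sorted(rxn.stoichiometry.items()))
    return (
        stoich,
        round(rxn.lower_bound, 9),
        round(rxn.upper_bound, 9),
    )


def models_equal(a: MetabolicModel, b: MetabolicModel) -> bool:
    """Canonical comparison: same reactions (stoichiometry, bounds,
    GPR truth tables) and same objective, ignoring storage order and GPR
    spelling."""
    if set(a.reactions) != set(b.reactions):
        return False
    if set(a.metabolites) != set(b.metabolites):
        return False
    for rid, ra in a.reactions.items():
        rb = b.reactions[rid]
        if _canonical_reaction(ra) != _canonical_reaction(rb):
            return False
        if not gprs_equivalent(ra.gpr, rb.gpr):
            return False
    return (
        a.biomass_reaction_id == b.biomass_reaction_id
        and (a.objective_reaction_id or a.biomass_reaction_id)
        == (b.objective_reaction_id or b.biomass_reaction_id)
    )
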