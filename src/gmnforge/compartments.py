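"""Compartment assignment for an uncompartmentalised network.

Subcellular localisation annotations (unioned over sources, none ranked)
give a gene → compartment dictionary; each reaction is then replicated once
per compartment in the union of its genes' compartments, with the replica's
metabolites re-homed to that compartment and its GPR pruned to the genes
localised there.  Connecting transport is deliberately not added — the
compartmentation is flexible by design, and implausible replicas are
removed later by duplicate screening and leak testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .gpr import substitute_genes
from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "CompartmentDictionary",
    "build_compartment_dictionary",
    "compartmentalize",
]

#: Compartment assigned when no annotation or prediction is available.
DEFAULT_COMPARTMENT = "c"


@dataclass
class CompartmentDictionary:
    """Gene → set of compartment codes; every gene has at least one."""

    entries: dict[str, set[str]] = field(default_factory=dict)

    def __getitem__(self, gene: str) -> set[str]:
        return self.entries[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries


def build_compartment_dictionary(
    annotations: Iterable[tuple[str, str, str]] | pd.DataFrame,
    allowed: set[str],
    fallback: Optional[dict[str, set[str]]] = None,
) -> CompartmentDictionary:
    """Union annotated compartments per gene, restricted to ``allowed``.

    ``annotations`` rows are (gene, compartment, source); compartments
    outside the allowed set (those not found in the draft model) are
    discarded.  A gene left empty receives its ``fallback`` prediction
    (emulating a localisation predictor); a gene still empty is assigned
    the cytosol.
    """
    if isinstance(annotations, pd.DataFrame):
        annotations = list(
            annotations[["gene_id", "compartment_code", "source"]].itertuples(index=False)
        )
    entries: dict[str, set[str]] = {}
    for gene, comp, _source in annotations:
        entries.setdefault(gene, set())
        if comp in allowed:
            entries[gene].add(comp)
    for gene, comps in (fallback or {}).items():
        entries.setdefault(gene, set())
        if not entries[gene]:
            entries[gene] |= comps & allowed
    for gene, comps in entries.items():
        if not comps:
            comps.add(DEFAULT_COMPARTMENT)
    return CompartmentDictionary(entries)


def compartmentalize(
    network: MetabolicModel,
    cdict: CompartmentDictionary,
) -> MetabolicModel:
    """Replicate each reaction per compartment of its genes' union.

    Replica ``k`` (id ``<base>.<ordinal>``, ordinals following the sorted
    compartment codes) re-homes every metabolite to compartment ``k``
    (creating compartment-specific metabolite instances named
    ``<base>_<k>``) and keeps only the genes whose compartment set contains
    ``k``; bounds are inherited from the source reaction.  A single-
    compartment reaction keeps its base id.  Gene-free reactions are placed
    in the cytosol.
    """
    missing = {g for r in network.reactions.values() for g in r.genes if g not in cdict}
    if missing:
        raise KeyError(f"compartment dictionary missing genes: {sorted(missing)[:10]}")

    out = MetabolicModel(id=f"{network.id}_compartmentalized")

    def rehome(met_id: str, comp: str) -> str:
        src = network.metabolites[met_id]
        base = met_id
        for suffix in (f"_{src.compartment}",):
            if base.endswith(suffix):
                base = base[: -len(suffix)]
        new_id = f"{base}_{comp}"
        if new_id not in out.metabolites:
            m = src.copy()
            m.id = new_id
            m.compartment = comp
            out.add_metabolite(m)
        return new_id

    used_comps: set[str] = set()
    for rid in sorted(network.reactions):
        rxn = network.reactions[rid]
        genes = sorted(rxn.genes)
        comps = sorted(set().union(*(cdict[g] for g in genes))) if genes else [DEFAULT_COMPARTMENT]
        used_comps.update(comps)
        for ordinal, comp in enumerate(comps, start=1):
            replica = rxn.copy()
            replica.id = rid if len(comps) == 1 else f"{rid}.{ordinal}"
            replica.stoichiometry = {
                rehome(m, comp): c for m, c in rxn.stoichiometry.items()
            }
            if genes:
                kept = {g for g in genes if comp in cdict[g]}
                replica.gpr = substitute_genes(
                    rxn.gpr, {g: None for g in genes if g not in kept}
                )
            out.add_reaction(replica)
    out.compartments = {c: c for c in sorted(used_comps)}
    out.validate()
    return out
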