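"""Reaction-, metabolite- and gene-centric model cleanup.

Synonymous metabolites (the same compound under two names, typically after
merging networks from different sources) are detected by matching
identifier dictionaries — normalised compound names plus external database
identifiers (KEGG, ChEBI at curation rank 3 only, PubChem, LIPID MAPS) —
using three criteria applied in order:

1. two metabolites share at least one identifier and share none with any
   third metabolite → synonyms;
2. among three or more metabolites with common identifiers, the pair with
   the maximum number of matched identifiers → synonyms;
3. more than one pair tied at the maximum → flagged as ambiguous for
   manual review, never auto-merged.

Duplicate reactions are found on a canonical form that ignores the
currency metabolites H+, H2O and Pi, optionally ignores compartments, and
treats a reaction and its exact reverse as equal; merging keeps one
survivor per group with the OR-combined GPR so that no gene is lost.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .gpr import gpr_or, normalize_gpr
from .model import MetabolicModel, Reaction

__all__ = [
    "IdentifierDictionary",
    "SynonymReport",
    "normalize_name",
    "build_identifier_dictionary",
    "read_xref_table",
    "find_synonyms",
    "apply_synonym_merge",
    "find_duplicate_reactions",
    "merge_duplicates",
    "remove_trivial",
]

logger = logging.getLogger(__name__)

_GREEK = {"α": "alpha", "β": "beta", "γ": "gamma", "Α": "alpha", "Β": "beta", "Γ": "gamma"}
_PUNCT_RE = re.compile(r"[-\s,'()\[\]]")

#: Metabolite base names treated as currency compounds in duplicate
#: screening (matched per compartment, case-insensitively).
CURRENCY_NAMES = frozenset({"h", "h+", "proton", "h2o", "water", "pi", "phosphate"})

#: Survivor preference by provenance when merging duplicate groups.
ORIGIN_PRIORITY = ("template", "manual", "gapfill", "kegg_metacyc")


def normalize_name(name: str) -> str:
    """Case-fold, strip punctuation/whitespace, canonicalise greek letters."""
    out = name
    for greek, latin in _GREEK.items():
        out = out.replace(greek, latin)
    return _PUNCT_RE.sub("", out).casefold()


@dataclass
class IdentifierDictionary:
    """Per metabolite id: the set of namespace-tagged identifiers used for
    synonym matching (normalised names and external IDs)."""

    identifiers: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    compartments: dict[str, str] = field(default_factory=dict)


def read_xref_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "star_rank" in df.columns:
        df["star_rank"] = pd.to_numeric(df["star_rank"]).fillna(0).astype(int)
    return df


def build_identifier_dictionary(
    model: MetabolicModel,
    xrefs: Optional[pd.DataFrame] = None,
    use_names: bool = True,
) -> IdentifierDictionary:
    """Build the matching dictionary for a model's metabolites.

    External identifiers come from the metabolites' own ``xrefs`` plus an
    optional cross-reference table (columns ``metabolite_id``,
    ``namespace``, ``external_id``, optional ``star_rank``).  ChEBI entries
    from the table are kept only at star rank 3 (the manually curated
    tier); normalised display names and synonyms participate when
    ``use_names``.
    """
    d = IdentifierDictionary()
    for met in model.metabolites.values():
        ids: set[tuple[str, str]] = set()
        if use_names and met.name:
            ids.add(("name", normalize_name(met.name)))
        if use_names:
            ids.update(("name", normalize_name(s)) for s in met.synonyms)
        for ns, vals in met.xrefs.items():
            ids.update((ns, v) for v in vals)
        d.identifiers[met.id] = ids
        d.compartments[met.id] = met.compartment
    if xrefs is not None:
        for row in xrefs.itertuples(index=False):
            if row.metabolite_id not in d.identifiers:
                continue
            if row.namespace == "chebi" and getattr(row, "star_rank", 3) not in (0, 3):
                continue
            d.identifiers[row.metabolite_id].add((row.namespace, str(row.external_id)))
    return d


@dataclass
class SynonymReport:
    """Outcome of synonym detection.

    ``merged`` lists (kept id, removed id, shared-identifier count);
    ``ambiguous`` lists candidate groups with tied counts, for manual
    review.
    """

    merged: list[tuple[str, str, int]] = field(default_factory=list)
    ambiguous: list[frozenset[str]] = field(default_factory=list)

    def merged_pairs(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b, _ in self.merged}


def _pair_counts(
    dict_a: IdentifierDictionary,
    dict_b: IdentifierDictionary,
    within: bool,
) -> dict[frozenset[str], int]:
    """Shared-identifier counts for candidate pairs.

    Within-model mode pairs distinct metabolites of one dictionary, never
    across compartments; across-model mode pairs one metabolite from each.
    """
    index: dict[tuple[str, str], set[str]] = {}
    for mid, ids in dict_a.identifiers.items():
        for ident in ids:
            index.setdefault(ident, set()).add(mid)
    counts: dict[frozenset[str], int] = {}
    if within:
        for ident, members in index.items():
            for a in members:
                for b in members:
                    if a < b and dict_a.compartments[a] == dict_a.compartments[b]:
                        counts[frozenset((a, b))] = counts.get(frozenset((a, b)), 0) + 1
    else:
        for mid_b, ids_b in dict_b.identifiers.items():
            for ident in ids_b:
                for mid_a in index.get(ident, ()):
                    key = frozenset((mid_a, mid_b))
                    counts[key] = counts.get(key, 0) + 1
    return counts


def find_synonyms(
    dict_a: IdentifierDictionary,
    dict_b: Optional[IdentifierDictionary] = None,
) -> SynonymReport:
    """Classify candidate synonym pairs by the three matching criteria.

    Passing a single dictionary runs within-model detection; passing two
    runs across-model detection (metabolite of A vs metabolite of B).  In
    a connected group the unique maximum-count pair is merged and the
    remaining members re-examined iteratively; a tie at the maximum flags
    the tied metabolites as one ambiguous group and stops the group.
    """
    within = dict_b is None
    counts = _pair_counts(dict_a, dict_b or dict_a, within)
    report = SynonymReport()

    # connected components over the "shares >=1 identifier" graph
    adjacency: dict[str, set[str]] = {}
    for pair in counts:
        a, b = sorted(pair)
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)

    unvisited = set(adjacency)
    while unvisited:
        seed_node = min(unvisited)
        component = {seed_node}
        stack = [seed_node]
        while stack:
            for nb in adjacency[stack.pop()]:
                if nb not in component:
                    component.add(nb)
                    stack.append(nb)
        unvisited -= component

        remaining = set(component)
        while True:
            live = {
                p: c for p, c in counts.items() if p <= remaining
            }
            if not live:
                break
            best = max(live.values())
            top = sorted(p for p, c in live.items() if c == best)
            if len(top) > 1:
                report.ambiguous.append(frozenset().union(*top))
                break
            kept, removed = sorted(top[0])
            report.merged.append((kept, removed, best))
            remaining -= {kept, removed}
    return report


def apply_synonym_merge(
    model: MetabolicModel,
    report: SynonymReport,
    mode: str = "within",
) -> MetabolicModel:
    """Apply merged pairs to a model.

    ``within``: occurrences of the removed id are rewritten to the kept id,
    coefficients summed where both appear in one reaction (zero-sum terms
    dropped), and the removed metabolite deleted; a reaction emptied by the
    merge is removed with a log entry.  ``across``: the removed-side
    metabolite is renamed to the kept id/name only (applied to the second
    model before merging networks).
    """
    out = model.copy()
    rename = {removed: kept for kept, removed, _ in report.merged}
    if mode == "across":
        for removed, kept in rename.items():
            if removed not in out.metabolites:
                continue
            met = out.metabolites.pop(removed)
            met.id = kept
            met.name = kept if kept not in model.metabolites else model.metabolites[kept].name
            out.metabolites[kept] = met
            for rxn in out.reactions.values():
                if removed in rxn.stoichiometry:
                    rxn.stoichiometry[kept] = rxn.stoichiometry.pop(removed)
        return out

    for rxn in list(out.reactions.values()):
        if not set(rxn.stoichiometry) & set(rename):
            continue
        new_stoich: dict[str, float] = {}
        for met, coef in rxn.stoichiometry.items():
            target = rename.get(met, met)
            new_stoich[target] = new_stoich.get(target, 0.0) + coef
        new_stoich = {m: c for m, c in new_stoich.items() if c != 0}
        if not new_stoich:
            logger.warning(
                "reaction %s emptied by synonym merge; removed", rxn.id
            )
            del out.reactions[rxn.id]
            continue
        rxn.stoichiometry = new_stoich
    for removed in rename:
        out.metabolites.pop(removed, None)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Duplicate reactions
# ---------------------------------------------------------------------------

def _is_currency(model: MetabolicModel, met_id: str) -> bool:
    met = model.metabolites[met_id]
    base = met_id
    if base.endswith(f"_{met.compartment}"):
        base = base[: -len(met.compartment) - 1]
    return (
        base.casefold() in CURRENCY_NAMES
        or normalize_name(met.name) in {normalize_name(n) for n in CURRENCY_NAMES}
    )


def _canonical_form(
    model: MetabolicModel, rxn: Reaction, ignore_compartments: bool
) -> tuple:
    terms = []
    for met, coef in rxn.stoichiometry.items():
        if _is_currency(model, met):
            continue
        key = met
        if ignore_compartments:
            comp = model.metabolites[met].compartment
            if key.endswith(f"_{comp}"):
                key = key[: -len(comp) - 1]
        terms.append((key, coef))
    if not terms:
        return ()
    forward = tuple(sorted(terms))
    reverse = tuple(sorted((m, -c) for m, c in terms))
    return min(forward, reverse)


def find_duplicate_reactions(
    model: MetabolicModel,
    ignore_compartments: bool = False,
) -> list[list[str]]:
    """Groups (≥2) of reactions equal under the canonical form.

    The canonical form drops H+/H2O/Pi terms, strips compartments from
    metabolite keys when ``ignore_compartments``, and identifies a reaction
    with its exact reverse.  Exchange reactions are never grouped (distinct
    exchanges for distinct species remain distinct by construction).
    """
    by_form: dict[tuple, list[str]] = {}
    for rid in sorted(model.reactions):
        form = _canonical_form(model, model.reactions[rid], ignore_compartments)
        if form == ():
            continue
        by_form.setdefault(form, []).append(rid)
    return [grp for grp in by_form.values() if len(grp) >= 2]


def merge_duplicates(
    model: MetabolicModel,
    groups: list[list[str]],
    keep_policy: tuple[str, ...] = ORIGIN_PRIORITY,
) -> MetabolicModel:
    """Keep one survivor per duplicate group, losing no gene.

    The survivor is chosen by provenance priority (template-derived
    preferred over database-derived), ties broken lexicographically; its
    GPR becomes the normalised OR over the group's rules and its bounds the
    widest interval in the group.  A post-merge check asserts the model's
    gene set is unchanged.
    """
    genes_before = model.genes
    out = model.copy()
    priority = {origin: i for i, origin in enumerate(keep_policy)}
    for group in groups:
        members = [out.reactions[r] for r in group if r in out.reactions]
        if len(members) < 2:
            continue
        survivor = min(
            members, key=lambda r: (priority.get(r.origin, len(priority)), r.id)
        )
        rules = [r.gpr for r in members if r.gpr is not None]
        if rules:
            survivor.gpr = normalize_gpr(gpr_or(*rules)) if len(rules) > 1 else normalize_gpr(rules[0])
        survivor.lower_bound = min(r.lower_bound for r in members)
        survivor.upper_bound = max(r.upper_bound for r in members)
        for r in members:
            if r.id != survivor.id:
                del out.reactions[r.id]
    lost = genes_before - out.genes
    if lost:
        raise RuntimeError(f"gene loss during duplicate merge: {sorted(lost)}")
    return out


def remove_trivial(model: MetabolicModel) -> MetabolicModel:
    """Drop metabolites used by no reaction and reactions with empty
    stoichiometry, iterating to a fixpoint."""
    out = model.copy()
    changed = True
    while changed:
        changed = False
        for rid, rxn in list(out.reactions.items()):
            if not rxn.stoichiometry:
                del out.reactions[rid]
                changed = True
        used = {m for r in out.reactions.values() for m in r.stoichiometry}
        for mid in list(out.metabolites):
            if mid not in used:
                del out.metabolites[mid]
                changed = True
    return out
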