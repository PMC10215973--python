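"""Orthology-based GPR transfer.

Translates a template model's GPR rules into target-organism rules using an
orthology table with per-pair DIOPT confidence scores (the number of
prediction tools supporting the pair, 3–15 in practice).  Filtering keeps,
per source gene, only the target(s) tied at the maximum score; a source
gene with more than nine surviving targets is considered unspecific — its
gene association is dropped, but the reaction is kept because the orthology
evidence shows the reaction exists in the target organism.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import pandas as pd

from .gpr import GprTree, gene_leaf, gpr_or, substitute_genes
from .model import MetabolicModel

__all__ = [
    "NO_ORTHOLOG",
    "DROPPED_BUT_EVIDENCED",
    "OrthologyTable",
    "read_orthology_table",
    "filter_orthologs",
    "translate_gprs",
]

#: Sentinel: the source gene has no target-organism ortholog at all.
NO_ORTHOLOG = "NO-ORTHOLOG"
#: Sentinel: orthologs exist but the association is too unspecific (>9
#: targets at the maximum score); the gene is dropped, the reaction kept.
DROPPED_BUT_EVIDENCED = "DROPPED-BUT-EVIDENCED"

#: Keep at most this many tied top-score orthologs; beyond it the
#: association is unspecific ("over nine" read strictly: 9 kept is legal).
MAX_ORTHOLOGS = 9


@dataclass
class OrthologyTable:
    """Records of (source gene, target gene, DIOPT score)."""

    records: pd.DataFrame  # columns: human_gene_id, fly_gene_id, diopt_score

    def __post_init__(self) -> None:
        required = {"human_gene_id", "fly_gene_id", "diopt_score"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"orthology table missing columns: {sorted(missing)}")
        dup = self.records.duplicated(["human_gene_id", "fly_gene_id"])
        if dup.any():
            pairs = self.records.loc[dup, ["human_gene_id", "fly_gene_id"]]
            raise ValueError(f"duplicate (source, target) pairs: {pairs.values[:5].tolist()}")
        if (self.records["diopt_score"] < 1).any():
            raise ValueError("DIOPT scores must be >= 1")


def read_orthology_table(path: Union[str, Path]) -> OrthologyTable:
    df = pd.read_csv(path, sep="\t")
    return OrthologyTable(df)


def filter_orthologs(
    table: OrthologyTable,
    source_genes: set[str] | None = None,
) -> dict[str, Union[set[str], str]]:
    """Per source gene: the max-score target set, or a sentinel.

    Keeps only targets tied at the maximum DIOPT score; maps the gene to
    :data:`DROPPED_BUT_EVIDENCED` when more than nine survive, and to
    :data:`NO_ORTHOLOG` when the gene is absent from the table (sources
    outside ``source_genes``, if given, are still mapped from the table).
    """
    mapping: dict[str, Union[set[str], str]] = {}
    for src, grp in table.records.groupby("human_gene_id"):
        best = grp["diopt_score"].max()
        kept = set(grp.loc[grp["diopt_score"] == best, "fly_gene_id"])
        mapping[str(src)] = DROPPED_BUT_EVIDENCED if len(kept) > MAX_ORTHOLOGS else kept
    for gene in source_genes or set():
        mapping.setdefault(gene, NO_ORTHOLOG)
    return mapping


def translate_gprs(
    model: MetabolicModel,
    mapping: dict[str, Union[set[str], str]],
) -> tuple[MetabolicModel, pd.DataFrame]:
    """Rewrite every GPR through the ortholog mapping; return the draft
    model and a per-gene disposition report.

    Leaf semantics: one ortholog substitutes directly; k orthologs become
    an OR over the k targets; a :data:`DROPPED_BUT_EVIDENCED` or
    :data:`NO_ORTHOLOG` leaf is deleted from its tree (an AND node losing a
    child keeps the remaining children — evidence without specificity must
    not over-constrain).  A reaction whose every leaf resolves to
    :data:`NO_ORTHOLOG` is removed; non-enzymatic reactions are kept
    unchanged.  Trees are normalised afterwards, collapsing the duplicate
    siblings that shared orthologs create.
    """
    missing = {
        g
        for r in model.reactions.values()
        for g in r.genes
        if g not in mapping
    }
    if missing:
        raise KeyError(
            f"orthology mapping does not cover {len(missing)} GPR gene(s): "
            f"{sorted(missing)[:10]}"
        )

    replacements: dict[str, GprTree | None] = {}
    rows = []
    for gene, target in sorted(mapping.items()):
        if target == NO_ORTHOLOG:
            replacements[gene] = None
            rows.append((gene, "no_ortholog", ""))
        elif target == DROPPED_BUT_EVIDENCED:
            replacements[gene] = None
            rows.append((gene, "dropped_unspecific", ""))
        else:
            targets = sorted(target)  # type: ignore[arg-type]
            replacements[gene] = (
                gene_leaf(targets[0])
                if len(targets) == 1
                else gpr_or(*(gene_leaf(t) for t in targets))
            )
            rows.append((gene, "mapped", ";".join(targets)))

    out = model.copy()
    out.id = f"{model.id}_draft"
    removed = []
    for rid, rxn in list(out.reactions.items()):
        if rxn.gpr is None:
            continue  # non-enzymatic: retained unchanged
        genes = rxn.genes
        if genes and all(mapping[g] == NO_ORTHOLOG for g in genes):
            removed.append(rid)
            del out.reactions[rid]
            continue
        rxn.gpr = substitute_genes(rxn.gpr, replacements)
    report = pd.DataFrame(rows, columns=["source_gene", "disposition", "targets"])
    report.attrs["removed_reactions"] = removed
    return out, report
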