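"""Boolean gene-protein-reaction (GPR) rule algebra.

A GPR rule is a boolean expression over gene identifiers that states which
gene products enable a reaction: AND nodes encode enzyme complexes (every
subunit required), OR nodes encode isozymes (any one suffices).  An absent
rule (``None``) marks a non-enzymatic / spontaneous reaction, which is
always considered active.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = [
    "GprTree",
    "gene_leaf",
    "gpr_and",
    "gpr_or",
    "parse_gpr",
    "evaluate_gpr",
    "normalize_gpr",
    "gpr_genes",
    "gpr_to_string",
    "gprs_equivalent",
    "substitute_genes",
]


@dataclass(frozen=True)
class GprTree:
    """A node of a GPR expression tree.

    ``kind`` is one of ``"gene"``, ``"and"``, ``"or"``.  GENE leaves carry
    the gene identifier; AND/OR nodes carry a non-empty tuple of children.
    """

    kind: str
    gene: Optional[str] = None
    children: tuple["GprTree", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind == "gene":
            if not self.gene:
                raise ValueError("GENE leaf requires a gene identifier")
        elif self.kind in ("and", "or"):
            if len(self.children) < 1:
                raise ValueError(f"{self.kind.upper()} node requires >=1 child")
        else:
            raise ValueError(f"unknown GPR node kind: {self.kind!r}")


def gene_leaf(gene: str) -> GprTree:
    return GprTree("gene", gene=gene)


def gpr_and(*children: GprTree) -> GprTree:
    return GprTree("and", children=tuple(children))


def gpr_or(*children: GprTree) -> GprTree:
    return GprTree("or", children=tuple(children))


# ---------------------------------------------------------------------------
# Parsing / printing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(rule: str) -> Optional[GprTree]:
    """Parse a textual GPR rule into a tree.

    Accepts ``and``/``or`` keywords case-insensitively, arbitrary
    parenthesisation, and ``&``/``|`` as synonyms.  An empty or
    whitespace-only string parses to ``None`` (non-enzymatic reaction).
    ``or`` binds looser than ``and``, as in every constraint-based modelling
    toolkit.
    """
    tokens = _TOKEN_RE.findall(rule or "")
    if not tokens:
        return None
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def is_op(tok: Optional[str], name: str) -> bool:
        if tok is None:
            return False
        low = tok.lower()
        return low == name or (name == "and" and tok == "&") or (
            name == "or" and tok == "|"
        )

    def parse_atom() -> GprTree:
        tok = peek()
        if tok is None:
            raise ValueError(f"unexpected end of GPR rule: {rule!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise ValueError(f"unbalanced parentheses in GPR rule: {rule!r}")
            take()
            return node
        if tok == ")" or is_op(tok, "and") or is_op(tok, "or"):
            raise ValueError(f"misplaced token {tok!r} in GPR rule: {rule!r}")
        return gene_leaf(take())

    def parse_and() -> GprTree:
        parts = [parse_atom()]
        while is_op(peek(), "and"):
            take()
            parts.append(parse_atom())
        return parts[0] if len(parts) == 1 else GprTree("and", children=tuple(parts))

    def parse_or() -> GprTree:
        parts = [parse_and()]
        while is_op(peek(), "or"):
            take()
            parts.append(parse_and())
        return parts[0] if len(parts) == 1 else GprTree("or", children=tuple(parts))

    tree = parse_or()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in GPR rule: {rule!r}")
    return tree


def gpr_to_string(gpr: Optional[GprTree]) -> str:
    """Render a tree back to the conventional ``(a and b) or c`` syntax."""
    if gpr is None:
        return ""
    if gpr.kind == "gene":
        return gpr.gene  # type: ignore[return-value]
    op = f" {gpr.kind} "
    parts = []
    for child in gpr.children:
        text = gpr_to_string(child)
        if child.kind != "gene" and child.kind != gpr.kind:
            text = f"({text})"
        elif child.kind == gpr.kind:
            text = f"({text})"
        parts.append(text)
    return op.join(parts)


# ---------------------------------------------------------------------------
# Evaluation and normalisation
# ---------------------------------------------------------------------------

def evaluate_gpr(gpr: Optional[GprTree], knocked_out: set[str] | frozenset[str] = frozenset()) -> bool:
    """Truth value of a rule with ``knocked_out`` genes false, others true.

    Genes absent from the tree are irrelevant; an empty rule is true (the
    reaction is not gene-controlled and survives any knockout).
    """
    if gpr is None:
        return True
    if gpr.kind == "gene":
        return gpr.gene not in knocked_out
    if gpr.kind == "and":
        return all(evaluate_gpr(c, knocked_out) for c in gpr.children)
    return any(evaluate_gpr(c, knocked_out) for c in gpr.children)


def gpr_genes(gpr: Optional[GprTree]) -> set[str]:
    """The set of gene identifiers appearing as leaves."""
    if gpr is None:
        return set()
    if gpr.kind == "gene":
        return {gpr.gene}  # type: ignore[arg-type]
    out: set[str] = set()
    for child in gpr.children:
        out |= gpr_genes(child)
    return out


def _iter_flat(gpr: GprTree, kind: str) -> Iterator[GprTree]:
    for child in gpr.children:
        if child.kind == kind:
            yield from _iter_flat(child, kind)
        else:
            yield child


def normalize_gpr(gpr: Optional[GprTree]) -> Optional[GprTree]:
    """Canonicalise a tree: flatten nested same-kind nodes, drop duplicate
    siblings, collapse single-child nodes, and sort siblings by their
    printed form so equal rules have equal trees."""
    if gpr is None:
        return None
    if gpr.kind == "gene":
        return gpr
    flat = [normalize_gpr(c) for c in _iter_flat(gpr, gpr.kind)]
    seen: dict[str, GprTree] = {}
    for child in flat:
        assert child is not None
        key = gpr_to_string(child)
        if key not in seen:
            seen[key] = child
    children = tuple(seen[k] for k in sorted(seen))
    if len(children) == 1:
        return children[0]
    return GprTree(gpr.kind, children=children)


def gprs_equivalent(a: Optional[GprTree], b: Optional[GprTree]) -> bool:
    """Logical equivalence via truth tables over the union gene set.

    Intended for small rules (the exhaustive table is 2^n assignments);
    model GPRs in this package stay well below that limit.
    """
    genes = sorted(gpr_genes(a) | gpr_genes(b))
    if len(genes) > 20:
        raise ValueError("truth-table comparison limited to 20 genes")
    for mask in range(2 ** len(genes)):
        ko = {g for i, g in enumerate(genes) if not (mask >> i) & 1}
        if evaluate_gpr(a, ko) != evaluate_gpr(b, ko):
            return False
    return True


def substitute_genes(
    gpr: Optional[GprTree],
    replacements: dict[str, Optional[GprTree]],
) -> Optional[GprTree]:
    """Replace GENE leaves by subtrees (or delete them with ``None``).

    Deletion semantics: a leaf mapped to ``None`` is removed from its parent;
    an AND/OR node losing all children collapses to ``None`` (treated as
    satisfied), so a rule whose every gene is deleted becomes the empty rule.
    Leaves absent from ``replacements`` are kept as-is.  The result is
    normalised.
    """
    def rec(node: GprTree) -> Optional[GprTree]:
        if node.kind == "gene":
            if node.gene in replacements:
                return replacements[node.gene]  # may be None (delete)
            return node
        kids = [rec(c) for c in node.children]
        kept = tuple(k for k in kids if k is not None)
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        return GprTree(node.kind, children=kept)

    if gpr is None:
        return None
    return normalize_gpr(rec(gpr))
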