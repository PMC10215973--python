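"""Seeded generators for every input the reconstruction pipeline consumes.

Each generator is a pure function of its parameters and a seed, and returns
the fixture together with a :class:`SyntheticTruth` recording the planted
ground truth (essential genes, synonym pairs, energy-leak reaction pairs,
regulated reaction directions, ambiguous orthology cases), so every
downstream pipeline stage has a recoverable answer.

The template model emulates a curated, compartmentalised metabolic network
of a sterol auxotroph: linear biosynthetic pathways distributed over
compartments feed a biomass reaction, respiration is the sole ATP source, a
non-growth-associated maintenance (NGAM) reaction drains 8.55 mmol ATP
gDW⁻¹ h⁻¹, and a sterol-derived biomass precursor can only be made from
dietary sterol (the auxotrophy branch).  GPR rules mix single genes,
AND-complexes and OR-isozymes so that gene essentiality is known by
construction: a gene is essential iff it is required by the sole unblocked
route to some biomass precursor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .gpr import gene_leaf, gpr_and, gpr_or, GprTree
from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction

__all__ = [
    "SyntheticTruth",
    "make_template_model",
    "make_leaky_model",
    "make_gapfill_fixture",
    "make_orthology_table",
    "make_synonym_fixture",
    "make_second_network",
    "make_expression_dataset",
    "generate_all",
]

#: NGAM flux fixed in the template (mmol ATP gDW⁻¹ h⁻¹).
NGAM_FLUX = 8.55
#: Maximum carbon (glucose-like) uptake in the template's rich medium.
GLC_UPTAKE = 10.0
#: ATP stoichiometry of the biomass reaction (growth-associated maintenance).
BIOMASS_ATP = 20.0
#: ATP yield per unit carbon in the lumped respiration reaction.
RESP_ATP_YIELD = 10.0

_COMPARTMENTS = ["c", "m", "p", "r", "g", "l", "n"]


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated fixture set."""

    essential_genes: set[str] = field(default_factory=set)
    nonessential_genes: set[str] = field(default_factory=set)
    blocked_only_genes: set[str] = field(default_factory=set)
    synonym_pairs: set[tuple[str, str]] = field(default_factory=set)
    ambiguous_synonym_groups: list[frozenset[str]] = field(default_factory=list)
    leak_reactions: set[tuple[str, str]] = field(default_factory=set)
    regulated_reactions: dict[str, str] = field(default_factory=dict)
    orthology_ambiguities: set[str] = field(default_factory=set)
    no_ortholog_genes: set[str] = field(default_factory=set)
    ortholog_map: dict[str, set[str]] = field(default_factory=dict)
    unproducible_precursors: set[str] = field(default_factory=set)
    removed_reactions: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# Template model
# ---------------------------------------------------------------------------

def _add_species(model: MetabolicModel, base: str, comp: str, name: str = "") -> str:
    mid = f"{base}_{comp}"
    if mid not in model.metabolites:
        model.add_metabolite(Metabolite(mid, name=name or base, compartment=comp))
    return mid


def _exchange(model: MetabolicModel, base: str, uptake: float) -> str:
    """Add exchange for an extracellular species; negative lb = uptake."""
    mid = _add_species(model, base, "s")
    rid = f"EX_{base}"
    model.add_reaction(
        Reaction(rid, name=f"{base} exchange", stoichiometry={mid: -1.0},
                 lower_bound=-uptake, upper_bound=DEFAULT_BOUND)
    )
    return rid


def _transport(model: MetabolicModel, base: str, c_from: str, c_to: str,
               gpr: Optional[GprTree] = None, reversible: bool = False) -> str:
    src = _add_species(model, base, c_from)
    dst = _add_species(model, base, c_to)
    rid = f"T_{base}_{c_from}{c_to}"
    model.add_reaction(
        Reaction(rid, name=f"{base} transport {c_from}->{c_to}",
                 stoichiometry={src: -1.0, dst: 1.0},
                 lower_bound=-DEFAULT_BOUND if reversible else 0.0,
                 upper_bound=DEFAULT_BOUND, gpr=gpr, subsystem="transport")
    )
    return rid


def _gpr_pattern(rng: np.random.Generator, tag: str, truth: SyntheticTruth) -> GprTree:
    """Draw a GPR shape for an essential pathway step and record truth.

    The step is on the sole route to a biomass precursor, so: a lone gene
    is essential; every AND subunit is essential; OR isozymes are not.
    """
    kind = rng.integers(0, 4)
    g = lambda suffix: f"g_{tag}{suffix}"
    if kind == 0:
        truth.essential_genes.add(g("a"))
        return gene_leaf(g("a"))
    if kind == 1:
        truth.essential_genes.update({g("a"), g("b")})
        return gpr_and(gene_leaf(g("a")), gene_leaf(g("b")))
    if kind == 2:
        truth.nonessential_genes.update({g("a"), g("b")})
        return gpr_or(gene_leaf(g("a")), gene_leaf(g("b")))
    truth.nonessential_genes.update({g("a"), g("b"), g("c")})
    return gpr_or(gpr_and(gene_leaf(g("a")), gene_leaf(g("b"))), gene_leaf(g("c")))


def make_template_model(
    n_pathways: int = 4,
    n_compartments: int = 3,
    seed: int = 7,
) -> tuple[MetabolicModel, SyntheticTruth]:
    """Generate the compartmentalised template model with planted truth.

    The model grows on a rich medium (carbon capped at 10 mmol gDW⁻¹ h⁻¹,
    everything else effectively unlimited); each of ``n_pathways`` linear
    biosynthetic chains makes one biomass precursor in a compartment cycled
    from the declared set, with the chain's GPR shapes drawn from the seed.
    """
    if not 2 <= n_compartments <= 8:
        raise ValueError("n_compartments must be in [2, 8]")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()
    comps = _COMPARTMENTS[:n_compartments]
    model = MetabolicModel(id=f"synthetic_template_s{seed}")
    model.compartments = {c: c for c in comps}
    model.compartments["s"] = "extracellular"

    # Medium and transport
    _exchange(model, "glc", GLC_UPTAKE)
    _exchange(model, "o2", DEFAULT_BOUND)
    _exchange(model, "nh4", DEFAULT_BOUND)
    _exchange(model, "sterol", DEFAULT_BOUND)
    _exchange(model, "asp", DEFAULT_BOUND)
    for base in ("glc", "o2", "nh4", "sterol", "asp"):
        _transport(model, base, "s", "c")
    # CO2 leaves freely
    _add_species(model, "co2", "c")
    _transport(model, "co2", "c", "s")
    model.add_reaction(
        Reaction("EX_co2", name="co2 exchange",
                 stoichiometry={_add_species(model, "co2", "s"): -1.0},
                 lower_bound=0.0, upper_bound=DEFAULT_BOUND)
    )

    # Energy metabolism: lumped aerobic respiration, the sole ATP source.
    for base in ("atp", "adp", "pi"):
        _add_species(model, base, "c")
    truth.essential_genes.update({"g_respa", "g_respb"})
    model.add_reaction(
        Reaction(
            "RESP",
            name="lumped aerobic respiration",
            stoichiometry={
                "glc_c": -1.0, "o2_c": -1.0,
                "adp_c": -RESP_ATP_YIELD, "pi_c": -RESP_ATP_YIELD,
                "atp_c": RESP_ATP_YIELD, "co2_c": 1.0,
            },
            gpr=gpr_and(gene_leaf("g_respa"), gene_leaf("g_respb")),
            subsystem="energy metabolism",
        )
    )
    model.add_reaction(
        Reaction("NGAM", name="non-growth-associated maintenance",
                 stoichiometry={"atp_c": -1.0, "adp_c": 1.0, "pi_c": 1.0},
                 lower_bound=NGAM_FLUX, upper_bound=NGAM_FLUX,
                 subsystem="maintenance")
    )
    model.ngam_reaction_id = "NGAM"

    biomass_stoich: dict[str, float] = {
        "atp_c": -BIOMASS_ATP, "adp_c": BIOMASS_ATP, "pi_c": BIOMASS_ATP,
    }

    # Sterol auxotrophy branch: the precursor is producible only from
    # dietary sterol (no de novo route), via a single essential gene.
    _add_species(model, "prec_ster", "c")
    truth.essential_genes.add("g_ster")
    model.add_reaction(
        Reaction("STER_SYN", name="sterol activation",
                 stoichiometry={"sterol_c": -1.0, "atp_c": -1.0,
                                "prec_ster_c": 1.0, "adp_c": 1.0, "pi_c": 1.0},
                 gpr=gene_leaf("g_ster"), subsystem="sterol metabolism")
    )
    biomass_stoich["prec_ster_c"] = -1.0

    # Aspartate-like branch: dietary uptake OR de novo synthesis.  The
    # synthesis refixes respiratory CO2 with unlimited nitrogen, so it does
    # not compete for the limiting carbon and depleting the dietary supply
    # leaves growth unchanged.
    _add_species(model, "prec_asp", "c")
    truth.nonessential_genes.add("g_aspsyn")
    model.add_reaction(
        Reaction("ASP_SYN", name="aspartate-like synthesis",
                 stoichiometry={"co2_c": -1.0, "nh4_c": -1.0, "asp_c": 1.0},
                 gpr=gene_leaf("g_aspsyn"), subsystem="amino acid metabolism")
    )
    truth.nonessential_genes.update({"g_aspua", "g_aspub"})
    model.add_reaction(
        Reaction("ASP_USE", name="aspartate-like incorporation",
                 stoichiometry={"asp_c": -1.0, "atp_c": -1.0,
                                "prec_asp_c": 1.0, "adp_c": 1.0, "pi_c": 1.0},
                 gpr=gpr_or(gene_leaf("g_aspua"), gene_leaf("g_aspub")),
                 subsystem="amino acid metabolism")
    )
    biomass_stoich["prec_asp_c"] = -1.0

    # Biosynthetic pathways, one biomass precursor each, distributed over
    # compartments; non-enzymatic transporters shuttle intermediates.
    for i in range(1, n_pathways + 1):
        comp = comps[i % len(comps)]
        tag = f"p{i}"
        a_c = _add_species(model, f"a{i}", "c")
        model.add_reaction(
            Reaction(f"{tag.upper()}_S1", name=f"pathway {i} step 1",
                     stoichiometry={"glc_c": -1.0, a_c: 1.0},
                     gpr=_gpr_pattern(rng, f"{tag}s1", truth),
                     subsystem=f"pathway {i}")
        )
        if comp != "c":
            _transport(model, f"a{i}", "c", comp)
        a_k = _add_species(model, f"a{i}", comp)
        b_k = _add_species(model, f"b{i}", comp)
        model.add_reaction(
            Reaction(f"{tag.upper()}_S2", name=f"pathway {i} step 2",
                     stoichiometry={a_k: -1.0, b_k: 1.0},
                     gpr=_gpr_pattern(rng, f"{tag}s2", truth),
                     subsystem=f"pathway {i}")
        )
        prec_k = _add_species(model, f"prec{i}", comp)
        model.add_reaction(
            Reaction(f"{tag.upper()}_S3", name=f"pathway {i} step 3",
                     stoichiometry={b_k: -1.0, prec_k: 1.0},
                     gpr=_gpr_pattern(rng, f"{tag}s3", truth),
                     subsystem=f"pathway {i}")
        )
        if comp != "c":
            _transport(model, f"prec{i}", comp, "c")
        biomass_stoich[f"prec{i}_c"] = -1.0

    # A structurally blocked reaction whose gene must be excluded from
    # essentiality calls (it cannot affect biomass formation).
    _add_species(model, "orphan_sub", "c")
    _add_species(model, "orphan_prod", "c")
    truth.blocked_only_genes.add("g_blk")
    model.add_reaction(
        Reaction("BLOCKED_RXN", name="dead-end conversion",
                 stoichiometry={"orphan_sub_c": -1.0, "orphan_prod_c": 1.0},
                 gpr=gene_leaf("g_blk"), subsystem="orphan")
    )

    _add_species(model, "biomass", "c")
    biomass_stoich["biomass_c"] = 1.0
    model.add_reaction(
        Reaction("BIOMASS", name="biomass formation",
                 stoichiometry=biomass_stoich, subsystem="biomass")
    )
    model.add_reaction(
        Reaction("DM_biomass", name="biomass drain",
                 stoichiometry={"biomass_c": -1.0}, upper_bound=DEFAULT_BOUND)
    )
    model.biomass_reaction_id = "BIOMASS"
    model.objective_reaction_id = "BIOMASS"
    model.validate()
    return model, truth


def make_leaky_model(seed: int = 7, **kwargs) -> tuple[MetabolicModel, SyntheticTruth]:
    """Template plus a planted two-reaction energy-generating cycle.

    The pair emulates an incorrectly compartmentalised, duplicated carrier
    reduction (``LEAK_QRED``: free quinol formation) feeding a duplicated
    oxidative phosphorylation step (``LEAK_OXPHOS``), which together
    regenerate ATP from ADP + Pi with all uptakes closed.
    """
    model, truth = make_template_model(seed=seed, **kwargs)
    model.id = f"synthetic_leaky_s{seed}"
    _add_species(model, "q", "c")
    _add_species(model, "qh2", "c")
    model.add_reaction(
        Reaction("LEAK_QRED", name="spurious carrier reduction (duplicate)",
                 stoichiometry={"q_c": -1.0, "qh2_c": 1.0},
                 origin="kegg_metacyc", subsystem="energy metabolism")
    )
    model.add_reaction(
        Reaction("LEAK_OXPHOS", name="duplicated oxidative phosphorylation",
                 stoichiometry={"qh2_c": -1.0, "adp_c": -1.0, "pi_c": -1.0,
                                "q_c": 1.0, "atp_c": 1.0},
                 origin="kegg_metacyc", subsystem="energy metabolism")
    )
    truth.leak_reactions = {("LEAK_OXPHOS", "LEAK_QRED")}
    return model, truth


def make_gapfill_fixture(
    seed: int = 7, n_gaps: int = 1, **kwargs
) -> tuple[MetabolicModel, MetabolicModel, SyntheticTruth]:
    """A broken model / reference pair with known minimal repair.

    Severs the middle step of the first ``n_gaps`` biosynthetic pathways in
    the template, so the corresponding biomass precursors become
    unproducible; the intact template serves as the gap-filling reference.
    """
    reference, truth = make_template_model(seed=seed, **kwargs)
    broken = reference.copy()
    broken.id = f"synthetic_gapped_s{seed}"
    for i in range(1, n_gaps + 1):
        rid = f"P{i}_S2"
        del broken.reactions[rid]
        truth.removed_reactions.add(rid)
        truth.unproducible_precursors.add(f"prec{i}_c")  # biomass-side instance
    return broken, reference, truth


# ---------------------------------------------------------------------------
# Orthology table
# ---------------------------------------------------------------------------

def make_orthology_table(
    template_genes: set[str],
    seed: int = 7,
    frac_single: float = 0.55,
    frac_multi: float = 0.15,
    frac_shared: float = 0.10,
    frac_many: float = 0.05,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Emulated orthology export: source gene, target gene, DIOPT score.

    DIOPT scores lie in [3, 15] (the number of prediction tools agreeing).
    Planted categories: one ortholog; multiple orthologs at distinct scores
    (only the maximum-score target should survive filtering); two source
    genes sharing one target (redundancy); a >9-ortholog case (to be
    dropped as unspecific); and sources with no ortholog at all.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(template_genes)
    order = rng.permutation(len(genes))
    genes = [genes[i] for i in order]
    n = len(genes)
    n_single = round(n * frac_single)
    n_multi = round(n * frac_multi)
    n_shared = round(n * frac_shared) // 2 * 2
    n_many = max(1, round(n * frac_many)) if n >= 4 else 0

    truth = SyntheticTruth()
    rows: list[tuple[str, str, int]] = []
    fly = iter(f"FLY{i:04d}" for i in range(1, 10 * n + 100))
    idx = 0

    for g in genes[idx: idx + n_single]:
        target = next(fly)
        rows.append((g, target, int(rng.integers(3, 16))))
        truth.ortholog_map[g] = {target}
    idx += n_single

    for g in genes[idx: idx + n_multi]:
        best = next(fly)
        best_score = int(rng.integers(8, 16))
        rows.append((g, best, best_score))
        for _ in range(int(rng.integers(1, 3))):
            rows.append((g, next(fly), int(rng.integers(3, best_score))))
        truth.ortholog_map[g] = {best}
    idx += n_multi

    for k in range(0, n_shared, 2):
        g1, g2 = genes[idx + k], genes[idx + k + 1]
        shared = next(fly)
        score = int(rng.integers(5, 16))
        rows.append((g1, shared, score))
        rows.append((g2, shared, score))
        truth.ortholog_map[g1] = {shared}
        truth.ortholog_map[g2] = {shared}
    idx += n_shared

    for g in genes[idx: idx + n_many]:
        score = int(rng.integers(3, 16))
        for _ in range(10):
            rows.append((g, next(fly), score))
        truth.orthology_ambiguities.add(g)
    idx += n_many

    truth.no_ortholog_genes = set(genes[idx:])

    table = pd.DataFrame(rows, columns=["human_gene_id", "fly_gene_id", "diopt_score"])
    return table.sort_values(["human_gene_id", "fly_gene_id"]).reset_index(drop=True), truth


# ---------------------------------------------------------------------------
# Synonym / identifier fixture
# ---------------------------------------------------------------------------

def make_synonym_fixture(
    n_pairs: int = 5, seed: int = 7
) -> tuple[MetabolicModel, pd.DataFrame, SyntheticTruth]:
    """A model with planted synonymous metabolites plus one ambiguous tie.

    Each planted pair is the same compound imported from two sources under
    different names; the pair shares external identifiers with each other
    and with nothing else.  The ambiguous group has two candidate partners
    tied at the same number of shared identifiers, which must be flagged
    for manual review rather than merged.
    """
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()
    model = MetabolicModel(id=f"synonym_fixture_s{seed}")
    model.compartments = {"c": "cytosol", "s": "extracellular"}
    xrows: list[tuple[str, str, str, int]] = []

    def met(mid: str, name: str, xrefs: dict[str, list[str]]) -> str:
        model.add_metabolite(Metabolite(mid, name=name, compartment="c",
                                        xrefs={ns: set(v) for ns, v in xrefs.items()}))
        for ns, ids in xrefs.items():
            for ext in ids:
                xrows.append((mid, ns, ext, 3 if ns == "chebi" else 0))
        return mid

    # hub substrate everything hangs off, so merges rewrite real reactions
    met("hub_c", "hub compound", {"kegg": ["C90000"]})
    model.add_reaction(Reaction("EX_hub", stoichiometry={"hub_c": -1.0},
                                lower_bound=-DEFAULT_BOUND))

    for i in range(1, n_pairs + 1):
        kegg = f"C{10000 + i}"
        chebi = f"CHEBI:{20000 + i}"
        a = met(f"cpd{i}_c", f"compound {i}", {"kegg": [kegg], "chebi": [chebi]})
        b = met(f"cpd{i}alt_c", f"compound {i} (alt source)",
                {"kegg": [kegg], "pubchem": [f"{30000 + i}"]})
        truth.synonym_pairs.add((a, b))
        model.add_reaction(Reaction(f"USE{i}A", stoichiometry={"hub_c": -1.0, a: 1.0}))
        model.add_reaction(Reaction(f"USE{i}B", stoichiometry={b: -1.0, "hub_c": 1.0}))

    # Ambiguous tie: amb0 shares 3 identifiers with amb1 AND 3 with amb2.
    shared1 = {"kegg": ["C40001"], "chebi": ["CHEBI:40001"], "pubchem": ["40001"]}
    shared2 = {"kegg": ["C40002"], "chebi": ["CHEBI:40002"], "pubchem": ["40002"]}
    a0 = met("amb0_c", "ambiguous parent",
             {ns: shared1[ns] + shared2[ns] for ns in shared1})
    a1 = met("amb1_c", "ambiguous candidate 1", shared1)
    a2 = met("amb2_c", "ambiguous candidate 2", shared2)
    truth.ambiguous_synonym_groups.append(frozenset({a0, a1, a2}))
    for mid in (a0, a1, a2):
        model.add_reaction(Reaction(f"USE_{mid}", stoichiometry={"hub_c": -1.0, mid: 1.0}))

    xref = pd.DataFrame(xrows, columns=["metabolite_id", "namespace", "external_id", "star_rank"])
    model.validate()
    return model, xref.sort_values(["metabolite_id", "namespace", "external_id"]).reset_index(drop=True), truth


# ---------------------------------------------------------------------------
# Uncompartmentalised second network
# ---------------------------------------------------------------------------

def make_second_network(
    template: MetabolicModel,
    seed: int = 7,
    n_reactions: int = 6,
    n_shared_genes: int = 3,
) -> tuple[MetabolicModel, pd.DataFrame]:
    """An uncompartmentalised network sharing some genes with the template.

    Stands in for a database-derived draft expansion: metabolites live in a
    single pseudo-compartment ``u`` and a gene → compartment table (drawn
    from the template's declared compartments) accompanies the network for
    the compartmentalisation step.
    """
    rng = np.random.default_rng(seed)
    comps = sorted(c for c in template.compartments if c != "s")
    shared = sorted(template.genes)[:n_shared_genes]
    net = MetabolicModel(id=f"second_network_s{seed}")
    net.compartments = {"u": "uncompartmentalized"}
    rows: list[tuple[str, str, str]] = []

    def kgene(i: int) -> str:
        return f"g_km{i:02d}"

    gene_pool = list(shared) + [kgene(i) for i in range(1, n_reactions + 2)]
    for gene in gene_pool:
        n_loc = int(rng.integers(1, 3))
        locs = rng.choice(comps, size=n_loc, replace=False)
        for loc in sorted(locs):
            rows.append((gene, str(loc), "synthetic_annotation"))

    prev = None
    for i in range(1, n_reactions + 1):
        sub = prev or _add_species(net, f"km_sub{i}", "u")
        prod = _add_species(net, f"km_prod{i}", "u")
        g1 = gene_pool[(2 * i) % len(gene_pool)]
        g2 = gene_pool[(2 * i + 1) % len(gene_pool)]
        gpr = gene_leaf(g1) if i % 2 else gpr_or(gene_leaf(g1), gene_leaf(g2))
        net.add_reaction(
            Reaction(f"KM_R{i}", name=f"database reaction {i}",
                     stoichiometry={sub: -1.0, prod: 1.0},
                     gpr=gpr, origin="kegg_metacyc")
        )
        prev = prod
    net.validate()
    gene_comp = pd.DataFrame(rows, columns=["gene_id", "compartment_code", "source"])
    return net, gene_comp.drop_duplicates().reset_index(drop=True)


# ---------------------------------------------------------------------------
# Expression dataset
# ---------------------------------------------------------------------------

def make_expression_dataset(
    model: MetabolicModel,
    up: set[str],
    down: set[str],
    n_probes_max: int = 3,
    seed: int = 7,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Probe-level expression table whose GPR mapping reproduces planted
    reaction regulation directions.

    Regulated probes draw fold changes log-uniformly from [1.5, 4] (up) or
    [0.25, 0.67] (down) with p-values uniform in (0, 0.01); unregulated
    genes receive moderate fold changes, some deliberately non-significant
    (p ≥ 0.01) to exercise the significance filter.  Multi-probe genes
    exercise all three aggregation rules (max over an up probe, min over a
    down probe, mean over moderate probes).
    """
    if up & down:
        raise ValueError(f"invalid truth: reactions planted both up and down: {up & down}")
    missing = (up | down) - set(model.reactions)
    if missing:
        raise ValueError(f"planted reactions not in model: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()

    gene_dir: dict[str, str] = {}
    for rid in sorted(up):
        truth.regulated_reactions[rid] = "up"
        for g in model.reactions[rid].genes:
            if gene_dir.get(g, "up") != "up":
                raise ValueError(f"gene {g} required both up and down; choose gene-disjoint sets")
            gene_dir[g] = "up"
    for rid in sorted(down):
        truth.regulated_reactions[rid] = "down"
        for g in model.reactions[rid].genes:
            if gene_dir.get(g, "down") != "down":
                raise ValueError(f"gene {g} required both up and down; choose gene-disjoint sets")
            gene_dir[g] = "down"

    rows: list[tuple[str, str, float, float]] = []

    def probe(gene: str, k: int, fc: float, p: float) -> None:
        rows.append((gene, f"{gene}_probe{k}", round(float(fc), 4), round(float(p), 6)))

    for gene in sorted(model.genes):
        direction = gene_dir.get(gene)
        n_probes = int(rng.integers(1, n_probes_max + 1))
        if direction == "up":
            fc = float(np.exp(rng.uniform(np.log(1.5), np.log(4.0))))
            probe(gene, 1, fc, rng.uniform(1e-6, 0.01))
            # extra moderate probes: rule (1) must still pick the max
            for k in range(2, n_probes + 1):
                probe(gene, k, rng.uniform(0.8, 1.3), rng.uniform(1e-6, 0.01))
        elif direction == "down":
            fc = float(np.exp(rng.uniform(np.log(0.25), np.log(0.67))))
            probe(gene, 1, fc, rng.uniform(1e-6, 0.01))
            for k in range(2, n_probes + 1):
                probe(gene, k, rng.uniform(0.8, 1.3), rng.uniform(1e-6, 0.01))
        else:
            # unregulated: moderate, or strong-but-insignificant
            if rng.random() < 0.25:
                probe(gene, 1, rng.uniform(1.6, 3.0), rng.uniform(0.05, 0.9))
            else:
                for k in range(1, n_probes + 1):
                    probe(gene, k, rng.uniform(0.8, 1.25), rng.uniform(1e-6, 0.01))

    table = pd.DataFrame(rows, columns=["gene_id", "probe_id", "fold_change", "p_value"])
    return table, truth


# ---------------------------------------------------------------------------
# One-stop provisioning
# ---------------------------------------------------------------------------

def generate_all(seed: int, outdir: str | Path) -> dict[str, Path]:
    """Write every fixture the pipeline consumes under ``outdir``.

    Emits the template model (JSON + SBML), the leaky variant, the
    gap-fixture pair, the orthology TSV, the gene-compartment TSV and
    second network, the metabolite cross-reference TSV, and the expression
    TSV.  One seed provisions the whole pipeline.
    """
    from .io import write_model  # local import to avoid cycle at module load

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    template, truth = make_template_model(seed=seed)
    paths["template_json"] = out / "template.json"
    paths["template_sbml"] = out / "template.xml"
    write_model(template, paths["template_json"])
    write_model(template, paths["template_sbml"])

    leaky, _ = make_leaky_model(seed=seed)
    paths["leaky_json"] = out / "leaky.json"
    write_model(leaky, paths["leaky_json"])

    broken, reference, _ = make_gapfill_fixture(seed=seed)
    paths["gapped_json"] = out / "gapped.json"
    write_model(broken, paths["gapped_json"])

    ortho, _ = make_orthology_table(template.genes, seed=seed)
    paths["orthology_tsv"] = out / "orthology.tsv"
    ortho.to_csv(paths["orthology_tsv"], sep="\t", index=False)

    syn_model, xref, _ = make_synonym_fixture(seed=seed)
    paths["synonym_model_json"] = out / "synonym_model.json"
    paths["xref_tsv"] = out / "metabolite_xrefs.tsv"
    write_model(syn_model, paths["synonym_model_json"])
    xref.to_csv(paths["xref_tsv"], sep="\t", index=False)

    second, gene_comp = make_second_network(template, seed=seed)
    paths["second_network_json"] = out / "second_network.json"
    paths["gene_compartments_tsv"] = out / "gene_compartments.tsv"
    write_model(second, paths["second_network_json"])
    gene_comp.to_csv(paths["gene_compartments_tsv"], sep="\t", index=False)

    # up: one whole biosynthetic chain; down: the de novo branch of the
    # dietary-OR-synthesis pair, whose flux can shift to the uptake route.
    # (Planting opposite directions on two biomass-coupled chains would be
    # structurally unrecoverable: biomass stoichiometry ties all chains.)
    up = {"P1_S1", "P1_S2", "P1_S3"}
    down = {"ASP_SYN"}
    expr, _ = make_expression_dataset(template, up=up, down=down, seed=seed)
    paths["expression_tsv"] = out / "expression.tsv"
    expr.to_csv(paths["expression_tsv"], sep="\t", index=False)
    return paths
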