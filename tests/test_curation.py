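"""Synonym resolution, duplicate-reaction merging, trivial removal."""

import pytest

from gmnforge.curation import (
    IdentifierDictionary,
    apply_synonym_merge,
    build_identifier_dictionary,
    find_duplicate_reactions,
    find_synonyms,
    merge_duplicates,
    normalize_name,
    remove_trivial,
)
from gmnforge.fluxsim import fba
from gmnforge.gpr import parse_gpr
from gmnforge.model import MetabolicModel, Metabolite, Reaction


def _dict(entries, compartment="c"):
    return IdentifierDictionary(
        identifiers={k: set(v) for k, v in entries.items()},
        compartments={k: compartment for k in entries},
    )


def test_normalize_name():
    assert normalize_name("α-D-Glucose 6-phosphate") == "alphadglucose6phosphate"
    assert normalize_name("L-aspartate") == normalize_name("laspartate")


class TestFindSynonyms:
    def test_single_shared_identifier_pair(self):
        d = _dict({"M1": [("kegg", "C1")], "M2": [("kegg", "C1")],
                   "M9": [("kegg", "C9")]})
        report = find_synonyms(d)
        assert report.merged == [("M1", "M2", 1)]
        assert report.ambiguous == []

    def test_maximum_count_pair_wins(self):
        d = _dict({
            "M3": [("kegg", "C1"), ("chebi", "X1"), ("pubchem", "P1"), ("kegg", "C2")],
            "M4": [("kegg", "C1"), ("chebi", "X1"), ("pubchem", "P1")],
            "M5": [("kegg", "C2")],
        })
        report = find_synonyms(d)
        assert ("M3", "M4", 3) in report.merged
        assert all({"M5"} != {a, b} & {"M5"} or True for a, b, _ in report.merged)

    def test_tied_maximum_is_ambiguous(self):
        shared_a = [("kegg", "C1"), ("chebi", "X1"), ("pubchem", "P1")]
        shared_b = [("kegg", "C2"), ("chebi", "X2"), ("pubchem", "P2")]
        d = _dict({"M1": shared_a, "M2": shared_b, "M3": shared_a + shared_b})
        report = find_synonyms(d)
        assert report.merged == []
        assert report.ambiguous == [frozenset({"M1", "M2", "M3"})]

    def test_compartments_never_pair_within_model(self):
        d = IdentifierDictionary(
            identifiers={"A_c": {("kegg", "C1")}, "A_m": {("kegg", "C1")}},
            compartments={"A_c": "c", "A_m": "m"},
        )
        report = find_synonyms(d)
        assert report.merged == []

    def test_planted_fixture_recovery(self, synonym_fixture):
        model, xref, truth = synonym_fixture
        report = find_synonyms(build_identifier_dictionary(model, xref))
        assert report.merged_pairs() == {frozenset(p) for p in truth.synonym_pairs}
        assert report.ambiguous == truth.ambiguous_synonym_groups


class TestApplySynonymMerge:
    def test_rewrite_and_zero_sum_removal(self):
        m = MetabolicModel(id="t")
        m.compartments = {"c": "c"}
        for mid in ("keep", "drop", "X"):
            m.add_metabolite(Metabolite(mid, compartment="c"))
        m.add_reaction(Reaction("R1", stoichiometry={"drop": -1.0, "X": 1.0}))
        m.add_reaction(Reaction("R2", stoichiometry={"keep": -1.0, "drop": 1.0}))
        from gmnforge.curation import SynonymReport

        report = SynonymReport(merged=[("keep", "drop", 1)])
        out = apply_synonym_merge(m, report)
        assert out.reactions["R1"].stoichiometry == {"keep": -1.0, "X": 1.0}
        assert "R2" not in out.reactions  # became keep -> keep, i.e. empty
        assert "drop" not in out.metabolites

    def test_fixture_merge_and_idempotence(self, synonym_fixture):
        model, xref, truth = synonym_fixture
        report = find_synonyms(build_identifier_dictionary(model, xref))
        merged = apply_synonym_merge(model, report)
        assert len(merged.metabolites) == len(model.metabolites) - len(truth.synonym_pairs)
        # second pass finds nothing new to merge
        report2 = find_synonyms(build_identifier_dictionary(merged, xref))
        assert report2.merged == []


class TestDuplicateReactions:
    def _model(self):
        m = MetabolicModel(id="dup")
        m.compartments = {"c": "c", "m": "m"}
        for mid, name, comp in [
            ("A_c", "A", "c"), ("B_c", "B", "c"), ("A_m", "A", "m"),
            ("B_m", "B", "m"), ("h2o_c", "water", "c"),
        ]:
            m.add_metabolite(Metabolite(mid, name=name, compartment=comp))
        return m

    def test_currency_metabolites_ignored(self):
        m = self._model()
        m.add_reaction(Reaction("R1", stoichiometry={"A_c": -1, "h2o_c": -1, "B_c": 1},
                                gpr=parse_gpr("g1"), origin="template"))
        m.add_reaction(Reaction("R2", stoichiometry={"A_c": -1, "B_c": 1},
                                gpr=parse_gpr("g2"), origin="kegg_metacyc"))
        groups = find_duplicate_reactions(m)
        assert groups == [["R1", "R2"]]

    def test_compartment_insensitive_mode(self):
        m = self._model()
        m.add_reaction(Reaction("R1", stoichiometry={"A_c": -1, "B_c": 1}))
        m.add_reaction(Reaction("R2", stoichiometry={"A_m": -1, "B_m": 1}))
        assert find_duplicate_reactions(m) == []
        assert find_duplicate_reactions(m, ignore_compartments=True) == [["R1", "R2"]]

    def test_reverse_direction_counts_as_duplicate(self):
        m = self._model()
        m.add_reaction(Reaction("FWD", stoichiometry={"A_c": -1, "B_c": 1},
                                lower_bound=-1000))
        m.add_reaction(Reaction("REV", stoichiometry={"B_c": -1, "A_c": 1}))
        assert find_duplicate_reactions(m) == [["FWD", "REV"]]


class TestMergeDuplicates:
    def _dup_model(self, gpr1="g1", gpr2="g2"):
        m = MetabolicModel(id="dm")
        m.compartments = {"c": "c"}
        for mid in ("A", "B"):
            m.add_metabolite(Metabolite(mid, name=mid, compartment="c"))
        m.add_reaction(Reaction("R1", stoichiometry={"A": -1, "B": 1},
                                gpr=parse_gpr(gpr1), origin="template"))
        m.add_reaction(Reaction("R2", stoichiometry={"A": -1, "B": 1},
                                gpr=parse_gpr(gpr2), origin="kegg_metacyc",
                                lower_bound=-1000))
        return m

    def test_survivor_gpr_is_or_and_no_gene_loss(self):
        m = self._dup_model()
        out = merge_duplicates(m, find_duplicate_reactions(m))
        assert set(out.reactions) == {"R1"}  # template origin preferred
        assert out.reactions["R1"].gene_reaction_rule == "g1 or g2"
        assert out.genes == {"g1", "g2"}
        # widest bounds in the group survive
        assert out.reactions["R1"].lower_bound == -1000

    def test_identical_gpr_unchanged(self):
        m = self._dup_model("g1", "g1")
        out = merge_duplicates(m, find_duplicate_reactions(m))
        assert out.reactions["R1"].gene_reaction_rule == "g1"

    def test_idempotence(self):
        m = self._dup_model()
        once = merge_duplicates(m, find_duplicate_reactions(m))
        assert find_duplicate_reactions(once) == []

    def test_dedup_preserves_growth_optimum(self, template):
        """Adding a true duplicate then merging it away leaves the FBA
        optimum unchanged."""
        model, _ = template
        withdup = model.copy()
        dup = model.reactions["P1_S1"].copy()
        dup.id = "P1_S1_copy"
        dup.origin = "kegg_metacyc"
        withdup.add_reaction(dup)
        groups = [g for g in find_duplicate_reactions(withdup)
                  if "P1_S1_copy" in g]
        merged = merge_duplicates(withdup, groups)
        assert fba(merged).objective_value == pytest.approx(
            fba(model).objective_value, abs=1e-6
        )


def test_remove_trivial_fixpoint():
    m = MetabolicModel(id="triv")
    m.compartments = {"c": "c"}
    m.add_metabolite(Metabolite("used", compartment="c"))
    m.add_metabolite(Metabolite("orphan", compartment="c"))
    m.add_reaction(Reaction("KEEP", stoichiometry={"used": -1.0}))
    m.reactions["EMPTY"] = Reaction("EMPTY", stoichiometry={"used": 1.0})
    m.reactions["EMPTY"].stoichiometry = {}
    out = remove_trivial(m)
    assert set(out.reactions) == {"KEEP"}
    assert set(out.metabolites) == {"used"}
    # clean model is unchanged
    again = remove_trivial(out)
    assert set(again.reactions) == {"KEEP"} and set(again.metabolites) == {"used"}
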