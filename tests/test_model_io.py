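"""Model domain types, merging, biomass editing, and SBML/JSON round-trips."""

import textwrap

import pytest

from gmnforge.fluxsim import fba
from gmnforge.gpr import parse_gpr
from gmnforge.io import ParseError, read_model, write_model
from gmnforge.model import (
    MetabolicModel,
    Metabolite,
    ModelIntegrityError,
    Reaction,
    edit_biomass,
    merge_models,
    models_equal,
)
from gmnforge.synth import make_second_network, make_template_model

# A hand-written 3-reaction SBML toy: uptake, conversion, export.
TOY_SBML = textwrap.dedent("""\
    <?xml version="1.0" encoding="UTF-8"?>
    <sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
          xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2"
          level="3" version="1" fbc:required="false">
      <model id="toy" fbc:strict="false">
        <listOfCompartments>
          <compartment id="c" constant="true"/>
        </listOfCompartments>
        <listOfSpecies>
          <species id="M_A" compartment="c" constant="false"
                   boundaryCondition="false" hasOnlySubstanceUnits="false"/>
          <species id="M_B" compartment="c" constant="false"
                   boundaryCondition="false" hasOnlySubstanceUnits="false"/>
        </listOfSpecies>
        <listOfParameters>
          <parameter id="lb_u" value="-10" constant="true"/>
          <parameter id="lb_0" value="0" constant="true"/>
          <parameter id="ub" value="1000" constant="true"/>
        </listOfParameters>
        <listOfReactions>
          <reaction id="R_EX_A" reversible="true" fast="false"
                    fbc:lowerFluxBound="lb_u" fbc:upperFluxBound="ub">
            <listOfReactants>
              <speciesReference species="M_A" stoichiometry="1" constant="true"/>
            </listOfReactants>
          </reaction>
          <reaction id="R_CONV" reversible="false" fast="false"
                    fbc:lowerFluxBound="lb_0" fbc:upperFluxBound="ub">
            <listOfReactants>
              <speciesReference species="M_A" stoichiometry="1" constant="true"/>
            </listOfReactants>
            <listOfProducts>
              <speciesReference species="M_B" stoichiometry="1" constant="true"/>
            </listOfProducts>
          </reaction>
          <reaction id="R_EX_B" reversible="false" fast="false"
                    fbc:lowerFluxBound="lb_0" fbc:upperFluxBound="ub">
            <listOfReactants>
              <speciesReference species="M_B" stoichiometry="1" constant="true"/>
            </listOfReactants>
          </reaction>
        </listOfReactions>
      </model>
    </sbml>
""")


def test_read_toy_sbml(tmp_path):
    path = tmp_path / "toy.xml"
    path.write_text(TOY_SBML)
    model = read_model(path)
    assert len(model.reactions) == 3
    assert len(model.metabolites) == 2
    assert model.reactions["EX_A"].lower_bound == -10
    assert model.reactions["CONV"].stoichiometry == {"A": -1.0, "B": 1.0}


def test_malformed_sbml_raises(tmp_path):
    path = tmp_path / "bad.xml"
    path.write_text("<sbml><model></sbml>")
    with pytest.raises(ParseError):
        read_model(path)


def test_dangling_reference_raises():
    model = MetabolicModel()
    model.add_metabolite(Metabolite("A", compartment="c"))
    model.reactions["R"] = Reaction("R", stoichiometry={"A": -1.0, "GHOST": 1.0})
    with pytest.raises(ModelIntegrityError, match="GHOST"):
        model.validate()


@pytest.mark.parametrize("fmt", ["json", "sbml"])
def test_roundtrip_preserves_model(template, tmp_path, fmt):
    model, _ = template
    path = tmp_path / ("m.json" if fmt == "json" else "m.xml")
    write_model(model, path)
    assert models_equal(model, read_model(path))


def test_notes_field_gpr_dialect(tmp_path):
    """Older SBML files carry GPRs in notes; the reader must accept them."""
    notes = (
        '<notes><body xmlns="http://www.w3.org/1999/xhtml">'
        "<p>GENE_ASSOCIATION: ga1 or ga2</p></body></notes>"
    )
    marker = 'fbc:lowerFluxBound="lb_0" fbc:upperFluxBound="ub">'
    assert TOY_SBML.count(marker) == 2  # CONV and EX_B
    sbml = TOY_SBML.replace(marker, marker + notes, 1)
    path = tmp_path / "notes.xml"
    path.write_text(sbml)
    model = read_model(path)
    assert model.reactions["CONV"].genes == {"ga1", "ga2"}


# -- merging ---------------------------------------------------------------

def _mini(rids, mets, mid="mini"):
    m = MetabolicModel(id=mid)
    m.compartments = {"c": "c"}
    for met in mets:
        m.add_metabolite(Metabolite(met, name=met, compartment="c"))
    for rid, stoich, rule in rids:
        m.add_reaction(Reaction(rid, stoichiometry=stoich, gpr=parse_gpr(rule)))
    return m


def test_merge_counts_and_shared_metabolite():
    base = _mini(
        [("R1", {"A": -1, "B": 1}, "g1"), ("R2", {"B": -1, "C": 1}, ""),
         ("R3", {"C": -1}, "")],
        ["A", "B", "C"],
    )
    addition = _mini(
        [("R4", {"C": -1, "D": 1}, "g2"), ("R5", {"D": -1}, "")],
        ["C", "D"], mid="add",
    )
    merged = merge_models(base, addition)
    assert len(merged.reactions) == 5
    assert len(merged.metabolites) == 4  # shared C not duplicated
    assert merged.genes == {"g1", "g2"}


def test_merge_empty_addition_is_identity(template):
    model, _ = template
    merged = merge_models(model, MetabolicModel(id="empty"))
    assert models_equal(model, merged)


def test_merge_gene_union_on_synthetic_fixture(template):
    model, _ = template
    second, _ = make_second_network(model, seed=7)
    merged = merge_models(model, second)
    assert merged.genes == model.genes | second.genes


def test_merge_contradictory_bounds_raise():
    base = _mini([("R1", {"A": -1, "B": 1}, "")], ["A", "B"])
    other = _mini([("R1", {"A": -1, "B": 1}, "")], ["A", "B"], mid="o")
    other.reactions["R1"].upper_bound = 5.0
    with pytest.raises(ModelIntegrityError, match="contradictory"):
        merge_models(base, other)


# -- biomass editing -------------------------------------------------------

def test_edit_biomass_remove_component(template):
    model, _ = template
    edited = edit_biomass(model, remove={"prec_ster_c"})
    biomass = edited.reactions[edited.biomass_reaction_id]
    assert "prec_ster_c" not in biomass.stoichiometry
    # the metabolite itself stays in the model
    assert "prec_ster_c" in edited.metabolites
    assert "prec_ster_c" in edited.reactions["STER_SYN"].stoichiometry


def test_edit_biomass_noop_and_warning(template):
    model, _ = template
    assert models_equal(model, edit_biomass(model, remove=set()))
    with pytest.warns(UserWarning, match="not in biomass"):
        edit_biomass(model, remove={"not_a_met"})


def test_growth_monotone_in_biomass_atp_demand(template):
    """Raising the growth-associated ATP cost can only reduce growth."""
    model, _ = template
    lo = fba(model).objective_value
    heavier = edit_biomass(
        model, set_coefficients={"atp_c": -60.0, "adp_c": 60.0, "pi_c": 60.0}
    )
    hi = fba(heavier).objective_value
    assert hi <= lo + 1e-9
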