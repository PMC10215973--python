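import pytest

from gmnforge.model import MetabolicModel, Metabolite, Reaction
from gmnforge.synth import (
    make_gapfill_fixture,
    make_leaky_model,
    make_synonym_fixture,
    make_template_model,
)

SEED = 7


@pytest.fixture(scope="session")
def template():
    return make_template_model(seed=SEED)


@pytest.fixture(scope="session")
def leaky():
    return make_leaky_model(seed=SEED)


@pytest.fixture(scope="session")
def gapfill_fixture():
    return make_gapfill_fixture(seed=SEED)


@pytest.fixture(scope="session")
def synonym_fixture():
    return make_synonym_fixture(seed=SEED)


def toy_chain_model(uptake: float = 10.0) -> MetabolicModel:
    """EX_A (uptake) -> A -> B -> EX_B: the minimal throughput-bounded net."""
    m = MetabolicModel(id="toy_chain")
    m.compartments = {"c": "cytosol"}
    m.add_metabolite(Metabolite("A", compartment="c"))
    m.add_metabolite(Metabolite("B", compartment="c"))
    m.add_reaction(Reaction("EX_A", stoichiometry={"A": -1.0}, lower_bound=-uptake))
    m.add_reaction(Reaction("CONV", stoichiometry={"A": -1.0, "B": 1.0}))
    m.add_reaction(Reaction("EX_B", stoichiometry={"B": -1.0}))
    m.objective_reaction_id = "EX_B"
    return m


@pytest.fixture
def toy_chain():
    return toy_chain_model()
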