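"""FBA/FVA/deletion solvers against brute-force oracles."""

import itertools

import numpy as np
import pytest

from gmnforge.fluxsim import (
    build_stoichiometric_matrix,
    double_reaction_deletion,
    fba,
    fva,
    single_gene_deletion,
)
from gmnforge.gpr import parse_gpr
from gmnforge.model import MetabolicModel, Metabolite, Reaction

from conftest import toy_chain_model


def test_fba_throughput_bound(toy_chain):
    sol = fba(toy_chain)
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(10.0)


def test_fba_no_input_zero_flux(toy_chain):
    toy_chain.reactions["EX_A"].lower_bound = 0.0
    sol = fba(toy_chain)
    assert sol.objective_value == pytest.approx(0.0)


def test_fba_mass_balance_residual(template):
    model, _ = template
    sol = fba(model)
    S, met_ids, rxn_ids = build_stoichiometric_matrix(model)
    v = np.array([sol.fluxes[r] for r in rxn_ids])
    assert np.abs(S @ v).max() <= 1e-6
    for rid in rxn_ids:
        rxn = model.reactions[rid]
        assert rxn.lower_bound - 1e-9 <= sol.fluxes[rid] <= rxn.upper_bound + 1e-9


# -- vertex-enumeration oracle --------------------------------------------

def _random_network(rng, n_rxns=6, n_mets=3):
    S = rng.integers(-2, 3, size=(n_mets, n_rxns)).astype(float)
    lb = np.where(rng.random(n_rxns) < 0.5, -rng.integers(1, 11, n_rxns), 0).astype(float)
    ub = rng.integers(1, 11, n_rxns).astype(float)
    return S, lb, ub


def _vertex_oracle(S, lb, ub, c):
    """Enumerate candidate vertices of {Sv=0, lb<=v<=ub}; return max c·v."""
    m, n = S.shape
    r = np.linalg.matrix_rank(S)
    best = None
    for k in range(n - r, n + 1):
        for fixed in itertools.combinations(range(n), k):
            free = [j for j in range(n) if j not in fixed]
            A = S[:, free]
            if free and np.linalg.matrix_rank(A) < len(free):
                continue
            for values in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
                b = -S[:, fixed] @ np.array(values) if fixed else np.zeros(m)
                if free:
                    x_free, *_ = np.linalg.lstsq(A, b, rcond=None)
                    if np.abs(A @ x_free - b).max() > 1e-8:
                        continue
                else:
                    x_free = np.array([])
                    if np.abs(b).max() > 1e-8:
                        continue
                v = np.zeros(n)
                for j, val in zip(fixed, values):
                    v[j] = val
                v[free] = x_free
                if (v >= lb - 1e-8).all() and (v <= ub + 1e-8).all():
                    value = float(c @ v)
                    best = value if best is None else max(best, value)
    return best


def _to_model(S, lb, ub):
    model = MetabolicModel(id="rand")
    model.compartments = {"c": "c"}
    n_mets, n_rxns = S.shape
    for i in range(n_mets):
        model.add_metabolite(Metabolite(f"m{i}", compartment="c"))
    for j in range(n_rxns):
        stoich = {f"m{i}": S[i, j] for i in range(n_mets) if S[i, j] != 0}
        if not stoich:
            stoich = {"m0": 1.0}
            S[0, j] = 1.0
        model.add_reaction(
            Reaction(f"r{j:02d}", stoichiometry=stoich,
                     lower_bound=lb[j], upper_bound=ub[j])
        )
    model.objective_reaction_id = "r00"
    return model


@pytest.mark.parametrize("seed", range(12))
def test_fba_matches_vertex_enumeration(seed):
    rng = np.random.default_rng(seed)
    S, lb, ub = _random_network(rng)
    model = _to_model(S, lb, ub)
    S = np.array(
        [[model.reactions[f"r{j:02d}"].stoichiometry.get(f"m{i}", 0.0)
          for j in range(S.shape[1])] for i in range(S.shape[0])]
    )
    c = np.zeros(S.shape[1])
    c[0] = 1.0
    oracle = _vertex_oracle(S, lb, ub, c)
    sol = fba(model)
    if sol.status == "optimal":
        assert oracle is not None
        assert sol.objective_value == pytest.approx(oracle, abs=1e-6)
    else:
        assert oracle is None


# -- FVA -------------------------------------------------------------------

def test_fva_blocked_disconnected_reaction(toy_chain):
    toy_chain.add_metabolite(Metabolite("C", compartment="c"))
    toy_chain.add_metabolite(Metabolite("D", compartment="c"))
    toy_chain.add_reaction(Reaction("DEAD", stoichiometry={"C": -1.0, "D": 1.0}))
    result = fva(toy_chain)
    assert "DEAD" in result.blocked
    assert result.ranges["EX_B"] == pytest.approx((0.0, 10.0), abs=1e-7)


def test_fva_contains_fba_flux(template):
    model, _ = template
    sol = fba(model)
    result = fva(model)
    for rid, (lo, hi) in result.ranges.items():
        assert lo - 1e-6 <= sol.fluxes[rid] <= hi + 1e-6


def test_fva_objective_fraction(template):
    model, _ = template
    wt = fba(model).objective_value
    result = fva(model, reactions=["BIOMASS"], fix_objective_fraction=0.9)
    lo, _hi = result.ranges["BIOMASS"]
    assert lo >= 0.9 * wt - 1e-6


# -- gene deletion ---------------------------------------------------------

def test_single_gene_deletion_sole_path_and_isozyme(toy_chain):
    toy_chain.reactions["CONV"].gpr = parse_gpr("gx")
    growth = single_gene_deletion(toy_chain, {"gx"})
    assert growth["gx"] == pytest.approx(0.0, abs=1e-9)
    toy_chain.reactions["CONV"].gpr = parse_gpr("gx or gy")
    growth = single_gene_deletion(toy_chain, {"gx"})
    assert growth["gx"] == pytest.approx(growth[""])


def test_deletion_classification_matches_planted_truth(template):
    model, truth = template
    growth = single_gene_deletion(model)
    wt = growth[""]
    essential = {g for g in model.genes if growth[g] / wt < 0.3}
    assert essential == truth.essential_genes


@pytest.mark.parametrize("seed", range(50))
def test_deletion_monotonicity_random_fixtures(seed):
    """No knockout can grow faster than wild type."""
    rng = np.random.default_rng(seed)
    model = toy_chain_model(uptake=float(rng.integers(1, 20)))
    genes = [f"g{k}" for k in range(int(rng.integers(1, 4)))]
    rule = (" or " if rng.random() < 0.5 else " and ").join(genes)
    model.reactions["CONV"].gpr = parse_gpr(rule)
    growth = single_gene_deletion(model)
    wt = growth[""]
    assert all(growth[g] <= wt + 1e-9 for g in genes)


# -- double reaction deletion ----------------------------------------------

def test_double_deletion_matches_nested_loop_oracle(template):
    model, _ = template
    candidates = ["P1_S1", "P1_S2", "RESP", "STER_SYN", "ASP_SYN",
                  "ASP_USE", "EX_glc", "NGAM"]
    grid = double_reaction_deletion(model, candidates)

    def oracle(r1, r2):
        work = model.copy()
        for rid in (r1, r2):
            work.reactions[rid].lower_bound = 0.0
            work.reactions[rid].upper_bound = 0.0
        sol = fba(work)
        return sol.objective_value if sol.optimal else 0.0

    wt = fba(model).objective_value
    for (r1, r2), value in grid.items():
        assert value == pytest.approx(oracle(r1, r2), abs=1e-6)
    # a pair covering both routes to the aspartate-like precursor is lethal,
    # while two irrelevant deletions leave growth at wild type
    lethal = double_reaction_deletion(model, ["ASP_SYN", "T_asp_sc"])
    assert lethal[("ASP_SYN", "T_asp_sc")] == pytest.approx(0.0, abs=1e-6)
    benign = double_reaction_deletion(model, ["ASP_SYN", "BLOCKED_RXN"])
    assert benign[("ASP_SYN", "BLOCKED_RXN")] == pytest.approx(wt, abs=1e-6)


def test_double_deletion_cap(template):
    model, _ = template
    with pytest.raises(ValueError, match="cap"):
        double_reaction_deletion(model, sorted(model.reactions), cap=5)


# -- scaling invariance ----------------------------------------------------

def test_scaling_invariance(toy_chain):
    base = fba(toy_chain).objective_value
    scaled = toy_chain.copy()
    for rxn in scaled.reactions.values():
        rxn.lower_bound *= 2.0
        rxn.upper_bound *= 2.0
    assert fba(scaled).objective_value == pytest.approx(2.0 * base)
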