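"""Expression aggregation, GPR mapping, and two-step ΔFBA."""

import numpy as np
import pandas as pd
import pytest

from gmnforge.deltafba import (
    aggregate_gene_fold_changes,
    delta_fba,
    map_expression_to_reactions,
    open_exchanges,
    regulated_genes,
)
from gmnforge.fluxsim import build_stoichiometric_matrix
from gmnforge.gpr import parse_gpr
from gmnforge.model import MetabolicModel, Metabolite, Reaction
from gmnforge.synth import make_expression_dataset


def _table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "probe_id", "fold_change", "p_value"])


class TestAggregation:
    @pytest.mark.parametrize(
        "fcs, expected",
        [
            ([1.8, 1.2], 1.8),     # rule 1: any up probe -> max
            ([0.5, 1.2], 0.5),     # rule 2: any down probe -> min
            ([0.5, 2.0], 1.25),    # rule 3: ambiguous -> mean
            ([0.8, 1.2], 1.0),     # rule 3: all moderate -> mean
        ],
    )
    def test_rules(self, fcs, expected):
        rows = [("g1", f"p{i}", fc, 0.001) for i, fc in enumerate(fcs)]
        assert aggregate_gene_fold_changes(_table(rows))["g1"] == pytest.approx(expected)

    def test_insignificant_probes_dropped_first(self):
        rows = [("g1", "p1", 3.0, 0.5), ("g1", "p2", 1.0, 0.001)]
        assert aggregate_gene_fold_changes(_table(rows))["g1"] == pytest.approx(1.0)
        # gene with no surviving probe is omitted
        rows = [("g2", "p1", 3.0, 0.5)]
        assert aggregate_gene_fold_changes(_table(rows)) == {}


class TestMapping:
    def _model(self, rule):
        m = MetabolicModel(id="t")
        m.compartments = {"c": "c"}
        m.add_metabolite(Metabolite("A", compartment="c"))
        m.add_reaction(Reaction("R", stoichiometry={"A": 1.0}, gpr=parse_gpr(rule)))
        return m

    @pytest.mark.parametrize(
        "rule, fc, expected",
        [
            ("g1 and g2", {"g1": 2.0, "g2": 0.5}, 0.5),  # complex: min
            ("g1 or g2", {"g1": 2.0, "g2": 0.5}, 2.0),   # isozymes: max
            ("(g1 and g2) or g3", {"g1": 2.0, "g2": 0.5, "g3": 1.1}, 1.1),
            ("g1 and g2", {"g1": 2.0}, 2.0),  # unmeasured child skipped
        ],
    )
    def test_recursive_min_max(self, rule, fc, expected):
        m = self._model(rule)
        assert map_expression_to_reactions(m, fc)["R"] == pytest.approx(expected)

    def test_unmeasured_sentinel(self):
        m = self._model("g1")
        assert map_expression_to_reactions(m, {})["R"] is None
        m2 = self._model("")
        assert map_expression_to_reactions(m2, {"g1": 2.0})["R"] is None


def _linear_path_model():
    """EX_A <-> A -> B -> C -> EX_C, every internal step gene-controlled."""
    m = MetabolicModel(id="path")
    m.compartments = {"c": "c"}
    for mid in ("A", "B", "C"):
        m.add_metabolite(Metabolite(mid, compartment="c"))
    m.add_reaction(Reaction("EX_A", stoichiometry={"A": -1.0}, lower_bound=-1000))
    m.add_reaction(Reaction("S1", stoichiometry={"A": -1.0, "B": 1.0},
                            gpr=parse_gpr("g1")))
    m.add_reaction(Reaction("S2", stoichiometry={"B": -1.0, "C": 1.0},
                            gpr=parse_gpr("g2")))
    m.add_reaction(Reaction("EX_C", stoichiometry={"C": -1.0}))
    m.objective_reaction_id = "EX_C"
    return m


class TestDeltaFba:
    def test_planted_up_path_recovered(self):
        m = _linear_path_model()
        sol = delta_fba(m, {"S1": 2.0, "S2": 3.0})
        assert sol.n_consistent == 2
        assert sol.up_regulated == {"S1", "S2"}
        assert sol.delta_v["S1"] >= sol.threshold

    def test_no_calls_gives_zero_delta(self):
        m = _linear_path_model()
        sol = delta_fba(m, {})
        assert all(abs(v) <= 1e-9 for v in sol.delta_v.values())
        assert sol.up_regulated == set() and sol.down_regulated == set()

    def test_steady_state_and_bounds_respected(self, template):
        model, _ = template
        m = open_exchanges(model)
        expr, _ = make_expression_dataset(
            m, up={"P1_S1", "P1_S2", "P1_S3"}, down={"ASP_SYN"}, seed=7
        )
        rxn_fc = map_expression_to_reactions(m, aggregate_gene_fold_changes(expr))
        sol = delta_fba(m, rxn_fc)
        S, met_ids, rxn_ids = build_stoichiometric_matrix(m)
        dv = np.array([sol.delta_v[r] for r in rxn_ids])
        assert np.abs(S @ dv).max() <= 1e-6
        for rid in rxn_ids:
            rxn = m.reactions[rid]
            width = rxn.upper_bound - rxn.lower_bound
            assert -width - 1e-6 <= sol.delta_v[rid] <= width + 1e-6
        # maintenance flux held constant between conditions
        assert sol.delta_v[m.ngam_reaction_id] == pytest.approx(0.0, abs=1e-9)

    def test_planted_direction_recovery_rate(self, template):
        model, _ = template
        m = open_exchanges(model)
        up = {"P1_S1", "P1_S2", "P1_S3"}
        down = {"ASP_SYN"}
        expr, truth = make_expression_dataset(m, up=up, down=down, seed=7)
        rxn_fc = map_expression_to_reactions(m, aggregate_gene_fold_changes(expr))
        sol = delta_fba(m, rxn_fc)
        recovered = sum(1 for r in up if r in sol.up_regulated) + sum(
            1 for r in down if r in sol.down_regulated
        )
        recoverable = sol.n_consistent
        assert recoverable > 0
        assert recovered / recoverable >= 0.95

    def test_biomass_coupled_conflict_is_unrecoverable(self, template):
        """Opposite calls on two chains that biomass stoichiometry ties
        together cannot all be consistent; step 1 reports the true maximum."""
        model, _ = template
        m = open_exchanges(model)
        calls = {"P1_S1": 2.0, "P1_S2": 2.0, "P1_S3": 2.0,
                 "P2_S1": 0.4, "P2_S2": 0.4}
        sol = delta_fba(m, calls)
        assert sol.n_consistent == 3  # one chain direction must lose

    def test_regulated_gene_extraction(self):
        m = _linear_path_model()
        sol = delta_fba(m, {"S1": 2.0, "S2": 0.5})
        genes = regulated_genes(m, sol)
        assert genes["up"] <= {"g1"} and genes["down"] <= {"g2"}
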