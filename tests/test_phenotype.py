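"""Diet construction, nutrient titrations, essentiality screening, scoring."""

import numpy as np
import pandas as pd
import pytest

from gmnforge.phenotype import (
    DietSpec,
    EssentialityReport,
    build_holidic_diet,
    essentiality_screen,
    score_predictions,
    titration_curve,
    unlimited_diet,
)
from gmnforge.fluxsim import fba


def _composition():
    return pd.DataFrame(
        [
            ("EX_sucrose", "carbon", 2.212),
            ("EX_thiamine", "vitamin", None),
            ("EX_leucine", "other", None),
            ("EX_nacl", "salt_water", None),
        ],
        columns=["exchange_id", "category", "max_uptake"],
    )


class TestHolidicDiet:
    def test_flexible_ratios(self):
        diet = build_holidic_diet(_composition(), sucrose_max=2.212)
        assert diet.entries["EX_sucrose"][1] == pytest.approx(2.212)
        assert diet.entries["EX_thiamine"][1] == pytest.approx(0.02212)  # 1/100
        assert diet.entries["EX_leucine"][1] == pytest.approx(0.2212)  # 1/10
        assert diet.entries["EX_nacl"][1] == 1000.0  # salts/water unbounded

    def test_measured_mode_uses_table_verbatim(self):
        comp = _composition()
        comp["max_uptake"] = [1.0, 2.0, 3.0, 4.0]
        diet = build_holidic_diet(comp, flexible=False)
        assert [diet.entries[r][1] for r in comp["exchange_id"]] == [1, 2, 3, 4]

    def test_unknown_category_raises(self):
        comp = _composition()
        comp.loc[0, "category"] = "mystery"
        with pytest.raises(ValueError, match="mystery"):
            build_holidic_diet(comp)


def _synthetic_diet(model, carbon_max=2.212):
    """Holidic-style diet for the synthetic template: capped carbon,
    proportional other compounds, unlimited salts, fixed oxygen."""
    diet = DietSpec(oxygen_exchange="EX_o2", oxygen_max=24.0)
    diet.entries = {
        "EX_glc": ("carbon", carbon_max),
        "EX_sterol": ("other", carbon_max / 10.0),
        "EX_asp": ("other", carbon_max / 10.0),
        "EX_nh4": ("salt_water", 1000.0),
    }
    return diet


class TestTitration:
    def test_sterol_auxotrophy_zero_uptake_zero_growth(self, template):
        model, _ = template
        diet = _synthetic_diet(model)
        curve = titration_curve(model, diet, "EX_sterol", [0.0])
        assert curve[0][1] == pytest.approx(0.0, abs=1e-9)

    def test_sterol_monotone_to_plateau(self, template):
        model, _ = template
        diet = _synthetic_diet(model)
        grid = list(np.linspace(0, 0.25, 11))
        curve = titration_curve(model, diet, "EX_sterol", grid)
        growth = [g for _, g in curve]
        assert all(g is not None for g in growth)
        assert all(b >= a - 1e-9 for a, b in zip(growth, growth[1:]))
        # saturates: the last increments no longer raise growth
        assert growth[-1] == pytest.approx(growth[-2], abs=1e-6)
        assert growth[-1] > 0

    def test_aspartate_analog_depletion_harmless(self, template):
        model, _ = template
        diet = _synthetic_diet(model)
        full = fba(diet.apply(model)).objective_value
        curve = titration_curve(model, diet, "EX_asp", [0.0])
        assert curve[0][1] == pytest.approx(full, abs=1e-6)

    def test_min_fraction_forces_uptake(self, template):
        model, _ = template
        diet = _synthetic_diet(model)
        curve = titration_curve(model, diet, "EX_sterol", [0.1], min_fraction=0.1)
        point = diet.apply(model)
        point.reactions["EX_sterol"].lower_bound = -0.1
        point.reactions["EX_sterol"].upper_bound = -0.01
        sol = fba(point)
        assert curve[0][1] == pytest.approx(sol.objective_value, abs=1e-9)


class TestEssentialityScreen:
    def test_matches_planted_truth(self, template):
        model, truth = template
        report = essentiality_screen(model, unlimited_diet(model))
        assert report.essential_genes == truth.essential_genes

    def test_blocked_only_genes_excluded(self, template):
        model, truth = template
        report = essentiality_screen(model, unlimited_diet(model))
        excluded = {g for g, c in report.calls.items() if c == "excluded_blocked"}
        assert excluded == truth.blocked_only_genes

    def test_monotone_in_cutoff(self, template):
        model, _ = template
        diet = unlimited_diet(model)
        loose = essentiality_screen(model, diet, cutoff=0.3)
        strict = essentiality_screen(model, diet, cutoff=1.0)
        assert loose.essential_genes <= strict.essential_genes

    def test_zero_growth_raises(self, template):
        model, _ = template
        starved = model.copy()
        starved.reactions["EX_sterol"].lower_bound = 0.0
        starved.reactions["NGAM"].lower_bound = 0.0
        with pytest.raises(RuntimeError, match="wild-type growth"):
            essentiality_screen(starved)

    def test_diet_tightening_never_increases_growth(self, template):
        model, _ = template
        diet = _synthetic_diet(model, carbon_max=2.212)
        tighter = _synthetic_diet(model, carbon_max=1.0)
        assert (
            fba(tighter.apply(model)).objective_value
            <= fba(diet.apply(model)).objective_value + 1e-9
        )


class TestScorePredictions:
    @pytest.mark.parametrize(
        "tp, fp, expected_precision",
        [(90, 32, 0.74), (64, 25, 0.72), (3, 3, 0.50)],
    )
    def test_precision_from_printed_counts(self, tp, fp, expected_precision):
        calls = {f"e{i}": "essential" for i in range(tp + fp)}
        gold = {f"e{i}": "essential" if i < tp else "nonessential"
                for i in range(tp + fp)}
        report = score_predictions(calls, gold)
        assert report.confusion["TP"] == tp and report.confusion["FP"] == fp
        assert report.metrics["precision"] == pytest.approx(expected_precision)

    def test_perfect_classifier(self):
        calls = {"a": "essential", "b": "nonessential", "c": "essential"}
        gold = {"a": "essential", "b": "nonessential", "c": "essential"}
        report = score_predictions(calls, gold)
        assert report.metrics["mcc"] == 1.0
        assert report.metrics["f1"] == 1.0

    def test_unknown_gold_counts_unclassified(self):
        calls = {"a": "essential", "b": "essential"}
        gold = {"a": "essential"}
        report = score_predictions(calls, gold)
        assert report.confusion["unclassified"] == 1
        assert report.confusion["TP"] == 1

    def test_zero_denominator_is_undefined(self):
        report = score_predictions({"a": "nonessential"}, {"a": "nonessential"})
        assert report.metrics["precision"] is None  # no predicted positives

    def test_against_independent_confusion_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(2, 30))
            calls = {f"g{i}": rng.choice(["essential", "nonessential"]) for i in range(n)}
            gold = {f"g{i}": rng.choice(["essential", "nonessential", "unknown"])
                    for i in range(n)}
            report = score_predictions(calls, gold)
            tp = sum(calls[g] == "essential" and gold[g] == "essential" for g in calls)
            fp = sum(calls[g] == "essential" and gold[g] == "nonessential" for g in calls)
            tn = sum(calls[g] == "nonessential" and gold[g] == "nonessential" for g in calls)
            fn = sum(calls[g] == "nonessential" and gold[g] == "essential" for g in calls)
            unk = sum(gold[g] == "unknown" for g in calls)
            assert report.confusion == {
                "TP": tp, "FP": fp, "TN": tn, "FN": fn, "unclassified": unk
            }
            if tp + fp:
                assert report.metrics["precision"] == pytest.approx(
                    round(tp / (tp + fp), 2)
                )
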