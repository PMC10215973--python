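"""Growth phenotyping and gene-essentiality scoring.

Encodes a chemically defined holidic diet (HD) as exchange-bound
constraints: with flexible intake, the carbon source (sucrose analog) is
capped at ~2.212 mmol gDW⁻¹ h⁻¹, vitamins at 1/100 of it, the remaining
dietary substances (except salts and water) at 1/10, and oxygen at 24.
Nutrient titrations trace growth against one exchange bound; gene
essentiality screens single-gene knockouts at a growth-ratio cutoff
(default 30% of wild type), excluding genes found only in blocked
reactions, and scores calls against a gold standard with the standard
confusion-matrix metrics (sensitivity, specificity, precision, accuracy,
F1, MCC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .fluxsim import fba, fva, single_gene_deletion
from .model import DEFAULT_BOUND, MetabolicModel

__all__ = [
    "DietSpec",
    "EssentialityReport",
    "build_holidic_diet",
    "unlimited_diet",
    "titration_curve",
    "essentiality_screen",
    "score_predictions",
]

SUCROSE_UPTAKE_DEFAULT = 2.212
OXYGEN_UPTAKE_DEFAULT = 24.0
ESSENTIALITY_CUTOFF = 0.3

_CATEGORIES = ("carbon", "vitamin", "salt_water", "other")


@dataclass
class DietSpec:
    """Uptake bounds for a defined medium.

    ``entries`` maps an exchange reaction id to (category, max uptake in
    mmol gDW⁻¹ h⁻¹); exchanges not listed are closed to uptake.
    """

    entries: dict[str, tuple[str, float]] = field(default_factory=dict)
    oxygen_exchange: Optional[str] = None
    oxygen_max: float = OXYGEN_UPTAKE_DEFAULT
    ngam_flux: Optional[float] = None

    def apply(self, model: MetabolicModel) -> MetabolicModel:
        out = model.copy()
        for rxn in out.reactions.values():
            if rxn.is_exchange():
                rxn.lower_bound = max(rxn.lower_bound, 0.0)
        for rid, (_cat, max_uptake) in self.entries.items():
            out.reactions[rid].lower_bound = -abs(max_uptake)
        if self.oxygen_exchange and self.oxygen_exchange in out.reactions:
            out.reactions[self.oxygen_exchange].lower_bound = -abs(self.oxygen_max)
        if self.ngam_flux is not None and out.ngam_reaction_id:
            ngam = out.reactions[out.ngam_reaction_id]
            ngam.lower_bound = ngam.upper_bound = self.ngam_flux
        return out


def build_holidic_diet(
    composition: Union[pd.DataFrame, str, Path],
    sucrose_max: float = SUCROSE_UPTAKE_DEFAULT,
    flexible: bool = True,
    oxygen_exchange: Optional[str] = None,
    ngam_flux: Optional[float] = None,
) -> DietSpec:
    """Build a diet from a composition table.

    ``composition`` columns: ``exchange_id``, ``category`` (one of carbon,
    vitamin, salt_water, other), optional ``max_uptake``.  With
    ``flexible=True`` bounds derive from the carbon cap by category ratios
    (vitamins 1/100, other non-salt substances 1/10, salts/water
    unbounded); with ``flexible=False`` the measured ``max_uptake`` column
    is used verbatim.
    """
    if not isinstance(composition, pd.DataFrame):
        composition = pd.read_csv(composition, sep="\t")
    diet = DietSpec(oxygen_exchange=oxygen_exchange, ngam_flux=ngam_flux)
    for row in composition.itertuples(index=False):
        cat = row.category
        if cat not in _CATEGORIES:
            raise ValueError(f"unknown diet category {cat!r} for {row.exchange_id}")
        if flexible:
            bound = {
                "carbon": sucrose_max,
                "vitamin": sucrose_max / 100.0,
                "other": sucrose_max / 10.0,
                "salt_water": DEFAULT_BOUND,
            }[cat]
        else:
            bound = float(row.max_uptake)
        diet.entries[row.exchange_id] = (cat, bound)
    return diet


def unlimited_diet(model: MetabolicModel, ngam_flux: Optional[float] = None) -> DietSpec:
    """Infinite intake of every exchange metabolite (bounds at 1000)."""
    diet = DietSpec(ngam_flux=ngam_flux)
    for rxn in model.reactions.values():
        if rxn.is_exchange():
            diet.entries[rxn.id] = ("other", DEFAULT_BOUND)
    return diet


def titration_curve(
    model: MetabolicModel,
    diet: DietSpec,
    nutrient: str,
    grid: Iterable[float],
    min_fraction: float = 0.0,
) -> list[tuple[float, Optional[float]]]:
    """Growth across a grid of maximum uptake rates for one nutrient.

    With ``min_fraction > 0`` the minimum uptake is pinned to that fraction
    of the maximum (a flexible flux interval avoiding infeasibility at
    forced-consumption points).  Infeasible points are recorded as
    ``None``, distinct from zero growth.
    """
    base = diet.apply(model)
    if nutrient not in base.reactions or not base.reactions[nutrient].is_exchange():
        raise ValueError(f"{nutrient} is not an exchange reaction")
    curve = []
    for max_uptake in grid:
        point = base.copy()
        rxn = point.reactions[nutrient]
        rxn.lower_bound = -abs(max_uptake)
        rxn.upper_bound = -min_fraction * abs(max_uptake) if min_fraction > 0 else rxn.upper_bound
        sol = fba(point)
        curve.append((float(max_uptake), sol.objective_value if sol.optimal else None))
    return curve


@dataclass
class EssentialityReport:
    """Per-gene essentiality calls and (optionally) confusion metrics."""

    cutoff: float = ESSENTIALITY_CUTOFF
    wild_type_growth: float = 0.0
    growth_ratios: dict[str, float] = field(default_factory=dict)
    calls: dict[str, str] = field(default_factory=dict)  # essential | nonessential | excluded_blocked
    confusion: dict[str, int] = field(default_factory=dict)
    metrics: dict[str, Optional[float]] = field(default_factory=dict)

    @property
    def essential_genes(self) -> set[str]:
        return {g for g, c in self.calls.items() if c == "essential"}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(self.calls),
                "growth_ratio": [self.growth_ratios.get(g) for g in self.calls],
                "call": list(self.calls.values()),
            }
        ).sort_values("gene_id").reset_index(drop=True)


def essentiality_screen(
    model: MetabolicModel,
    diet: Optional[DietSpec] = None,
    cutoff: float = ESSENTIALITY_CUTOFF,
) -> EssentialityReport:
    """Classify every gene as essential / nonessential / excluded_blocked.

    Blocked reactions (flux-variability rule: |vmin| + |vmax| < 1e-5 under
    the diet) are found first; genes appearing only in blocked reactions
    are excluded — they cannot affect biomass formation.  The remaining
    genes are screened by single-gene deletion FBA and called essential
    when knockout growth falls below ``cutoff`` × wild type.
    """
    work = diet.apply(model) if diet is not None else model.copy()
    report = EssentialityReport(cutoff=cutoff)
    wt = fba(work)
    if not wt.optimal or wt.objective_value <= 0:
        raise RuntimeError("wild-type growth is zero; essentiality cutoff undefined")
    report.wild_type_growth = wt.objective_value

    blocked = fva(work).blocked
    excluded = {
        g
        for g in work.genes
        if all(r.id in blocked for r in work.reactions_for_gene(g))
    }
    for gene in sorted(excluded):
        report.calls[gene] = "excluded_blocked"

    screened = sorted(work.genes - excluded)
    growth = single_gene_deletion(work, screened)
    for gene in screened:
        ratio = growth[gene] / report.wild_type_growth
        report.growth_ratios[gene] = ratio
        report.calls[gene] = "essential" if ratio < cutoff else "nonessential"
    return report


def _round2(x: float) -> float:
    # round-half-even to 2 decimals, the convention for reported metrics
    return float(f"{round(x, 2):.2f}")


def score_predictions(
    calls: Union[EssentialityReport, dict[str, str]],
    gold: dict[str, str],
) -> EssentialityReport:
    """Confusion-matrix scoring of essentiality calls against a gold set.

    Gold labels are ``essential`` / ``nonessential`` / ``unknown``; genes
    with unknown labels (or absent from the gold set) count as
    unclassified and are excluded from every metric denominator.  Metrics
    are reported to two decimals; a zero denominator yields ``None``
    (undefined), never 0.
    """
    if isinstance(calls, EssentialityReport):
        report = calls
    else:
        report = EssentialityReport(calls=dict(calls))
    tp = fp = tn = fn = unclassified = 0
    for gene, call in report.calls.items():
        if call == "excluded_blocked":
            continue
        label = gold.get(gene, "unknown")
        if label == "unknown":
            unclassified += 1
        elif call == "essential":
            tp += label == "essential"
            fp += label == "nonessential"
        else:
            tn += label == "nonessential"
            fn += label == "essential"
    report.confusion = {
        "TP": tp, "FP": fp, "TN": tn, "FN": fn, "unclassified": unclassified
    }

    def ratio(num: float, den: float) -> Optional[float]:
        return _round2(num / den) if den else None

    precision = tp / (tp + fp) if tp + fp else None
    sensitivity = tp / (tp + fn) if tp + fn else None
    report.metrics = {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "precision": ratio(tp, tp + fp),
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "f1": (
            _round2(2 * precision * sensitivity / (precision + sensitivity))
            if precision is not None and sensitivity is not None
            and (precision + sensitivity) > 0
            else None
        ),
        "mcc": (
            _round2(
                (tp * tn - fp * fn)
                / math.sqrt(
                    float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
                )
            )
            if min(tp + fp, tp + fn, tn + fp, tn + fn) > 0
            else None
        ),
    }
    return report
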