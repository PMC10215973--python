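"""Readers and writers for constraint-based models.

Two on-disk formats are supported:

* SBML Level 3 with the ``fbc`` package (flux bounds as parameters, GPR as
  gene-product associations).  On read, a rule embedded in the reaction
  notes as ``GENE_ASSOCIATION: ...`` (the older dialect still found in
  published insect models) is accepted when no fbc association is present.
* A JSON dialect with top-level keys ``compartments``, ``metabolites``,
  ``reactions``, ``genes``, ``biomass``, ``objective``; each reaction
  carries ``id``, ``name``, ``metabolites``, ``lower_bound``,
  ``upper_bound``, ``gene_reaction_rule``, ``subsystem``.

Round-tripping either format preserves stoichiometry, bounds, GPR truth
tables and the objective exactly.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional, Union

import libsbml

from .gpr import gpr_to_string, parse_gpr
from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelIntegrityError,
    Reaction,
)

__all__ = ["read_model", "write_model", "read_json", "write_json", "read_sbml", "write_sbml"]


class ParseError(ValueError):
    """A model file is malformed."""


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def read_json(path: Union[str, Path]) -> MetabolicModel:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc

    model = MetabolicModel(id=data.get("id", Path(path).stem))
    model.compartments = dict(data.get("compartments", {}))
    for m in data.get("metabolites", []):
        model.add_metabolite(
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=m.get("formula"),
                xrefs={ns: set(v) for ns, v in m.get("xrefs", {}).items()},
                synonyms=set(m.get("synonyms", [])),
            )
        )
    for r in data.get("reactions", []):
        rev_default = -DEFAULT_BOUND if r.get("reversible") else 0.0
        model.add_reaction(
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                lower_bound=float(r.get("lower_bound", rev_default)),
                upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                gpr=parse_gpr(r.get("gene_reaction_rule", "")),
                subsystem=r.get("subsystem", ""),
                origin=r.get("origin", "template"),
            )
        )
    model.biomass_reaction_id = data.get("biomass")
    obj = data.get("objective")
    if isinstance(obj, dict):
        model.objective_reaction_id = obj.get("reaction")
        model.objective_sense = obj.get("sense", "max")
    elif isinstance(obj, str):
        model.objective_reaction_id = obj
    model.ngam_reaction_id = data.get("ngam")
    model.validate()
    return model


def write_json(model: MetabolicModel, path: Union[str, Path]) -> None:
    data = {
        "id": model.id,
        "compartments": model.compartments,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"formula": m.formula} if m.formula else {}),
                **(
                    {"xrefs": {ns: sorted(v) for ns, v in m.xrefs.items()}}
                    if m.xrefs
                    else {}
                ),
                **({"synonyms": sorted(m.synonyms)} if m.synonyms else {}),
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gene_reaction_rule,
                "subsystem": r.subsystem,
                "origin": r.origin,
            }
            for r in model.reactions.values()
        ],
        "genes": sorted(model.genes),
        "biomass": model.biomass_reaction_id,
        "objective": {
            "reaction": model.objective_reaction_id or model.biomass_reaction_id,
            "sense": model.objective_sense,
        },
        "ngam": model.ngam_reaction_id,
    }
    Path(path).write_text(json.dumps(data, indent=1))


# ---------------------------------------------------------------------------
# SBML (Level 3 + fbc)
# ---------------------------------------------------------------------------

_SID_OK = re.compile(r"[A-Za-z0-9_]")


def _encode_sid(raw: str, prefix: str) -> str:
    """Escape an arbitrary identifier into a valid SBML SId, reversibly."""
    out = []
    for ch in raw:
        out.append(ch if _SID_OK.match(ch) else f"__{ord(ch)}__")
    return prefix + "".join(out)


_DECODE_RE = re.compile(r"__(\d+)__")


def _decode_sid(sid: str, prefix: str) -> str:
    body = sid[len(prefix):] if sid.startswith(prefix) else sid
    return _DECODE_RE.sub(lambda m: chr(int(m.group(1))), body)


def _gpr_from_fbc(assoc) -> Optional[str]:
    if assoc is None:
        return None

    def rec(node) -> str:
        if node.isGeneProductRef():
            return _decode_sid(node.getGeneProduct(), "G_")
        parts = [rec(node.getAssociation(i)) for i in range(node.getNumAssociations())]
        op = " and " if node.isFbcAnd() else " or "
        return "(" + op.join(parts) + ")"

    return rec(assoc.getAssociation())


_NOTES_GPR_RE = re.compile(
    r"GENE[ _]?ASSOCIATION\s*:\s*([^<\n]+)", re.IGNORECASE
)


def read_sbml(path: Union[str, Path]) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ParseError(
            f"{path}: SBML error at line {err.getLine()}: {err.getMessage().strip()}"
        )
    smodel = doc.getModel()
    if smodel is None:
        raise ParseError(f"{path}: file contains no SBML model element")

    model = MetabolicModel(id=smodel.getId() or Path(path).stem)
    for i in range(smodel.getNumCompartments()):
        comp = smodel.getCompartment(i)
        model.compartments[comp.getId()] = comp.getName() or comp.getId()

    for i in range(smodel.getNumSpecies()):
        sp = smodel.getSpecies(i)
        if sp.getBoundaryCondition():
            continue
        model.add_metabolite(
            Metabolite(
                id=_decode_sid(sp.getId(), "M_"),
                name=sp.getName(),
                compartment=sp.getCompartment(),
            )
        )

    mplug = smodel.getPlugin("fbc")
    for i in range(smodel.getNumReactions()):
        srxn = smodel.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(srxn.getNumReactants()):
            ref = srxn.getReactant(j)
            mid = _decode_sid(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(srxn.getNumProducts()):
            ref = srxn.getProduct(j)
            mid = _decode_sid(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0}

        rplug = srxn.getPlugin("fbc")
        lb, ub = None, None
        if rplug is not None:
            for attr, setter in (("LowerFluxBound", "lb"), ("UpperFluxBound", "ub")):
                pid = getattr(rplug, f"get{attr}")()
                if pid:
                    par = smodel.getParameter(pid)
                    if par is not None:
                        if setter == "lb":
                            lb = par.getValue()
                        else:
                            ub = par.getValue()
        if lb is None:
            lb = -DEFAULT_BOUND if srxn.getReversible() else 0.0
        if ub is None:
            ub = DEFAULT_BOUND

        rule: Optional[str] = None
        if rplug is not None:
            rule = _gpr_from_fbc(rplug.getGeneProductAssociation())
        if rule is None and srxn.isSetNotes():
            match = _NOTES_GPR_RE.search(srxn.getNotesString())
            if match:
                rule = match.group(1).strip()

        model.add_reaction(
            Reaction(
                id=_decode_sid(srxn.getId(), "R_"),
                name=srxn.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=parse_gpr(rule or ""),
            )
        )

    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getActiveObjective() or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            rid = _decode_sid(obj.getFluxObjective(0).getReaction(), "R_")
            model.objective_reaction_id = rid
            model.biomass_reaction_id = model.biomass_reaction_id or rid
            model.objective_sense = (
                "min" if obj.getType() == libsbml.OBJECTIVE_TYPE_MINIMIZE else "max"
            )
    model.validate()
    return model


def write_sbml(model: MetabolicModel, path: Union[str, Path]) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    smodel = doc.createModel()
    smodel.setId(_encode_sid(model.id, ""))
    mplug = smodel.getPlugin("fbc")
    mplug.setStrict(True)

    comps = model.compartments or {
        c: c for c in sorted({m.compartment for m in model.metabolites.values()})
    }
    for cid, cname in comps.items():
        comp = smodel.createCompartment()
        comp.setId(cid)
        comp.setName(cname)
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = smodel.createSpecies()
        sp.setId(_encode_sid(met.id, "M_"))
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)

    bounds_seen: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bounds_seen:
            pid = f"fb_{len(bounds_seen)}"
            par = smodel.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bounds_seen[value] = pid
        return bounds_seen[value]

    for gene in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gp.setId(_encode_sid(gene, "G_"))
        gp.setLabel(gene)

    for rxn in model.reactions.values():
        srxn = smodel.createReaction()
        srxn.setId(_encode_sid(rxn.id, "R_"))
        srxn.setName(rxn.name)
        srxn.setFast(False)
        srxn.setReversible(rxn.reversible)
        for met, coef in rxn.stoichiometry.items():
            ref = srxn.createReactant() if coef < 0 else srxn.createProduct()
            ref.setSpecies(_encode_sid(met, "M_"))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = srxn.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr is not None:
            assoc = rplug.createGeneProductAssociation()
            rule = gpr_to_string(rxn.gpr)
            encoded = re.sub(
                r"[^\s()]+",
                lambda m: m.group(0)
                if m.group(0).lower() in ("and", "or")
                else _encode_sid(m.group(0), "G_"),
                rule,
            )
            # match registered gene products by id, never auto-create
            assoc.setAssociation(encoded, True, False)

    obj_rid = model.objective_reaction_id or model.biomass_reaction_id
    if obj_rid is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("minimize" if model.objective_sense == "min" else "maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(_encode_sid(obj_rid, "R_"))
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def _infer_format(path: Union[str, Path]) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix == ".json":
        return "json"
    raise ValueError(f"cannot infer model format from {path}")


def read_model(path: Union[str, Path], format: Optional[str] = None) -> MetabolicModel:
    """Read a model from SBML or the JSON dialect.

    Raises :class:`ParseError` on malformed input and
    :class:`ModelIntegrityError` on dangling references.
    """
    fmt = format or _infer_format(path)
    if fmt == "sbml":
        return read_sbml(path)
    if fmt == "json":
        return read_json(path)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path: Union[str, Path], format: Optional[str] = None) -> None:
    fmt = format or _infer_format(path)
    if fmt == "sbml":
        write_sbml(model, path)
    elif fmt == "json":
        write_json(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")
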