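"""SBML Level 3 import/export (fbc v2 flux bounds and gene associations).

The round trip preserves stoichiometry, bounds and gene rules; models
written here load in any fbc-aware tool.  Documents lacking explicit
flux bounds import with default bounds and a logged warning.
"""

from __future__ import annotations

import logging

import libsbml

from .model import (
    DEFAULT_BOUND,
    EnergeticsConfig,
    Metabolite,
    ModelValidationError,
    Reaction,
    StoichiometricModel,
    format_formula,
    parse_formula,
)
from .overlay import parse_gene_rule

logger = logging.getLogger(__name__)

__all__ = ["export_sbml", "import_sbml", "write_sbml_file", "read_sbml_file"]

_SBML_LEVEL, _SBML_VERSION, _FBC_VERSION = 3, 1, 2


def _check(value, message: str):
    if value is None:
        raise RuntimeError(f"libsbml returned None: {message}")
    if isinstance(value, int) and value != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise RuntimeError(f"libsbml error {value}: {message}")
    return value


def _sid(token: str) -> str:
    """SBML ids cannot start with a digit; prefix such tokens."""
    out = "".join(ch if (ch.isalnum() or ch == "_") else "_" for ch in token)
    if out and out[0].isdigit():
        out = "_" + out
    return out


def _unsid(sid: str, known: set[str]) -> str:
    if sid in known:
        return sid
    if sid.startswith("_") and sid[1:] in known:
        return sid[1:]
    return sid


def _rule_to_association(node, fbc_rxn):
    gpa = fbc_rxn.createGeneProductAssociation()

    def build(n, parent):
        if n[0] == "gene":
            ref = parent.createGeneProductRef()
            ref.setGeneProduct(_sid("G_" + n[1]))
        elif n[0] == "and":
            op = parent.createAnd()
            for child in n[1]:
                build(child, op)
        else:
            op = parent.createOr()
            for child in n[1]:
                build(child, op)

    build(node, gpa)


def _association_to_rule(assoc) -> str:
    if assoc is None:
        return ""

    def walk(node) -> str:
        if node.isGeneProductRef():
            gid = node.getGeneProduct()
            return gid[2:] if gid.startswith("G_") else gid
        parts = [walk(node.getAssociation(i)) for i in range(node.getNumAssociations())]
        joiner = " and " if node.isFbcAnd() else " or "
        return "(" + joiner.join(parts) + ")"

    text = walk(assoc.getAssociation())
    return text[1:-1] if text.startswith("(") and text.endswith(")") else text


def export_sbml(model: StoichiometricModel) -> str:
    """Serialize a model as an SBML L3V1 + fbc v2 document string."""
    ns = libsbml.SBMLNamespaces(_SBML_LEVEL, _SBML_VERSION, "fbc", _FBC_VERSION)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = _check(doc.createModel(), "createModel")
    sm.setId(_sid(model.id))
    fbc = sm.getPlugin("fbc")
    fbc.setStrict(True)

    compartments = sorted({m.compartment for m in model.metabolites.values()}) or ["c"]
    for comp in compartments:
        c = sm.createCompartment()
        c.setId(comp)
        c.setConstant(True)

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId(_sid("M_" + met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        plug = sp.getPlugin("fbc")
        if met.formula is not None:
            plug.setChemicalFormula(format_formula(met.formula))
        if met.charge is not None:
            plug.setCharge(met.charge)

    genes = sorted({g for r in model.reactions.values() for g in r.genes()})
    for gene in genes:
        gp = fbc.createGeneProduct()
        gp.setId(_sid("G_" + gene))
        gp.setLabel(gene)

    bounds_seen: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bounds_seen:
            pid = f"fb_{len(bounds_seen)}"
            par = sm.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bounds_seen[value] = pid
        return bounds_seen[value]

    for rxn in model.reactions.values():
        sr = sm.createReaction()
        sr.setId(_sid("R_" + rxn.id))
        sr.setName(rxn.name or rxn.id)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        for met, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(_sid("M_" + met))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        plug = sr.getPlugin("fbc")
        plug.setLowerFluxBound(bound_param(rxn.lower_bound))
        plug.setUpperFluxBound(bound_param(rxn.upper_bound))
        node = parse_gene_rule(rxn.gene_rule)
        if node is not None:
            _rule_to_association(node, plug)
        if rxn.subsystem:
            sr.appendNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml">'
                f"<p>SUBSYSTEM: {rxn.subsystem}</p></body>"
            )

    if model.objective:
        obj = fbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        for rid, weight in model.objective.items():
            fo = obj.createFluxObjective()
            fo.setReaction(_sid("R_" + rid))
            fo.setCoefficient(weight)
        fbc.setActiveObjectiveId("obj")

    return libsbml.writeSBMLToString(doc)


def import_sbml(text: str) -> StoichiometricModel:
    """Parse an SBML document string back into a model."""
    doc = libsbml.readSBMLFromString(text)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ModelValidationError(
            "SBML parse error: "
            + doc.getErrorLog().toString()
        )
    sm = doc.getModel()
    if sm is None:
        raise ModelValidationError("SBML document contains no model")
    model = StoichiometricModel(id=sm.getId() or "model")
    model.parameters = EnergeticsConfig()

    params = {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }

    met_ids: set[str] = set()
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        mid = sp.getId()
        if mid.startswith("M_"):
            mid = mid[2:]
        plug = sp.getPlugin("fbc")
        formula = None
        charge = None
        if plug is not None:
            if plug.isSetChemicalFormula():
                formula = parse_formula(plug.getChemicalFormula())
            if plug.isSetCharge():
                charge = plug.getCharge()
        met_ids.add(mid)
        model.add_metabolite(
            Metabolite(id=mid, name=sp.getName(), formula=formula, charge=charge)
        )

    missing_bounds = 0
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        rid = sr.getId()
        if rid.startswith("R_"):
            rid = rid[2:]
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            mid = _unsid(ref.getSpecies()[2:] if ref.getSpecies().startswith("M_") else ref.getSpecies(), met_ids)
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            mid = _unsid(ref.getSpecies()[2:] if ref.getSpecies().startswith("M_") else ref.getSpecies(), met_ids)
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0}
        plug = sr.getPlugin("fbc")
        lb = ub = None
        rule = ""
        if plug is not None:
            if plug.isSetLowerFluxBound():
                lb = params.get(plug.getLowerFluxBound())
            if plug.isSetUpperFluxBound():
                ub = params.get(plug.getUpperFluxBound())
            rule = _association_to_rule(plug.getGeneProductAssociation())
        if lb is None or ub is None:
            missing_bounds += 1
            lb = -DEFAULT_BOUND if sr.getReversible() else 0.0
            ub = DEFAULT_BOUND
        subsystem = ""
        if sr.isSetNotes():
            notes = sr.getNotesString()
            marker = "SUBSYSTEM: "
            if marker in notes:
                subsystem = notes.split(marker, 1)[1].split("<", 1)[0].strip()
        model.add_reaction(
            Reaction(
                id=rid,
                name=sr.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gene_rule=rule,
                subsystem=subsystem,
            )
        )
    if missing_bounds:
        logger.warning(
            "SBML import: %d reactions lacked explicit flux bounds; defaults applied",
            missing_bounds,
        )

    fbc = sm.getPlugin("fbc")
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getObjective(fbc.getActiveObjectiveId()) or fbc.getObjective(0)
        if obj is not None:
            for j in range(obj.getNumFluxObjectives()):
                fo = obj.getFluxObjective(j)
                rid = fo.getReaction()
                if rid.startswith("R_"):
                    rid = rid[2:]
                model.objective[rid] = fo.getCoefficient()
    model.validate()
    return model


def write_sbml_file(model: StoichiometricModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(export_sbml(model))


def read_sbml_file(path) -> StoichiometricModel:
    with open(path) as fh:
        return import_sbml(fh.read())
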