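"""Model readers and writers: SBML L3V1 with FBC v2, and a native JSON dialect.

The SBML support covers the subset genome-scale models actually use:
compartments, species, reactions with stoichiometry, flux bounds expressed
as FBC parameters, ``geneProductAssociation`` trees, and the active FBC
objective.  Unrecognized annotations are ignored rather than rejected.

The native JSON schema (documented in the README) is a faithful dump of
:class:`~gemsmith.model_core.MetabolicModel`; write followed by read is the
identity.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import libsbml

from .gpr import Gpr, parse_gpr
from .model_core import (
    DEFAULT_LB,
    DEFAULT_UB,
    MetabolicModel,
    Metabolite,
    Reaction,
)

__all__ = ["read_model", "write_model", "ModelParseError", "ModelReferenceError"]


class ModelParseError(ValueError):
    """Malformed model file."""


class ModelReferenceError(ValueError):
    """A bound parameter or gene-product reference did not resolve."""


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a model from ``path`` in ``sbml-fbc`` or ``native-json`` format.

    When ``format`` is None it is inferred from the file suffix
    (``.xml``/``.sbml`` -> SBML, ``.json`` -> native JSON).
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "sbml-fbc":
        return _read_sbml(path)
    if fmt == "native-json":
        return _read_json(path)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "sbml-fbc":
        _write_sbml(model, path)
    elif fmt == "native-json":
        _write_json(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


def _infer_format(path: Path) -> str:
    if path.suffix.lower() in (".xml", ".sbml"):
        return "sbml-fbc"
    if path.suffix.lower() == ".json":
        return "native-json"
    raise ValueError(f"cannot infer model format from suffix of {path}")


# ---------------------------------------------------------------------------
# native JSON
# ---------------------------------------------------------------------------

def _read_json(path: Path) -> MetabolicModel:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"malformed JSON in {path}: {exc}") from exc
    try:
        mets = {
            m["id"]: Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=m.get("formula"),
                charge=m.get("charge"),
                annotations=m.get("annotations", {}),
            )
            for m in data["metabolites"]
        }
        rxns = {}
        for r in data["reactions"]:
            gpr = parse_gpr(r["gpr"]) if r.get("gpr") else None
            rxns[r["id"]] = Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r.get("lower_bound", DEFAULT_LB)),
                upper_bound=float(r.get("upper_bound", DEFAULT_UB)),
                gpr=gpr,
                subsystem=r.get("subsystem", ""),
                kind=r.get("kind", "enzymatic"),
            )
    except KeyError as exc:
        raise ModelParseError(f"missing element {exc} in {path}") from exc
    declared = data.get("genes")
    return MetabolicModel(
        id=data.get("id", path.stem),
        metabolites=mets,
        reactions=rxns,
        objective_reaction_id=data.get("objective"),
        compartments=data.get("compartments", {}),
        declared_genes=frozenset(declared) if declared is not None else None,
    )


def _write_json(model: MetabolicModel, path: Path) -> None:
    data = {
        "id": model.id,
        "compartments": model.compartments,
        "objective": model.objective_reaction_id,
        "genes": sorted(model.genes),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"formula": m.formula} if m.formula else {}),
                **({"charge": m.charge} if m.charge is not None else {}),
                **({"annotations": m.annotations} if m.annotations else {}),
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr.to_string() if r.gpr is not None else None,
                "subsystem": r.subsystem,
                "kind": r.kind,
            }
            for r in model.reactions.values()
        ],
    }
    Path(path).write_text(json.dumps(data, indent=1))


# ---------------------------------------------------------------------------
# SBML L3V1 FBC v2
# ---------------------------------------------------------------------------

def _read_sbml(path: Path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors() > 0:
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise ModelParseError(
                    f"SBML error in {path}: {err.getMessage().strip()}"
                )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"no <model> element in {path}")
    fbc = sbml_model.getPlugin("fbc")

    compartments = {
        c.getId(): c.getName() or c.getId()
        for c in (sbml_model.getCompartment(i) for i in range(sbml_model.getNumCompartments()))
    }
    params = {
        p.getId(): p.getValue()
        for p in (sbml_model.getParameter(i) for i in range(sbml_model.getNumParameters()))
    }

    gene_products: dict[str, str] = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            gene_products[gp.getId()] = gp.getLabel() or gp.getId()

    mets: dict[str, Metabolite] = {}
    boundary: set[str] = set()
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        sfbc = sp.getPlugin("fbc")
        formula = None
        charge = None
        if sfbc is not None:
            if sfbc.isSetChemicalFormula():
                formula = sfbc.getChemicalFormula()
            if sfbc.isSetCharge():
                charge = sfbc.getCharge()
        if sp.getBoundaryCondition():
            boundary.add(sp.getId())
            continue
        mets[sp.getId()] = Metabolite(
            id=sp.getId(),
            name=sp.getName() or sp.getId(),
            compartment=sp.getCompartment(),
            formula=formula,
            charge=charge,
        )

    objective_rxn = None
    if fbc is not None:
        obj = fbc.getActiveObjective()
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective_rxn = obj.getFluxObjective(0).getReaction()

    rxns: dict[str, Reaction] = {}
    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            if ref.getSpecies() in boundary:
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            if ref.getSpecies() in boundary:
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0.0}

        rfbc = sr.getPlugin("fbc")
        lb, ub = None, None
        gpr: Gpr | None = None
        if rfbc is not None:
            if rfbc.isSetLowerFluxBound():
                ref = rfbc.getLowerFluxBound()
                if ref not in params:
                    raise ModelReferenceError(
                        f"reaction {sr.getId()!r}: unresolved bound parameter {ref!r}"
                    )
                lb = params[ref]
            if rfbc.isSetUpperFluxBound():
                ref = rfbc.getUpperFluxBound()
                if ref not in params:
                    raise ModelReferenceError(
                        f"reaction {sr.getId()!r}: unresolved bound parameter {ref!r}"
                    )
                ub = params[ref]
            gpa = rfbc.getGeneProductAssociation()
            if gpa is not None:
                gpr = _gpa_to_gpr(gpa.getAssociation(), gene_products, sr.getId())
        if lb is None:
            lb = DEFAULT_LB if sr.getReversible() else 0.0
        if ub is None:
            ub = DEFAULT_UB
        if math.isinf(lb):
            lb = DEFAULT_LB if lb < 0 else DEFAULT_UB
        if math.isinf(ub):
            ub = DEFAULT_UB if ub > 0 else DEFAULT_LB

        kind = _classify_kind(sr.getId(), stoich, gpr)
        rxns[sr.getId()] = Reaction(
            id=sr.getId(),
            name=sr.getName() or sr.getId(),
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            gpr=gpr,
            subsystem="",
            kind=kind,
        )

    return MetabolicModel(
        id=sbml_model.getId() or path.stem,
        metabolites=mets,
        reactions=rxns,
        objective_reaction_id=objective_rxn,
        compartments=compartments,
        declared_genes=frozenset(gene_products.values()) if gene_products else None,
    )


def _classify_kind(rid: str, stoich: dict[str, float], gpr: Gpr | None) -> str:
    # id/subsystem convention: exchanges carry one metabolite; pseudo
    # reactions are recognized by conventional id substrings.
    if len(stoich) == 1:
        return "exchange"
    low = rid.lower()
    if "biomass" in low or low.startswith(("dm_", "sk_")) or "pseudo" in low:
        return "pseudo"
    if gpr is None:
        return "spontaneous"
    return "enzymatic"


def _gpa_to_gpr(assoc, gene_products: dict[str, str], rxn_id: str) -> Gpr | None:
    if assoc is None:
        return None
    if isinstance(assoc, libsbml.GeneProductRef):
        ref = assoc.getGeneProduct()
        if ref not in gene_products:
            raise ModelReferenceError(
                f"reaction {rxn_id!r}: unresolved gene product {ref!r}"
            )
        return Gpr.leaf(gene_products[ref])
    children = [
        _gpa_to_gpr(assoc.getAssociation(i), gene_products, rxn_id)
        for i in range(assoc.getNumAssociations())
    ]
    children = [c for c in children if c is not None]
    if not children:
        return None
    if isinstance(assoc, libsbml.FbcAnd):
        return Gpr.and_(children)
    if isinstance(assoc, libsbml.FbcOr):
        return Gpr.or_(children)
    raise ModelParseError(
        f"reaction {rxn_id!r}: unsupported gene association node {type(assoc)}"
    )


def _sid(raw: str) -> str:
    """Coerce an identifier into a valid SBML SId."""
    out = "".join(ch if ch.isalnum() or ch == "_" else "_" for ch in raw)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "x_" + out
    return out


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sid(model.id))
    mfbc = sm.getPlugin("fbc")
    mfbc.setStrict(True)

    comps = model.compartments or {"c": "cytosol"}
    for cid, cname in comps.items():
        c = sm.createCompartment()
        c.setId(_sid(cid))
        c.setName(cname)
        c.setConstant(True)
        c.setSize(1.0)

    known_comps = set(comps)
    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId(_sid(met.id))
        sp.setName(met.name or met.id)
        comp = met.compartment if met.compartment in known_comps else next(iter(known_comps))
        sp.setCompartment(_sid(comp))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sfbc = sp.getPlugin("fbc")
        if met.formula:
            sfbc.setChemicalFormula(met.formula)
        if met.charge is not None:
            sfbc.setCharge(met.charge)

    # distinct bound values become shared parameters
    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    gene_ids: dict[str, str] = {}
    for g in sorted(model.genes):
        gid = _sid(f"G_{g}")
        gp = mfbc.createGeneProduct()
        gp.setId(gid)
        gp.setLabel(g)
        gene_ids[g] = gid

    for rxn in model.reactions.values():
        sr = sm.createReaction()
        sr.setId(_sid(rxn.id))
        sr.setName(rxn.name or rxn.id)
        sr.setFast(False)
        sr.setReversible(rxn.lower_bound < 0)
        for met_id, coeff in rxn.stoichiometry.items():
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies(_sid(met_id))
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rfbc = sr.getPlugin("fbc")
        rfbc.setLowerFluxBound(bound_param(rxn.lower_bound))
        rfbc.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr is not None:
            gpa = rfbc.createGeneProductAssociation()
            gpa.setAssociation(_gpr_to_infix(rxn.gpr, gene_ids), True)

    if model.objective_reaction_id is not None:
        obj = mfbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(_sid(model.objective_reaction_id))
        fo.setCoefficient(1.0)
        mfbc.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


def _gpr_to_infix(gpr: Gpr, gene_ids: dict[str, str]) -> str:
    if gpr.op == "gene":
        return gene_ids[gpr.gene]
    parts = [f"({_gpr_to_infix(c, gene_ids)})" for c in gpr.children]
    return f" {gpr.op} ".join(parts)
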