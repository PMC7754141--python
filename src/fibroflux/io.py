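"""Model readers and writers: JSON dialect and SBML Level 3 + FBC v2.

The JSON dialect mirrors the community constraint-based JSON schema
(metabolites / reactions / genes arrays; per-reaction ``metabolites`` map,
``lower_bound`` / ``upper_bound``, ``gene_reaction_rule``), so files written
here load directly into other constraint-based toolkits and published
genome-scale models in that schema load here.  SBML goes through libsbml
with the FBC v2 flux-bound and gene-product-association extensions.
"""

from __future__ import annotations

import json
from pathlib import Path

from .model import (
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    gpr_genes,
)

__all__ = ["read_model", "write_model", "ModelParseError"]


class ModelParseError(ValueError):
    """A model file could not be parsed; the message names the element."""


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a model from ``path``; format 'json' or 'sbml' (from suffix if None)."""
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt == "json":
        model = _read_json(path)
    elif fmt == "sbml":
        model = _read_sbml(path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")
    try:
        model.validate()
    except ModelValidationError as exc:
        raise ModelValidationError(f"{path}: {exc}") from None
    return model


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> Path:
    """Write a model; output is byte-stable for a fixed input model."""
    model.validate()
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt == "json":
        _write_json(model, path)
    elif fmt == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")
    return path


def _guess_format(path: Path) -> str:
    if path.suffix.lower() == ".json":
        return "json"
    if path.suffix.lower() in (".xml", ".sbml"):
        return "sbml"
    raise ValueError(f"cannot guess model format from {path.name!r}")


# ----------------------------------------------------------------- JSON side
def _read_json(path: Path) -> MetabolicModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"{path}: not valid JSON: {exc}") from None
    for key in ("metabolites", "reactions"):
        if key not in doc:
            raise ModelParseError(f"{path}: missing top-level {key!r} array")
    mets = [
        Metabolite(
            id=m["id"],
            name=m.get("name", ""),
            compartment=m.get("compartment", ""),
        )
        for m in doc["metabolites"]
    ]
    rxns = []
    objective = None
    sense = doc.get("objective_sense", "max")
    for r in doc["reactions"]:
        try:
            rxn = Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                lower_bound=float(r.get("lower_bound", -1000.0)),
                upper_bound=float(r.get("upper_bound", 1000.0)),
                gpr=r.get("gene_reaction_rule", ""),
                subsystem=r.get("subsystem", ""),
                name=r.get("name", ""),
                objective_coefficient=float(r.get("objective_coefficient", 0.0)),
            )
        except KeyError as exc:
            raise ModelParseError(f"{path}: reaction entry missing key {exc}") from None
        if rxn.objective_coefficient != 0.0:
            objective = rxn.id
        rxns.append(rxn)
    genes = [g["id"] if isinstance(g, dict) else str(g) for g in doc.get("genes", [])]
    if not genes:
        genes = sorted({g for r in rxns for g in gpr_genes(r.gpr)})
    return MetabolicModel(
        id=doc.get("id", path.stem),
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        objective=objective,
        objective_sense=sense,
    )


def _write_json(model: MetabolicModel, path: Path) -> None:
    doc = {
        "id": model.id,
        "version": "1",
        "objective_sense": model.objective_sense,
        "compartments": {
            c: c for c in sorted({m.compartment for m in model.metabolites if m.compartment})
        },
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": {k: float(r.stoichiometry[k]) for k in sorted(r.stoichiometry)},
                "lower_bound": float(r.lower_bound),
                "upper_bound": float(r.upper_bound),
                "gene_reaction_rule": r.gpr,
                "subsystem": r.subsystem,
                "objective_coefficient": (
                    1.0 if model.objective == r.id else r.objective_coefficient
                ),
            }
            for r in model.reactions
        ],
        "genes": [{"id": g, "name": g} for g in model.genes],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


# ----------------------------------------------------------------- SBML side
# SBML component ids cannot contain '(' / ')'; Recon-style ids such as
# "EX_glc(e)" are escaped with the COBRA convention _LPAREN_/_RPAREN_.
_SBML_ESCAPES = [("(", "_LPAREN_"), (")", "_RPAREN_"), ("[", "_LSQBKT_"), ("]", "_RSQBKT_")]


def _sbml_escape(raw: str) -> str:
    out = raw
    for char, token in _SBML_ESCAPES:
        out = out.replace(char, token)
    return out


def _sbml_unescape(escaped: str) -> str:
    out = escaped
    for char, token in _SBML_ESCAPES:
        out = out.replace(token, char)
    return out


def _read_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(f"{path}: SBML error: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"{path}: file contains no SBML model element")

    mets = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            continue
        mets.append(
            Metabolite(
                id=_strip_prefix(_sbml_unescape(sp.getId()), "M_"),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "",
            )
        )
    known = {m.id for m in mets}
    boundary = {
        _strip_prefix(_sbml_unescape(sbml_model.getSpecies(i).getId()), "M_")
        for i in range(sbml_model.getNumSpecies())
        if sbml_model.getSpecies(i).getBoundaryCondition()
    }

    fbc = sbml_model.getPlugin("fbc")
    genes: list[str] = []
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            genes.append(_sbml_unescape(_strip_prefix(fbc.getGeneProduct(i).getId(), "G_FBC_")))

    objective_id = None
    sense = "max"
    obj_targets: dict[str, float] = {}
    if fbc is not None and fbc.getActiveObjective() is not None:
        obj = fbc.getActiveObjective()
        sense = "max" if obj.getType() == "maximize" else "min"
        for i in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(i)
            obj_targets[fo.getReaction()] = fo.getCoefficient()

    rxns = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            mid = _strip_prefix(_sbml_unescape(ref.getSpecies()), "M_")
            if mid in boundary:
                continue
            if mid not in known:
                raise ModelValidationError(
                    f"{path}: reaction {rx.getId()!r} cites undeclared species {mid!r}"
                )
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            mid = _strip_prefix(_sbml_unescape(ref.getSpecies()), "M_")
            if mid in boundary:
                continue
            if mid not in known:
                raise ModelValidationError(
                    f"{path}: reaction {rx.getId()!r} cites undeclared species {mid!r}"
                )
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()

        rfbc = rx.getPlugin("fbc")
        lb, ub = -1000.0, 1000.0
        gpr = ""
        if rfbc is not None:
            lbp = sbml_model.getParameter(rfbc.getLowerFluxBound() or "")
            ubp = sbml_model.getParameter(rfbc.getUpperFluxBound() or "")
            if lbp is not None:
                lb = lbp.getValue()
            if ubp is not None:
                ub = ubp.getValue()
            gpa = rfbc.getGeneProductAssociation()
            if gpa is not None:
                gpr = _association_to_gpr(gpa.getAssociation())
        rid = _strip_prefix(_sbml_unescape(rx.getId()), "R_")
        rxn = Reaction(
            id=rid,
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            gpr=gpr,
            name=rx.getName() or "",
            objective_coefficient=obj_targets.get(rx.getId(), 0.0),
        )
        if rxn.objective_coefficient != 0.0:
            objective_id = rid
        rxns.append(rxn)

    if not genes:
        genes = sorted({g for r in rxns for g in gpr_genes(r.gpr)})
    return MetabolicModel(
        id=sbml_model.getId() or path.stem,
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        objective=objective_id,
        objective_sense=sense,
    )


def _strip_prefix(text: str, prefix: str) -> str:
    return text[len(prefix):] if text.startswith(prefix) else text


def _association_to_gpr(assoc) -> str:
    import libsbml

    if assoc is None:
        return ""
    if isinstance(assoc, libsbml.GeneProductRef):
        return _sbml_unescape(_strip_prefix(assoc.getGeneProduct(), "G_FBC_"))
    parts = [_association_to_gpr(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())]
    joiner = " and " if isinstance(assoc, libsbml.FbcAnd) else " or "
    return "(" + joiner.join(parts) + ")"


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sbml_escape(model.id))
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = sorted({m.compartment or "c" for m in model.metabolites})
    for comp in compartments:
        c = sbml_model.createCompartment()
        c.setId(comp)
        c.setConstant(True)

    for met in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId("M_" + _sbml_escape(met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment or "c")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    for gene in model.genes:
        gp = mplug.createGeneProduct()
        gp.setId("G_FBC_" + _sbml_escape(gene))
        gp.setLabel(gene)

    # unique flux-bound parameters per distinct value
    bound_params: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"FB_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        rx = sbml_model.createReaction()
        rx.setId("R_" + _sbml_escape(rxn.id))
        rx.setName(rxn.name or rxn.id)
        rx.setFast(False)
        rx.setReversible(rxn.lower_bound < 0)
        for mid, coeff in sorted(rxn.stoichiometry.items()):
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies("M_" + _sbml_escape(mid))
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(_bound_param(rxn.upper_bound))
        if rxn.gpr:
            gpa = rplug.createGeneProductAssociation()
            gpa.setAssociation(_gpr_to_infix(rxn.gpr), True, False)

    if model.objective is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize" if model.objective_sense == "max" else "minimize")
        mplug.setActiveObjectiveId("obj")
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + _sbml_escape(model.objective))
        fo.setCoefficient(1.0)

    libsbml.writeSBMLToFile(doc, str(path))


def _gpr_to_infix(gpr: str) -> str:
    """Rewrite gene tokens with the fbc id prefix, keeping and/or structure."""
    out: list[str] = []
    token = ""
    for ch in gpr + " ":
        if ch in "() ":
            if token:
                out.append(token if token in ("and", "or") else "G_FBC_" + _sbml_escape(token))
                token = ""
            if ch != " ":
                out.append(ch)
        else:
            token += ch
    text = " ".join(out)
    return text.replace("( ", "(").replace(" )", ")")
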