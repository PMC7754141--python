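"""Curation edits and medium constraints.

A curated genome-scale reconstruction is produced by an ordered list of
edits (add/delete reactions and metabolites, bound changes) applied to a
base model, and by a medium specification that opens uptake only for
compounds present in the culture medium (plus water and oxygen), closing
every other import.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .model import MetabolicModel, Metabolite, ModelValidationError, Reaction, gpr_genes

__all__ = [
    "CurationEdit",
    "MediumSpec",
    "apply_edits",
    "apply_medium",
    "read_edits_tsv",
    "write_edits_tsv",
    "read_medium_tsv",
    "write_medium_tsv",
]

_ACTIONS = ("add_reaction", "delete_reaction", "add_metabolite", "set_bounds")


@dataclass
class CurationEdit:
    """One model edit: action ∈ {add_reaction, delete_reaction, add_metabolite,
    set_bounds} with its payload (a Reaction / Metabolite / id / (id, lb, ub))."""

    action: str
    payload: object

    def __post_init__(self) -> None:
        if self.action not in _ACTIONS:
            raise ValueError(f"unknown curation action {self.action!r}")


@dataclass
class MediumSpec:
    """Exchange-reaction bounds describing a culture medium.

    ``rows`` maps exchange reaction id → (lower_bound, upper_bound) in
    mmol·gDW⁻¹·h⁻¹; lower bound < 0 permits uptake.
    """

    rows: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.rows.items())


def apply_edits(
    model: MetabolicModel,
    edits: list[CurationEdit],
    remove_orphan_metabolites: bool = False,
) -> MetabolicModel:
    """Apply curation edits in order, returning a new validated model.

    Deleting a reaction removes metabolites that become unreferenced only
    when ``remove_orphan_metabolites`` is set.
    """
    out = model.copy()
    for edit in edits:
        if edit.action == "add_metabolite":
            met = edit.payload
            assert isinstance(met, Metabolite)
            if out.has_metabolite(met.id):
                raise ModelValidationError(f"add_metabolite: duplicate id {met.id!r}")
            out.metabolites.append(met)
        elif edit.action == "add_reaction":
            rxn = edit.payload
            assert isinstance(rxn, Reaction)
            if out.has_reaction(rxn.id):
                raise ModelValidationError(f"add_reaction: duplicate id {rxn.id!r}")
            out.reactions.append(rxn.copy())
            for g in sorted(gpr_genes(rxn.gpr)):
                if g not in out.genes:
                    out.genes.append(g)
        elif edit.action == "delete_reaction":
            rid = str(edit.payload)
            if not out.has_reaction(rid):
                raise ModelValidationError(f"delete_reaction: no reaction {rid!r}")
            out.reactions = [r for r in out.reactions if r.id != rid]
            if remove_orphan_metabolites:
                used = {m for r in out.reactions for m in r.stoichiometry}
                out.metabolites = [m for m in out.metabolites if m.id in used]
        elif edit.action == "set_bounds":
            rid, lb, ub = edit.payload  # type: ignore[misc]
            if lb > ub:
                raise ModelValidationError(f"set_bounds {rid!r}: lb {lb} > ub {ub}")
            rxn = out.get_reaction(str(rid))
            rxn.lower_bound = float(lb)
            rxn.upper_bound = float(ub)
    out.validate()
    return out


def apply_medium(
    model: MetabolicModel, medium: MediumSpec, close_others: bool = True
) -> MetabolicModel:
    """Constrain exchange bounds to a medium.

    Listed exchanges get the listed bounds.  With ``close_others``, every
    exchange not listed has its uptake closed (lower bound 0); secretion
    bounds are left untouched so products can still leave the cell.
    """
    out = model.copy()
    exchange_ids = {r.id for r in out.exchanges}
    unknown = [rid for rid in medium.rows if rid not in exchange_ids]
    if unknown:
        raise KeyError(f"medium cites unknown exchange reactions: {sorted(unknown)}")
    if close_others:
        for rxn in out.reactions:
            if rxn.is_exchange and rxn.id not in medium.rows:
                rxn.lower_bound = max(rxn.lower_bound, 0.0)
                rxn.upper_bound = max(rxn.upper_bound, rxn.lower_bound)
    for rid, (lb, ub) in medium.rows.items():
        rxn = out.get_reaction(rid)
        rxn.lower_bound = float(lb)
        rxn.upper_bound = float(ub)
    out.validate()
    return out


# ------------------------------------------------------------------ TSV I/O
def read_medium_tsv(path: str | Path) -> MediumSpec:
    df = pd.read_csv(path, sep="\t")
    required = {"reaction_id", "lb", "ub"}
    if not required.issubset(df.columns):
        raise ValueError(f"medium TSV needs columns {sorted(required)}, got {list(df.columns)}")
    return MediumSpec(
        rows={row.reaction_id: (float(row.lb), float(row.ub)) for row in df.itertuples()}
    )


def write_medium_tsv(medium: MediumSpec, path: str | Path) -> Path:
    df = pd.DataFrame(
        [(rid, lb, ub) for rid, (lb, ub) in medium.rows.items()],
        columns=["reaction_id", "lb", "ub"],
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_edits_tsv(path: str | Path) -> list[CurationEdit]:
    """Edits as TSV with columns (action, id, payload_json)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    edits: list[CurationEdit] = []
    for row in df.itertuples():
        payload_doc = json.loads(row.payload_json) if row.payload_json else {}
        if row.action == "add_reaction":
            edits.append(
                CurationEdit(
                    "add_reaction",
                    Reaction(
                        id=row.id,
                        stoichiometry=payload_doc.get("metabolites", {}),
                        lower_bound=payload_doc.get("lower_bound", -1000.0),
                        upper_bound=payload_doc.get("upper_bound", 1000.0),
                        gpr=payload_doc.get("gene_reaction_rule", ""),
                        subsystem=payload_doc.get("subsystem", ""),
                    ),
                )
            )
        elif row.action == "add_metabolite":
            edits.append(
                CurationEdit(
                    "add_metabolite",
                    Metabolite(id=row.id, compartment=payload_doc.get("compartment", "")),
                )
            )
        elif row.action == "delete_reaction":
            edits.append(CurationEdit("delete_reaction", row.id))
        elif row.action == "set_bounds":
            edits.append(
                CurationEdit("set_bounds", (row.id, payload_doc["lb"], payload_doc["ub"]))
            )
        else:
            raise ValueError(f"unknown curation action {row.action!r} in {path}")
    return edits


def write_edits_tsv(edits: list[CurationEdit], path: str | Path) -> Path:
    rows = []
    for edit in edits:
        if edit.action == "add_reaction":
            rxn = edit.payload
            assert isinstance(rxn, Reaction)
            rows.append(
                (
                    edit.action,
                    rxn.id,
                    json.dumps(
                        {
                            "metabolites": rxn.stoichiometry,
                            "lower_bound": rxn.lower_bound,
                            "upper_bound": rxn.upper_bound,
                            "gene_reaction_rule": rxn.gpr,
                            "subsystem": rxn.subsystem,
                        },
                        sort_keys=True,
                    ),
                )
            )
        elif edit.action == "add_metabolite":
            met = edit.payload
            assert isinstance(met, Metabolite)
            rows.append((edit.action, met.id, json.dumps({"compartment": met.compartment})))
        elif edit.action == "delete_reaction":
            rows.append((edit.action, str(edit.payload), ""))
        else:
            rid, lb, ub = edit.payload  # type: ignore[misc]
            rows.append((edit.action, str(rid), json.dumps({"lb": lb, "ub": ub})))
    pd.DataFrame(rows, columns=["action", "id", "payload_json"]).to_csv(
        path, sep="\t", index=False
    )
    return Path(path)
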