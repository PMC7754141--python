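"""Stoichiometric model containers and gene-protein-reaction (GPR) logic.

The in-memory representation follows the conventions of constraint-based
reconstruction tools: a model is a list of metabolites and reactions, each
reaction holding a sparse stoichiometry map (negative coefficients consume,
positive produce), flux bounds in mmol·gDW⁻¹·h⁻¹, and an optional boolean
GPR rule over gene identifiers.  Exchange reactions are boundary
pseudo-reactions with a single metabolite at coefficient −1, so that
negative flux means uptake and positive flux means secretion.
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelValidationError",
    "GPRParseError",
    "parse_gpr",
    "evaluate_gpr",
    "gpr_genes",
    "lint_model",
]

#: default bound magnitude for reversible reactions
DEFAULT_BOUND = 1000.0


class ModelValidationError(ValueError):
    """A model object violates a structural invariant."""


class GPRParseError(ValueError):
    """A gene-reaction rule string is not a well-formed and/or expression."""


@dataclass
class Metabolite:
    """A compartmented chemical species, e.g. ``phyt_c`` (cytosolic phytanate)."""

    id: str
    name: str = ""
    compartment: str = ""

    def __post_init__(self) -> None:
        if not self.compartment and "_" in self.id:
            self.compartment = self.id.rsplit("_", 1)[1]


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds and an optional GPR.

    ``stoichiometry`` maps metabolite ids to signed coefficients; negative
    coefficients are consumed, positive produced.  Bounds default to the
    community convention of ±1000 for reversible reactions.
    """

    id: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    subsystem: str = ""
    name: str = ""
    objective_coefficient: float = 0.0

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        """True for boundary pseudo-reactions: one metabolite, coefficient −1."""
        if len(self.stoichiometry) != 1:
            return False
        (coeff,) = self.stoichiometry.values()
        return math.isclose(coeff, -1.0)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    """A stoichiometric network: metabolites × reactions, genes, objective."""

    id: str = "model"
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    objective: str | None = None
    objective_sense: str = "max"

    # ------------------------------------------------------------------ access
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"reaction {rid!r} not in model {self.id!r}")

    def get_metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(f"metabolite {mid!r} not in model {self.id!r}")

    def has_reaction(self, rid: str) -> bool:
        return any(r.id == rid for r in self.reactions)

    def has_metabolite(self, mid: str) -> bool:
        return any(m.id == mid for m in self.metabolites)

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    # --------------------------------------------------------------- numerics
    def stoichiometric_matrix(self):
        """Dense S of shape (n_metabolites, n_reactions)."""
        import numpy as np

        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for mid, coeff in rxn.stoichiometry.items():
                S[met_index[mid], j] = coeff
        return S

    def bounds_arrays(self):
        import numpy as np

        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    # ------------------------------------------------------------- validation
    def validate(self) -> None:
        """Raise :class:`ModelValidationError` on any broken invariant."""
        mids = self.metabolite_ids()
        if len(set(mids)) != len(mids):
            dupes = sorted({m for m in mids if mids.count(m) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dupes}")
        rids = self.reaction_ids()
        if len(set(rids)) != len(rids):
            dupes = sorted({r for r in rids if rids.count(r) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dupes}")
        mset = set(mids)
        gset = set(self.genes)
        for rxn in self.reactions:
            for mid in rxn.stoichiometry:
                if mid not in mset:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                    )
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(
                    f"reaction {rxn.id!r}: lb > ub ({rxn.lower_bound} > {rxn.upper_bound})"
                )
            missing = gpr_genes(rxn.gpr) - gset
            if missing:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} GPR cites genes not in model: {sorted(missing)}"
                )
        if self.objective is not None and not self.has_reaction(self.objective):
            raise ModelValidationError(f"objective reaction {self.objective!r} missing")
        if self.objective_sense not in ("max", "min"):
            raise ModelValidationError(f"objective sense {self.objective_sense!r}")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            genes=list(self.genes),
            objective=self.objective,
            objective_sense=self.objective_sense,
        )


# ----------------------------------------------------------------------- GPR
def parse_gpr(gpr: str) -> ast.expr | None:
    """Parse an and/or rule ("(A and B) or C") into an AST; '' → None."""
    text = gpr.strip()
    if not text:
        return None
    try:
        tree = ast.parse(text, mode="eval")
    except SyntaxError as exc:
        raise GPRParseError(f"malformed GPR {gpr!r}: {exc}") from None
    _check_gpr_node(tree.body, gpr)
    return tree.body


def _check_gpr_node(node: ast.expr, original: str) -> None:
    if isinstance(node, ast.BoolOp):
        if not isinstance(node.op, (ast.And, ast.Or)):
            raise GPRParseError(f"malformed GPR {original!r}")
        for child in node.values:
            _check_gpr_node(child, original)
    elif isinstance(node, ast.Name):
        return
    else:
        raise GPRParseError(
            f"malformed GPR {original!r}: only gene names, 'and', 'or' and "
            "parentheses are allowed"
        )


def evaluate_gpr(gpr: str, active_genes: set[str] | frozenset[str]) -> bool:
    """Evaluate a GPR under a set of active genes.

    AND requires all children active, OR any; an empty rule evaluates True
    (spontaneous / non-gene-associated reactions are always available).
    """
    node = parse_gpr(gpr)
    if node is None:
        return True
    return _eval_node(node, active_genes)


def _eval_node(node: ast.expr, active: set[str] | frozenset[str]) -> bool:
    if isinstance(node, ast.Name):
        return node.id in active
    assert isinstance(node, ast.BoolOp)
    if isinstance(node.op, ast.And):
        return all(_eval_node(v, active) for v in node.values)
    return any(_eval_node(v, active) for v in node.values)


def gpr_genes(gpr: str) -> set[str]:
    """The set of gene ids appearing in a rule."""
    node = parse_gpr(gpr)
    if node is None:
        return set()
    out: set[str] = set()
    stack = [node]
    while stack:
        n = stack.pop()
        if isinstance(n, ast.Name):
            out.add(n.id)
        else:
            stack.extend(n.values)  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------- lint
def lint_model(model: MetabolicModel) -> list[str]:
    """Non-fatal warnings: exchange-sign convention and suffix consistency.

    Returns human-readable messages; structural violations still raise via
    :meth:`MetabolicModel.validate`.
    """
    warnings: list[str] = []
    model.validate()
    for rxn in model.reactions:
        if len(rxn.stoichiometry) == 1 and not rxn.is_exchange:
            (coeff,) = rxn.stoichiometry.values()
            warnings.append(
                f"single-metabolite reaction {rxn.id!r} has coefficient {coeff}, "
                "not the exchange convention of -1 (flux<0 = uptake)"
            )
    for met in model.metabolites:
        if "_" in met.id:
            suffix = met.id.rsplit("_", 1)[1]
            if met.compartment and suffix != met.compartment:
                warnings.append(
                    f"metabolite {met.id!r}: compartment field "
                    f"{met.compartment!r} disagrees with id suffix {suffix!r}"
                )
    return warnings
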