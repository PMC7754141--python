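"""Context-specific model extraction from expression and evidence data.

The fibroblast context is decided gene-by-gene: a gene is active when its
raw counts summed over all samples reach a threshold (default 10) OR a
curated binary evidence table reports it present in fibroblasts (the
manual-override path for genes the RNAseq missed).  Reactions that depend
on inactive genes are removed, the network is pruned to its flux-consistent
part, and FASTCORE extracts a near-minimal flux-consistent subnetwork
containing every reaction whose GPR is satisfied by the active genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .flux import DEFAULT_EPSILON, _LP_OPTIONS, _lp7, _status_name, consistent_reactions
from .model import MetabolicModel, evaluate_gpr

__all__ = [
    "GeneEvidence",
    "decide_gene_activity",
    "core_reactions",
    "fastcore",
    "induce_submodel",
    "build_context_model",
    "InconsistentCoreError",
]

DEFAULT_COUNT_THRESHOLD = 10


class InconsistentCoreError(ValueError):
    """A requested core reaction cannot carry flux in the input network."""


@dataclass
class GeneEvidence:
    """Per-gene activity decision: counts, database evidence, final call."""

    gene_id: str
    summed_raw_counts: int
    database_evidence: int
    final_active: bool


def decide_gene_activity(
    counts: pd.DataFrame,
    evidence: pd.DataFrame,
    threshold: int = DEFAULT_COUNT_THRESHOLD,
) -> list[GeneEvidence]:
    """Binary gene-activity call: active ⇔ summed counts ≥ threshold OR
    database evidence = 1.

    ``counts`` is a gene × sample integer matrix (index gene_id);
    ``evidence`` has columns (gene_id, evidence).  Genes present in the
    evidence table but absent from counts are treated as zero counts.
    """
    if not np.issubdtype(np.asarray(counts.values).dtype, np.integer):
        values = counts.values
        if not np.allclose(values, np.round(values)):
            raise ValueError("raw counts must be integers")
        counts = counts.round().astype(int)
    evid_map = dict(zip(evidence["gene_id"], evidence["evidence"].astype(int)))
    genes = sorted(set(counts.index) | set(evid_map))
    summed = counts.sum(axis=1)
    out = []
    for gene in genes:
        total = int(summed.get(gene, 0))
        ev = int(evid_map.get(gene, 0))
        out.append(
            GeneEvidence(
                gene_id=gene,
                summed_raw_counts=total,
                database_evidence=ev,
                final_active=(total >= threshold) or (ev == 1),
            )
        )
    return out


def gene_evidence_frame(decisions: list[GeneEvidence]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (d.gene_id, d.summed_raw_counts, d.database_evidence, d.final_active)
            for d in decisions
        ],
        columns=["gene_id", "summed_counts", "evidence", "final_active"],
    )


def core_reactions(model: MetabolicModel, active_genes: set[str]) -> set[str]:
    """Reactions whose (non-empty) GPR is satisfied by the active genes.

    Empty-GPR reactions are neither core nor scheduled for removal: they are
    available but carry no expression support of their own.
    """
    return {
        r.id
        for r in model.reactions
        if r.gpr and evaluate_gpr(r.gpr, active_genes)
    }


# ----------------------------------------------------------------- FASTCORE
def _lp_sparse_with_core(S, lb, ub, K, P, epsilon):
    """Minimise Σ_{p∈P} |v_p| subject to Sv=0, bounds, v_k ≥ epsilon ∀k∈K.

    The sparsity step of FASTCORE (its LP10): activate the pinned core
    reactions K while paying for flux through the penalty set P.
    """
    m, n = S.shape
    k = len(P)
    lb = lb.copy()
    for j in K:
        lb[j] = max(lb[j], epsilon)
    if k == 0:
        res = linprog(
            np.zeros(n),
            A_eq=S if m else None,
            b_eq=np.zeros(m) if m else None,
            bounds=list(zip(lb, ub)),
            method="highs",
            options=_LP_OPTIONS,
        )
        if res.status != 0:
            raise InconsistentCoreError(
                f"core activation LP is {_status_name(res.status)}"
            )
        return res.x
    # variables [v; z], constraints v_p − z_p ≤ 0 and −v_p − z_p ≤ 0
    S_ext = sparse.hstack([S, sparse.csr_matrix((m, k))], format="csr") if m else None
    rows = sparse.lil_matrix((2 * k, n + k))
    for i, p in enumerate(P):
        rows[2 * i, p] = 1.0
        rows[2 * i, n + i] = -1.0
        rows[2 * i + 1, p] = -1.0
        rows[2 * i + 1, n + i] = -1.0
    c = np.zeros(n + k)
    c[n:] = 1.0
    zmax = float(np.max(np.abs(np.concatenate([lb, ub])))) + 1.0
    bounds = list(zip(lb, ub)) + [(0.0, zmax)] * k
    res = linprog(
        c,
        A_ub=rows.tocsr(),
        b_ub=np.zeros(2 * k),
        A_eq=S_ext,
        b_eq=np.zeros(m) if m else None,
        bounds=bounds,
        method="highs",
        options=_LP_OPTIONS,
    )
    if res.status != 0:
        raise InconsistentCoreError(f"sparsity LP is {_status_name(res.status)}")
    return res.x[:n]


def fastcore(
    model: MetabolicModel,
    core: set[str],
    epsilon: float = DEFAULT_EPSILON,
) -> set[str]:
    """FASTCORE: near-minimal flux-consistent subnetwork containing the core.

    The input model must itself be flux-consistent (run
    :func:`fibroflux.flux.consistent_reactions` first); a core reaction
    that cannot carry flux raises :class:`InconsistentCoreError` naming the
    offenders.  Alternates a dense step (activate as many remaining core
    reactions as possible, LP7) with a sparse step (minimal penalty flux,
    LP10), flipping reversible candidates before declaring them singleton.
    """
    rids = model.reaction_ids()
    index = {rid: j for j, rid in enumerate(rids)}
    missing = sorted(set(core) - set(rids))
    if missing:
        raise KeyError(f"core reactions not in model: {missing}")
    if not core:
        raise ValueError("core set is empty")
    n = len(rids)
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    irreversible = {j for j in range(n) if lb[j] >= 0}
    C = {index[rid] for rid in core}

    Swork = S.copy()
    lbw, ubw = lb.copy(), ub.copy()

    def flip(js):
        for j in js:
            Swork[:, j] = -Swork[:, j]
            lbw[j], ubw[j] = -ubw[j], -lbw[j]

    def find_sparse_mode(J, P, singleton):
        if not J:
            return set()
        J_use = [min(J)] if singleton else sorted(J)
        Ssp = sparse.csr_matrix(Swork)
        v = _lp7(Ssp, lbw, ubw, J_use, epsilon)
        K = [j for j in J_use if v[j] >= 0.99 * epsilon]
        if not K:
            return set()
        v = _lp_sparse_with_core(Ssp, lbw, ubw, K, sorted(P), epsilon)
        return {j for j in range(n) if abs(v[j]) >= 0.99 * epsilon}

    flipped = False
    singleton = False
    J = C & irreversible
    P = set(range(n)) - C
    supp = find_sparse_mode(J, P, singleton)
    bad = sorted(rids[j] for j in (J - supp))
    if bad:
        raise InconsistentCoreError(
            f"irreversible core reactions cannot carry flux: {bad}"
        )
    A = set(supp)
    J = C - A
    while J:
        P -= A
        supp = find_sparse_mode(J, P, singleton)
        A |= supp
        if J & A:
            J -= A
            flipped = False
        else:
            J_rev = ({min(J)} if singleton else J) - irreversible
            if flipped or not J_rev:
                if singleton:
                    raise InconsistentCoreError(
                        f"core reactions cannot carry flux: {sorted(rids[j] for j in J)}"
                    )
                flipped = False
                singleton = True
            else:
                flip(sorted(J_rev))
                flipped = True
    return {rids[j] for j in sorted(A)}


def induce_submodel(model: MetabolicModel, keep: set[str]) -> MetabolicModel:
    """Submodel on a reaction subset; metabolites/genes pruned to those used."""
    out = model.copy()
    out.reactions = [r for r in out.reactions if r.id in keep]
    used_mets = {m for r in out.reactions for m in r.stoichiometry}
    out.metabolites = [m for m in out.metabolites if m.id in used_mets]
    from .model import gpr_genes

    used_genes = {g for r in out.reactions for g in gpr_genes(r.gpr)}
    out.genes = sorted(used_genes)
    if out.objective is not None and out.objective not in keep:
        out.objective = None
    out.validate()
    return out


def build_context_model(
    model: MetabolicModel,
    counts: pd.DataFrame,
    evidence: pd.DataFrame,
    threshold: int = DEFAULT_COUNT_THRESHOLD,
    epsilon: float = DEFAULT_EPSILON,
    protected: tuple[str, ...] = ("biomass_reaction", "DM_atp_c", "DM_atp_c_"),
    protect_exchanges: bool = True,
) -> tuple[MetabolicModel, pd.DataFrame]:
    """Full extraction pipeline: activity calls → GPR-based removal →
    flux-consistency prune → core set → FASTCORE → induced submodel.

    Biomass, the ATP demand and (by default) the exchange reactions are
    appended to the core when they survive the consistency prune, so the
    extracted model retains its boundary and maintenance functions.
    Returns (extracted model, per-gene decision table).
    """
    decisions = decide_gene_activity(counts, evidence, threshold)
    active = {d.gene_id for d in decisions if d.final_active}
    table = gene_evidence_frame(decisions)

    # stage 1: drop reactions whose GPR is false under the active set
    stage1 = model.copy()
    stage1.reactions = [
        r for r in stage1.reactions if not r.gpr or evaluate_gpr(r.gpr, active)
    ]
    stage1 = induce_submodel(stage1, {r.id for r in stage1.reactions})
    stage1.id = f"{model.id}_expressed"

    # stage 2: flux-consistency prune
    consistent = consistent_reactions(stage1, epsilon)
    pruned = induce_submodel(stage1, consistent)
    pruned.id = f"{model.id}_consistent"

    # stage 3: core = expression-supported reactions + protected functions
    core = core_reactions(pruned, active)
    keep_always = set(protected)
    if protect_exchanges:
        keep_always |= {r.id for r in pruned.exchanges}
    core |= keep_always & set(pruned.reaction_ids())
    core &= set(pruned.reaction_ids())
    if not core:
        raise ValueError("empty core: no expression-supported reaction survived")

    # stage 4: FASTCORE extraction
    kept = fastcore(pruned, core, epsilon)
    extracted = induce_submodel(pruned, kept)
    extracted.id = f"{model.id}_context"
    if model.objective in kept:
        extracted.objective = model.objective
        extracted.objective_sense = model.objective_sense
    return extracted, table
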