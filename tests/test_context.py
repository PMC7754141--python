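"""Context extraction: activity calls, core sets, FASTCORE, full pipeline."""

import numpy as np
import pandas as pd
import pytest

import fibroflux as ff
from fibroflux.context import (
    InconsistentCoreError,
    core_reactions,
    decide_gene_activity,
    fastcore,
    induce_submodel,
)
from fibroflux.flux import _lp7
from fibroflux.model import MetabolicModel, Metabolite, Reaction
from fibroflux.synthetic import generate_evidence
from scipy import sparse

from helpers import minimal_subnetwork_oracle


def _frame(counts_by_gene, n_samples=2):
    rows = {}
    for gene, total in counts_by_gene.items():
        vec = [total, 0][:n_samples] + [0] * (n_samples - 2)
        vec[0] = total
        rows[gene] = vec
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"s{i}" for i in range(n_samples)])
    df.index.name = "gene_id"
    return df


def _evidence(ev_by_gene):
    return pd.DataFrame(
        {"gene_id": list(ev_by_gene), "evidence": list(ev_by_gene.values())}
    )


# ------------------------------------------------------------ decision rule
@pytest.mark.parametrize(
    "total,evid,expected",
    [
        (9, 0, False),   # below threshold, no evidence
        (9, 1, True),    # evidence override rescues a low-count gene
        (10, 0, True),   # boundary: threshold is inclusive
        (10, 1, True),
        (0, 0, False),
        (0, 1, True),
    ],
)
def test_activity_decision_truth_table(total, evid, expected):
    decisions = decide_gene_activity(_frame({"g": total}), _evidence({"g": evid}))
    (d,) = decisions
    assert d.final_active is expected
    assert d.summed_raw_counts == total
    assert d.final_active == ((d.summed_raw_counts >= 10) or (d.database_evidence == 1))


def test_gene_missing_from_counts_is_zero():
    decisions = decide_gene_activity(_frame({"g": 50}), _evidence({"g": 0, "h": 1}))
    by_id = {d.gene_id: d for d in decisions}
    assert by_id["h"].summed_raw_counts == 0
    assert by_id["h"].final_active  # evidence alone activates


def test_non_integer_counts_raise():
    df = _frame({"g": 5})
    df = df.astype(float)
    df.iloc[0, 0] = 4.5
    with pytest.raises(ValueError, match="integer"):
        decide_gene_activity(df, _evidence({"g": 0}))


def test_custom_threshold():
    decisions = decide_gene_activity(
        _frame({"g": 15}), _evidence({"g": 0}), threshold=20
    )
    assert not decisions[0].final_active


# ---------------------------------------------------------------- core sets
def test_all_genes_active_core_is_all_gene_associated(toy_model):
    core = core_reactions(toy_model, set(toy_model.genes))
    assert core == {r.id for r in toy_model.reactions if r.gpr}


def test_and_gpr_with_partial_genes_not_core(toy_model):
    active = set(toy_model.genes) - {"G_BOXW2"}
    core = core_reactions(toy_model, active)
    assert "PBOXwc" not in core  # AND rule broken
    assert "3MAAt" in core  # OR rule still satisfied


def test_inactive_decoy_genes_excluded_from_core(toy_model, expression, evidence):
    decisions = decide_gene_activity(expression.counts, evidence)
    active = {d.gene_id for d in decisions if d.final_active}
    core = core_reactions(toy_model, active)
    assert "DECOY1" not in core and "DECOY2" not in core
    assert "GLNCIT" in core  # evidence-override gene keeps its reaction


# ------------------------------------------------------------------ FASTCORE
def _chain_with_detour():
    """A 3-step linear chain plus a wasteful 3-step detour; minimal support
    of the middle chain reaction is the chain itself (5 reactions)."""
    mets = [Metabolite(id=f"m{i}_c", compartment="c") for i in range(2)] + [
        Metabolite(id="d0_c", compartment="c"),
        Metabolite(id="d1_c", compartment="c"),
    ]
    rxns = [
        Reaction(id="EX_in", stoichiometry={"m0_c": -1.0}, lower_bound=-10, upper_bound=10),
        Reaction(id="mid", stoichiometry={"m0_c": -1, "m1_c": 1}, lower_bound=0, upper_bound=10),
        Reaction(id="EX_out", stoichiometry={"m1_c": -1.0}, lower_bound=-10, upper_bound=10),
        # detour: m0 -> d0 -> d1 -> out
        Reaction(id="d_a", stoichiometry={"m0_c": -1, "d0_c": 1}, lower_bound=0, upper_bound=10),
        Reaction(id="d_b", stoichiometry={"d0_c": -1, "d1_c": 1}, lower_bound=0, upper_bound=10),
        Reaction(id="EX_d", stoichiometry={"d1_c": -1.0}, lower_bound=0, upper_bound=10),
    ]
    return MetabolicModel(id="chain_detour", metabolites=mets, reactions=rxns)


def test_fastcore_single_core_pulls_in_whole_chain():
    model = _chain_with_detour()
    eps = 1e-4
    result = fastcore(model, {"mid"}, eps)
    assert result == {"EX_in", "mid", "EX_out"}
    assert len(result) == minimal_subnetwork_oracle(model, {"mid"}, eps)


def test_fastcore_matches_bruteforce_minimum_on_branched_fixture():
    model = _chain_with_detour()
    eps = 1e-4
    result = fastcore(model, {"d_b"}, eps)
    assert {"d_a", "d_b", "EX_d"} <= result
    assert len(result) == minimal_subnetwork_oracle(model, {"d_b"}, eps)


def test_fastcore_core_equals_consistent_set_is_fixed_point(toy_model):
    eps = 1e-4
    consistent = ff.consistent_reactions(toy_model, eps)
    pruned = induce_submodel(toy_model, consistent)
    assert fastcore(pruned, consistent, eps) == consistent


def test_fastcore_output_contains_core_and_is_consistent(toy_model, expression, evidence):
    eps = 1e-4
    consistent = ff.consistent_reactions(toy_model, eps)
    pruned = induce_submodel(toy_model, consistent)
    decisions = decide_gene_activity(expression.counts, evidence)
    active = {d.gene_id for d in decisions if d.final_active}
    core = core_reactions(pruned, active) & set(pruned.reaction_ids())
    result = fastcore(pruned, core, eps)
    assert core <= result
    sub = induce_submodel(pruned, result)
    assert ff.consistent_reactions(sub, eps) == set(sub.reaction_ids())


def test_fastcore_inconsistent_core_raises():
    model = _chain_with_detour()
    model.reactions.append(
        Reaction(id="orphan", stoichiometry={"d1_c": -1, "d0_c": 2},
                 lower_bound=0, upper_bound=0)
    )
    with pytest.raises(InconsistentCoreError, match="orphan"):
        fastcore(model, {"orphan"}, 1e-4)


def test_fastcore_unknown_core_reaction_raises(toy_model):
    with pytest.raises(KeyError):
        fastcore(toy_model, {"NOT_THERE"}, 1e-4)


# ------------------------------------------------------- extraction pipeline
def test_extraction_removes_decoys_keeps_pathways(extracted_model):
    rids = set(extracted_model.reaction_ids())
    assert not any(r.startswith(("DECOY", "DEC1", "DEC2", "EX_dec")) for r in rids)
    for rid in ("PHYHx", "CYP450phyt", "DM_atp_c", "biomass_reaction", "GLNCIT"):
        assert rid in rids


def test_extraction_keeps_alpha_oxidation_in_ctrl(extracted_model):
    """The disease is imposed later by deletion, not during extraction."""
    rxn = extracted_model.get_reaction("PHYHx")
    assert rxn.upper_bound > 0


def test_extracted_model_is_flux_consistent(extracted_model):
    eps = 1e-4
    assert ff.consistent_reactions(extracted_model, eps) == set(
        extracted_model.reaction_ids()
    )


def test_all_genes_active_extraction_is_consistent_subset(toy_model):
    n_samples = 11
    counts = pd.DataFrame(
        {f"s{i}": [100] * len(toy_model.genes) for i in range(n_samples)},
        index=pd.Index(toy_model.genes, name="gene_id"),
    )
    evidence = pd.DataFrame({"gene_id": toy_model.genes, "evidence": 0})
    extracted, _ = ff.build_context_model(toy_model, counts, evidence)
    assert set(extracted.reaction_ids()) == ff.consistent_reactions(toy_model, 1e-4)


def test_extraction_deterministic(toy_model, expression, evidence):
    a, _ = ff.build_context_model(toy_model, expression.counts, evidence)
    b, _ = ff.build_context_model(toy_model, expression.counts, evidence)
    assert a.reaction_ids() == b.reaction_ids()


def test_enlarging_evidence_never_shrinks_extraction(toy_model, expression, evidence):
    base, _ = ff.build_context_model(toy_model, expression.counts, evidence)
    more = evidence.copy()
    more.loc[more.gene_id == "G_DEC1", "evidence"] = 1
    bigger, _ = ff.build_context_model(toy_model, expression.counts, more)
    assert set(base.reaction_ids()) <= set(bigger.reaction_ids())


def test_every_core_reaction_can_carry_flux_in_extraction(
    toy_model, expression, evidence, extracted_model
):
    eps = 1e-4
    decisions = decide_gene_activity(expression.counts, evidence)
    active = {d.gene_id for d in decisions if d.final_active}
    core = core_reactions(extracted_model, active)
    S = sparse.csr_matrix(extracted_model.stoichiometric_matrix())
    lb, ub = extracted_model.bounds_arrays()
    rids = extracted_model.reaction_ids()
    for rid in sorted(core):
        j = rids.index(rid)
        v = _lp7(S, lb, ub, [j], eps)
        forward = v[j] >= 0.99 * eps
        if not forward:
            # try the reverse orientation for reversible core members
            v = _lp7(-S, -ub, -lb, [j], eps)
            assert v[j] >= 0.99 * eps, rid
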