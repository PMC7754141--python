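"""LP core: FBA, FVA, flux consistency, deletions, ATP screen, tasks."""

import numpy as np
import pytest

import fibroflux as ff
from fibroflux.curation import CurationEdit, MediumSpec
from fibroflux.flux import TaskDefinition, blocked_reactions_naive, check_task
from fibroflux.model import MetabolicModel, Metabolite, Reaction

from helpers import consistency_oracle, fva_oracle_enumerate, random_network


# ---------------------------------------------------------------------- FBA
def test_fba_glucose_atp_yield(toy_model):
    work = ff.apply_medium(toy_model, ff.minimal_medium(), close_others=True)
    glc = work.get_reaction("EX_glc(e)")
    glc.lower_bound = glc.upper_bound = -1.0
    sol = ff.fba(work, objective="DM_atp_c", sense="max")
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(32.0, abs=1e-6)
    # steady state holds on the returned fluxes
    S = work.stoichiometric_matrix()
    v = np.array([sol[r] for r in work.reaction_ids()])
    assert np.abs(S @ v).max() < 1e-6


def test_fba_no_uptake_no_atp(toy_model):
    out = ff.apply_medium(toy_model, MediumSpec(rows={}), close_others=True)
    sol = ff.fba(out, objective="DM_atp_c", sense="max")
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)


def test_forced_biomass_on_empty_medium_is_infeasible(toy_model):
    out = ff.apply_medium(toy_model, MediumSpec(rows={}), close_others=True)
    out.get_reaction("biomass_reaction").lower_bound = 0.1
    sol = ff.fba(out, objective="DM_atp_c", sense="max")
    assert sol.status == "infeasible"
    assert sol.objective_value is None


def test_fba_agrees_with_cobra_oracle(toy_model, tmp_path):
    """Independent solver/stack cross-check on the same JSON file."""
    cobra = pytest.importorskip("cobra")
    work = ff.apply_medium(toy_model, ff.minimal_medium(), close_others=True)
    glc = work.get_reaction("EX_glc(e)")
    glc.lower_bound = glc.upper_bound = -1.0
    path = tmp_path / "fixed.json"
    ff.write_model(work, path)
    cm = cobra.io.load_json_model(str(path))
    cm.objective = "DM_atp_c"
    expected = cm.optimize().objective_value
    ours = ff.fba(work, objective="DM_atp_c", sense="max").objective_value
    assert ours == pytest.approx(expected, abs=1e-6)


# ---------------------------------------------------------------------- FVA
def test_fva_blocked_reaction_is_zero(toy_model):
    # phosphate exchange is moiety-blocked in the toy: adenylate pool is fixed
    bounds = ff.fva(toy_model, reactions=["EX_pi(e)", "PIt"])
    for lo, hi in bounds.values():
        assert lo == pytest.approx(0.0, abs=1e-9)
        assert hi == pytest.approx(0.0, abs=1e-9)


def test_fva_matches_vertex_enumeration_on_chain():
    """5-reaction linear chain: FVA equals brute-force vertex enumeration."""
    mets = [Metabolite(id=f"m{i}_c", compartment="c") for i in range(4)]
    rxns = [
        Reaction(id="in", stoichiometry={"m0_c": 1.0}, lower_bound=0, upper_bound=4),
        Reaction(id="a", stoichiometry={"m0_c": -1, "m1_c": 1}, lower_bound=0, upper_bound=10),
        Reaction(id="b", stoichiometry={"m1_c": -1, "m2_c": 1}, lower_bound=-10, upper_bound=3),
        Reaction(id="c", stoichiometry={"m2_c": -1, "m3_c": 1}, lower_bound=0, upper_bound=10),
        Reaction(id="out", stoichiometry={"m3_c": -1.0}, lower_bound=0, upper_bound=10),
    ]
    model = MetabolicModel(id="chain", metabolites=mets, reactions=rxns)
    expected = fva_oracle_enumerate(model)
    got = ff.fva(model)
    for rid in model.reaction_ids():
        assert got[rid][0] == pytest.approx(expected[rid][0], abs=1e-7)
        assert got[rid][1] == pytest.approx(expected[rid][1], abs=1e-7)


def test_fva_fraction_of_optimum(toy_model):
    work = ff.apply_medium(toy_model, ff.minimal_medium(), close_others=True)
    glc = work.get_reaction("EX_glc(e)")
    glc.lower_bound = glc.upper_bound = -1.0
    work.objective = "DM_atp_c"
    bounds = ff.fva(work, reactions=["DM_atp_c"], fraction_of_optimum=0.9)
    assert bounds["DM_atp_c"][0] >= 0.9 * 32.0 - 1e-6


# ------------------------------------------------------------- consistency
def test_dead_end_reaction_is_inconsistent():
    mets = [Metabolite(id="a_c", compartment="c"), Metabolite(id="b_c", compartment="c")]
    rxns = [
        Reaction(id="EX_a", stoichiometry={"a_c": -1.0}, lower_bound=-10, upper_bound=10),
        Reaction(id="dead", stoichiometry={"a_c": -1, "b_c": 1}, lower_bound=0, upper_bound=10),
    ]
    model = MetabolicModel(id="deadend", metabolites=mets, reactions=rxns)
    assert ff.consistent_reactions(model) == set()


def test_internal_reversible_cycle_is_consistent():
    """A fully reversible loop with no exchange can still carry flux (no
    loopless correction is applied)."""
    mets = [Metabolite(id="a_c", compartment="c"), Metabolite(id="b_c", compartment="c")]
    rxns = [
        Reaction(id="f", stoichiometry={"a_c": -1, "b_c": 1}, lower_bound=-10, upper_bound=10),
        Reaction(id="g", stoichiometry={"b_c": -1, "a_c": 1}, lower_bound=-10, upper_bound=10),
    ]
    model = MetabolicModel(id="loop", metabolites=mets, reactions=rxns)
    assert ff.consistent_reactions(model) == {"f", "g"}


def test_fastcc_matches_naive_oracle_on_toy(toy_model):
    eps = 1e-4
    assert ff.consistent_reactions(toy_model, eps) == set(
        toy_model.reaction_ids()
    ) - blocked_reactions_naive(toy_model, eps)


@pytest.mark.parametrize("seed", range(6))
def test_fastcc_matches_naive_oracle_on_random_fixtures(seed):
    rng = np.random.default_rng(seed)
    model = random_network(rng, n_reactions=int(rng.integers(10, 31)))
    eps = 1e-4
    assert ff.consistent_reactions(model, eps) == consistency_oracle(model, eps)


def test_epsilon_must_be_positive(toy_model):
    with pytest.raises(ValueError):
        ff.consistent_reactions(toy_model, epsilon=0.0)


# ---------------------------------------------------------------- deletions
def test_phyh_deletion_blocks_alpha_oxidation(toy_model):
    rd = ff.delete_genes(toy_model, ["G_PHYH"])
    rxn = rd.get_reaction("PHYHx")
    assert (rxn.lower_bound, rxn.upper_bound) == (0.0, 0.0)
    # other reactions untouched
    assert rd.get_reaction("CYP450phyt").upper_bound == 1000.0


def test_deleting_one_of_or_pair_keeps_reaction(toy_model):
    out = ff.delete_genes(toy_model, ["G_T1"])  # 3MAAt is "G_T1 or G_T2"
    assert out.get_reaction("3MAAt").upper_bound > 0


def test_deleting_one_of_and_pair_blocks_reaction(toy_model):
    out = ff.delete_genes(toy_model, ["G_BOXW1"])  # PBOXwc is AND-gated
    assert out.get_reaction("PBOXwc").upper_bound == 0.0


def test_deletion_never_increases_optimum(toy_model, rng):
    med = ff.minimal_medium(include_glutathione=True)
    base = ff.max_atp_yield(toy_model, "EX_phyt(e)", med)
    for _ in range(5):
        genes = list(rng.choice(toy_model.genes, size=2, replace=False))
        knocked = ff.delete_genes(toy_model, genes)
        after = ff.max_atp_yield(knocked, "EX_phyt(e)", med)
        assert after is None or after <= base + 1e-9


def test_unknown_gene_raises(toy_model):
    with pytest.raises(KeyError, match="G_NOPE"):
        ff.delete_genes(toy_model, ["G_NOPE"])


def test_phyh_deletion_drops_phytanate_yield_to_omega(toy_model):
    med = ff.minimal_medium(include_glutathione=True)
    assert ff.max_atp_yield(toy_model, "EX_phyt(e)", med) == pytest.approx(59.0)
    rd = ff.delete_genes(toy_model, ["G_PHYH"])
    assert ff.max_atp_yield(rd, "EX_phyt(e)", med) == pytest.approx(39.0)


# --------------------------------------------------------------- ATP screen
def test_atp_screen_infeasible_without_glutathione(toy_model):
    rd = ff.delete_genes(toy_model, ["G_PHYH"])
    assert ff.max_atp_yield(rd, "EX_phyt(e)", ff.minimal_medium()) is None


def test_atp_screen_zero_yield_source(toy_model):
    # sarcosine is disposed of oxidatively without any ATP gain
    assert ff.max_atp_yield(toy_model, "EX_srcs(e)", ff.minimal_medium()) == pytest.approx(
        0.0, abs=1e-9
    )


def test_atp_screen_missing_demand_reaction():
    model = MetabolicModel(
        id="nodm",
        metabolites=[Metabolite(id="a_e", compartment="e")],
        reactions=[Reaction(id="EX_a(e)", stoichiometry={"a_e": -1.0})],
    )
    with pytest.raises(KeyError, match="DM_atp"):
        ff.max_atp_yield(model, "EX_a(e)", MediumSpec(rows={}))


def test_atp_screen_accepts_recon_style_demand_name(toy_model):
    """Genome-scale models name the ATP demand 'DM_atp_c_'; the screen must
    find it without configuration."""
    renamed = toy_model.copy()
    renamed.get_reaction("DM_atp_c").id = "DM_atp_c_"
    renamed.objective = "DM_atp_c_"
    assert ff.max_atp_yield(renamed, "EX_glc(e)", ff.minimal_medium()) == pytest.approx(32.0)


# -------------------------------------------------------------------- tasks
def test_task_glucose_to_atp_passes(toy_model):
    task = TaskDefinition(
        id="glc_to_co2",
        inputs=[("glc_e", 10.0), ("o2_e", 1000.0), ("h2o_e", 1000.0)],
        outputs=[("co2_e", 1.0)],
    )
    assert check_task(toy_model, task).passed


def test_task_missing_metabolite_fails_with_reason(toy_model):
    task = TaskDefinition(id="impossible", inputs=[], outputs=[("unicorn_e", 1.0)])
    res = check_task(toy_model, task)
    assert not res.passed
    assert "missing metabolite" in res.reason


def test_task_respects_closed_exchanges(toy_model):
    # without oxygen in the allowed inputs, glucose cannot be combusted
    task = TaskDefinition(id="anaerobic", inputs=[("glc_e", 10.0)], outputs=[("co2_e", 1.0)])
    assert not check_task(toy_model, task).passed


def test_task_definition_requires_outputs():
    with pytest.raises(ValueError):
        TaskDefinition(id="empty", inputs=[("a_c", 1.0)], outputs=[])
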