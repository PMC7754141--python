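"""Synthetic fixtures with known ground truth for every pipeline stage.

The toy network emulates the metabolic situation of a cultured skin
fibroblast challenged with phytanate:

* glucose oxidation (lumped glycolysis + oxidative phosphorylation) with a
  designed net ATP yield per glucose;
* peroxisomal α-oxidation of phytanate (gene ``G_PHYH``): ATP-dependent
  peroxisomal import, α-oxidation to a pristanate analogue, then lumped
  β-oxidation — the efficient route;
* microsomal ω-oxidation (``CYP450phyt``, gene ``G_CYP4A``), optionally
  glutathione-dependent, feeding ATP-dependent peroxisomal import and
  β-oxidation of the dicarboxylate down to secreted 3-methyladipate
  (3-MAA) — the less efficient escape route;
* a sarcosine → glycine oxidation that disposes of a carbon source without
  any ATP yield (zero-yield control);
* amino-acid exchanges (alanine, glutamine, citrulline, glycine,
  sarcosine), a biomass maintenance reaction, and gene-gated decoy
  pathways whose genes are silent in the expression fixture.

All numeric ground truths (the yield table, intended gene activities,
measured-rate signs) are returned alongside the fixtures so downstream
stages can be tested against construction rather than against themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curation import MediumSpec
from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "ToyModelSpec",
    "ToyYieldTable",
    "ExpressionFixture",
    "MeasuredRates",
    "generate_toy_model",
    "minimal_medium",
    "rich_medium",
    "generate_expression_counts",
    "generate_evidence",
    "generate_measured_rates",
    "toy_tasks",
]

AMINO_ACID_EXCHANGES = ["EX_ala(e)", "EX_gln(e)", "EX_cit(e)", "EX_gly(e)", "EX_srcs(e)"]


@dataclass
class ToyModelSpec:
    """Construction parameters of the toy network.

    ATP yields are *net* (after the 1-ATP peroxisomal import cost); the
    α route must out-yield the ω route, mirroring the biology where
    ω-oxidation is the less efficient escape pathway.
    """

    seed: int = 0
    atp_per_glucose: int = 32
    atp_alpha_route: int = 59
    atp_omega_route: int = 39
    glutathione_required_for_omega: bool = True
    n_decoy_inactive_pathways: int = 2

    def __post_init__(self) -> None:
        if min(self.atp_per_glucose, self.atp_alpha_route, self.atp_omega_route) <= 0:
            raise ValueError("all ATP yields must be positive")
        if self.atp_alpha_route <= self.atp_omega_route:
            raise ValueError("α-route yield must exceed ω-route yield")


@dataclass
class ToyYieldTable:
    """Constructed net ATP yield per carbon source and route."""

    yields: dict[str, dict[str, float]]

    def best(self, carbon_source: str) -> float:
        return max(self.yields[carbon_source].values())


@dataclass
class ExpressionFixture:
    """Gene × sample raw-count matrix plus the intended activity truth."""

    counts: pd.DataFrame  # index gene_id, columns samples, integer counts
    truth: dict[str, bool]  # gene id -> intended active


@dataclass
class MeasuredRates:
    """Measured net exchange rates per group; uptake < 0, secretion > 0."""

    rates: pd.DataFrame  # columns: reaction_id, group, rate

    def group(self, label: str) -> pd.Series:
        sub = self.rates[self.rates.group == label]
        return pd.Series(sub.rate.values, index=sub.reaction_id.values)


def _exchange(rid: str, met: str) -> Reaction:
    return Reaction(id=rid, stoichiometry={met: -1.0})


def generate_toy_model(spec: ToyModelSpec | None = None) -> tuple[MetabolicModel, ToyYieldTable]:
    """Build the toy fibroblast network and its constructed yield table."""
    spec = spec or ToyModelSpec()
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []

    pairs = [
        ("glc", "ec"), ("o2", "ec"), ("co2", "ec"), ("h2o", "ec"), ("pi", "ec"),
        ("phyt", "ec"), ("gthrd", "ec"), ("3maa", "ec"),
        ("ala", "ec"), ("gln", "ec"), ("cit", "ec"), ("gly", "ec"), ("srcs", "ec"),
    ]
    for stem, comps in pairs:
        for comp in comps:
            mets.append(Metabolite(id=f"{stem}_{comp}", compartment=comp))
    for stem in ("atp", "adp"):
        mets.append(Metabolite(id=f"{stem}_c", compartment="c"))
    for stem in ("phyt", "prist", "wcphyt", "3maa"):
        mets.append(Metabolite(id=f"{stem}_x", compartment="x"))
    mets.append(Metabolite(id="wcphyt_c", compartment="c"))
    mets.append(Metabolite(id="dmhptcrn_c", compartment="c"))
    mets.append(Metabolite(id="dmhptcrn_e", compartment="e"))

    for stem in ("glc", "o2", "co2", "h2o", "pi", "phyt", "gthrd", "3maa",
                 "ala", "gln", "cit", "gly", "srcs", "dmhptcrn"):
        rxns.append(_exchange(f"EX_{stem}(e)", f"{stem}_e"))

    def rxn(rid, stoich, lb=0.0, ub=1000.0, gpr="", subsystem=""):
        rxns.append(Reaction(id=rid, stoichiometry=stoich, lower_bound=lb,
                             upper_bound=ub, gpr=gpr, subsystem=subsystem))

    # transport
    rxn("GLCt", {"glc_e": -1, "glc_c": 1}, subsystem="transport")
    rxn("O2t", {"o2_e": -1, "o2_c": 1}, lb=-1000, subsystem="transport")
    rxn("CO2t", {"co2_c": -1, "co2_e": 1}, lb=-1000, subsystem="transport")
    rxn("H2Ot", {"h2o_e": -1, "h2o_c": 1}, lb=-1000, subsystem="transport")
    rxn("PIt", {"pi_e": -1, "pi_c": 1}, lb=-1000, subsystem="transport")
    rxn("PHYTt", {"phyt_e": -1, "phyt_c": 1}, subsystem="transport")
    rxn("GTHRDt", {"gthrd_e": -1, "gthrd_c": 1}, subsystem="transport")
    rxn("ALAt", {"ala_e": -1, "ala_c": 1}, lb=-1000, subsystem="transport")
    rxn("GLNt", {"gln_e": -1, "gln_c": 1}, lb=-1000, subsystem="transport")
    rxn("CITt", {"cit_c": -1, "cit_e": 1}, lb=-1000, subsystem="transport")
    rxn("GLYt", {"gly_c": -1, "gly_e": 1}, lb=-1000, subsystem="transport")
    rxn("SRCSt", {"srcs_e": -1, "srcs_c": 1}, subsystem="transport")
    rxn("3MAAt", {"3maa_c": -1, "3maa_e": 1}, gpr="G_T1 or G_T2", subsystem="transport")

    a_glc = float(spec.atp_per_glucose)
    rxn("GLYCOX",
        {"glc_c": -1, "o2_c": -6, "adp_c": -a_glc, "pi_c": -a_glc,
         "atp_c": a_glc, "co2_c": 6, "h2o_c": 6},
        gpr="G_GLYC", subsystem="glycolysis/oxphos")

    # α route: peroxisomal import costs 1 ATP, β-oxidation repays yield+1
    a_alpha = float(spec.atp_alpha_route) + 1.0
    rxn("PHYTtx",
        {"phyt_c": -1, "atp_c": -1, "h2o_c": -1, "phyt_x": 1, "adp_c": 1, "pi_c": 1},
        subsystem="peroxisomal transport")
    rxn("PHYHx", {"phyt_x": -1, "o2_c": -1, "prist_x": 1, "co2_c": 1},
        gpr="G_PHYH", subsystem="alpha-oxidation")
    # β-oxidation releases a carnitine-ester by-product of the canonical
    # route (a 2,6-dimethylheptanoyl-carnitine analogue) that is secreted;
    # its efflux collapses to zero when the α route is lost
    rxn("PBOXpr",
        {"prist_x": -1, "o2_c": -11, "adp_c": -a_alpha, "pi_c": -a_alpha,
         "atp_c": a_alpha, "co2_c": 14, "h2o_c": 11, "dmhptcrn_c": 1},
        gpr="G_BOXP", subsystem="peroxisomal beta-oxidation")
    rxn("DMHPTCRNt", {"dmhptcrn_c": -1, "dmhptcrn_e": 1}, subsystem="transport")

    # ω route: microsomal hydroxylation/oxidation (glutathione-dependent if
    # flagged), ATP-dependent peroxisomal import, β-oxidation to 3-MAA
    omega_stoich = {"phyt_c": -1, "o2_c": -1, "wcphyt_c": 1, "h2o_c": 1}
    if spec.glutathione_required_for_omega:
        omega_stoich["gthrd_c"] = -1.0
    rxn("CYP450phyt", omega_stoich, gpr="G_CYP4A", subsystem="omega-oxidation")
    a_omega = float(spec.atp_omega_route) + 1.0
    rxn("WCPHYTtx",
        {"wcphyt_c": -1, "atp_c": -1, "h2o_c": -1, "wcphyt_x": 1, "adp_c": 1, "pi_c": 1},
        subsystem="peroxisomal transport")
    rxn("PBOXwc",
        {"wcphyt_x": -1, "o2_c": -9, "adp_c": -a_omega, "pi_c": -a_omega,
         "atp_c": a_omega, "co2_c": 10, "h2o_c": 9, "3maa_x": 1},
        gpr="G_BOXW1 and G_BOXW2", subsystem="peroxisomal beta-oxidation")
    rxn("3MAAtx", {"3maa_x": -1, "3maa_c": 1}, subsystem="peroxisomal transport")

    # amino-acid side reactions
    rxn("GLNCIT", {"gln_c": -1, "cit_c": 1}, gpr="G_LOWEXP",
        subsystem="amino acid metabolism")
    rxn("SARCOX", {"srcs_c": -1, "o2_c": -1, "gly_c": 1, "co2_c": 1},
        gpr="G_SOX", subsystem="amino acid metabolism")

    rxn("DM_atp_c", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
        subsystem="demand")
    rxn("biomass_reaction",
        {"ala_c": -0.2, "gln_c": -0.1, "atp_c": -1, "h2o_c": -1,
         "adp_c": 1, "pi_c": 1},
        subsystem="biomass")

    for i in range(1, spec.n_decoy_inactive_pathways + 1):
        mets.append(Metabolite(id=f"dec{i}_c", compartment="c"))
        mets.append(Metabolite(id=f"dec{i}_e", compartment="e"))
        rxns.append(_exchange(f"EX_dec{i}(e)", f"dec{i}_e"))
        rxn(f"DECOY{i}", {"glc_c": -1, f"dec{i}_c": 1}, gpr=f"G_DEC{i}",
            subsystem="decoy")
        rxn(f"DEC{i}t", {f"dec{i}_c": -1, f"dec{i}_e": 1}, subsystem="transport")

    genes = sorted(
        {"G_GLYC", "G_PHYH", "G_BOXP", "G_CYP4A", "G_BOXW1", "G_BOXW2",
         "G_T1", "G_T2", "G_LOWEXP", "G_SOX"}
        | {f"G_DEC{i}" for i in range(1, spec.n_decoy_inactive_pathways + 1)}
    )
    model = MetabolicModel(
        id="toy_fibroblast",
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        objective="DM_atp_c",
        objective_sense="max",
    )
    model.validate()

    yields = {
        "EX_glc(e)": {"glycolysis_oxphos": float(spec.atp_per_glucose)},
        "EX_phyt(e)": {
            "alpha": float(spec.atp_alpha_route),
            "omega": float(spec.atp_omega_route),
        },
        "EX_srcs(e)": {"sarcosine_oxidation": 0.0},
    }
    return model, ToyYieldTable(yields=yields)


def minimal_medium(include_glutathione: bool = False) -> MediumSpec:
    """Ions, oxygen and water at ±1000; no carbon source, no amino acids.

    The toy has no FAD chemistry, so the riboflavin component of the
    genome-scale minimal medium has no toy counterpart.  Optionally adds
    glutathione uptake at 1 mmol·gDW⁻¹·h⁻¹ (the supplementation used to
    probe the ω route).
    """
    rows = {
        "EX_o2(e)": (-1000.0, 1000.0),
        "EX_h2o(e)": (-1000.0, 1000.0),
        "EX_pi(e)": (-1000.0, 1000.0),
    }
    if include_glutathione:
        rows["EX_gthrd(e)"] = (-1.0, 1000.0)
    return MediumSpec(rows=rows)


def rich_medium(model: MetabolicModel) -> MediumSpec:
    """Every exchange open at ±1000 (culture-medium-like, used for sampling)."""
    return MediumSpec(rows={r.id: (-1000.0, 1000.0) for r in model.exchanges})


# ------------------------------------------------------------------- counts
def generate_expression_counts(
    model: MetabolicModel,
    seed: int = 0,
    overrides: dict[str, list[int]] | None = None,
    n_ctrl: int = 6,
    n_rd: int = 5,
    active_mean: float = 500.0,
    dispersion: float = 0.5,
) -> ExpressionFixture:
    """Negative-binomial raw counts for the model's genes.

    Genes gating decoy pathways and the designated low-expression gene
    ``G_LOWEXP`` are drawn so their summed counts stay below the 10-count
    activity threshold; every other gene is overdispersed around
    ``active_mean`` (variance μ + μ²·dispersion).  ``overrides`` maps a
    gene id to an explicit per-sample count vector.
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - set(model.genes)
    if unknown:
        raise KeyError(f"override for unknown genes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    samples = [f"CTRL_{i+1}" for i in range(n_ctrl)] + [f"RD_{i+1}" for i in range(n_rd)]
    n = len(samples)
    low_genes = {g for g in model.genes if g.startswith("G_DEC")}
    truth: dict[str, bool] = {}
    rows = {}
    nb_n = 1.0 / dispersion
    for gene in model.genes:
        if gene in overrides:
            vec = np.asarray(overrides[gene], dtype=int)
            if vec.shape != (n,):
                raise ValueError(f"override for {gene!r} must have {n} entries")
            rows[gene] = vec
            truth[gene] = bool(vec.sum() >= 10)
        elif gene == "G_LOWEXP":
            vec = np.zeros(n, dtype=int)
            vec[0], vec[1] = 2, 1  # detectably expressed, but below threshold
            rows[gene] = vec
            truth[gene] = False  # by counts alone; evidence rescues it
        elif gene in low_genes:
            vec = rng.poisson(0.3, size=n).astype(int)
            while vec.sum() >= 10:  # enforce the designed ground truth
                vec[np.argmax(vec)] -= 1
            rows[gene] = vec
            truth[gene] = False
        else:
            p = nb_n / (nb_n + active_mean)
            vec = rng.negative_binomial(nb_n, p, size=n).astype(int)
            if vec.sum() < 10:  # vanishingly rare at mean 500; keep truth exact
                vec[0] += 10 - vec.sum()
            rows[gene] = vec
            truth[gene] = True
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    counts.index.name = "gene_id"
    return ExpressionFixture(counts=counts, truth=truth)


def generate_evidence(model: MetabolicModel) -> pd.DataFrame:
    """Binary fibroblast-evidence table: 1 = reported present in fibroblasts.

    ``G_LOWEXP`` carries evidence 1 (the manual-override path: low counts
    but database support); decoy genes carry 0; well-expressed core genes
    get a mix so both (counts-only) and (counts+evidence) activations occur.
    """
    evid = {}
    for gene in model.genes:
        if gene == "G_LOWEXP" or gene in ("G_PHYH", "G_CYP4A"):
            evid[gene] = 1
        else:
            evid[gene] = 0
    df = pd.DataFrame({"gene_id": list(evid), "evidence": list(evid.values())})
    return df.sort_values("gene_id", ignore_index=True)


# ------------------------------------------------------------- measurements
_DEFAULT_SIGNS = {
    "EX_ala(e)": -1.0,
    "EX_gln(e)": -1.0,
    "EX_srcs(e)": -1.0,
    "EX_phyt(e)": -1.0,
    "EX_cit(e)": 1.0,
    "EX_gly(e)": 1.0,
    "EX_3maa(e)": 1.0,
}


def generate_measured_rates(
    model: MetabolicModel,
    seed: int = 0,
    flip_set: set[str] | frozenset[str] = frozenset(),
    attenuate_set: set[str] | frozenset[str] = frozenset({"EX_phyt(e)"}),
    attenuation: float = 0.15,
) -> MeasuredRates:
    """Measured net exchange rates for CTRL and RD fibroblast groups.

    CTRL rates carry the designed signs (uptake < 0); RD rates equal CTRL
    except for a sign flip on ``flip_set`` (the citrulline/sarcosine-style
    directionality reversal) and a multiplicative attenuation on
    ``attenuate_set`` (impaired phytanate uptake).
    """
    exchange_ids = {r.id for r in model.exchanges}
    bad = (set(flip_set) | set(attenuate_set)) - exchange_ids
    if bad:
        raise KeyError(f"not exchanges of the model: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    rows = []
    for rid, sign in _DEFAULT_SIGNS.items():
        if rid not in exchange_ids:
            continue
        magnitude = float(rng.lognormal(mean=-1.0, sigma=0.5))
        ctrl = sign * magnitude
        rd = ctrl
        if rid in flip_set:
            rd = -rd
        if rid in attenuate_set:
            rd = rd * attenuation
        rows.append((rid, "CTRL", ctrl))
        rows.append((rid, "RD", rd))
    return MeasuredRates(rates=pd.DataFrame(rows, columns=["reaction_id", "group", "rate"]))


# -------------------------------------------------------------------- tasks
def toy_tasks():
    """Small task battery over the toy network, with known truth on the
    extracted model (decoy tasks fail once their genes are called inactive)."""
    from .flux import TaskDefinition

    # a min_production of 0 marks a permitted (but not required) by-product
    return [
        TaskDefinition(
            id="glucose_to_atp",
            inputs=[("glc_e", 10.0), ("o2_e", 1000.0), ("h2o_e", 1000.0)],
            outputs=[("co2_e", 1.0), ("h2o_e", 0.0)],
            description="aerobic glucose catabolism",
        ),
        TaskDefinition(
            id="phytanate_alpha_oxidation",
            inputs=[("phyt_e", 10.0), ("o2_e", 1000.0), ("h2o_e", 1000.0)],
            outputs=[("co2_e", 1.0), ("dmhptcrn_e", 0.0)],
            description="phytanate catabolism via alpha route",
        ),
        TaskDefinition(
            id="phytanate_omega_to_3maa",
            inputs=[("phyt_e", 10.0), ("gthrd_e", 10.0), ("o2_e", 1000.0),
                    ("h2o_e", 1000.0)],
            outputs=[("3maa_e", 0.1), ("co2_e", 0.0), ("dmhptcrn_e", 0.0)],
            description="omega-oxidation of phytanate to 3-methyladipate",
        ),
        TaskDefinition(
            id="sarcosine_to_glycine",
            inputs=[("srcs_e", 10.0), ("o2_e", 1000.0)],
            outputs=[("gly_e", 1.0), ("co2_e", 0.0)],
            description="sarcosine oxidation",
        ),
        TaskDefinition(
            id="decoy_1_production",
            inputs=[("glc_e", 10.0), ("o2_e", 1000.0)],
            outputs=[("dec1_e", 1.0)],
            description="decoy pathway: absent from the fibroblast context",
        ),
        TaskDefinition(
            id="bile_acid_analogue",
            inputs=[("glc_e", 10.0)],
            outputs=[("bileacid_e", 1.0)],
            description="function absent from the toy network entirely",
        ),
    ]
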