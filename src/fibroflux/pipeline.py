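"""End-to-end study pipeline: curate → extract → characterise → disease
simulation → sampling → differential statistics → directionality scoring.

A single config (YAML-serialisable) holds every path, threshold and
sampling parameter; all randomness derives from one master seed, so a
rerun with the same config is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as model_io
from .curation import MediumSpec, apply_edits, apply_medium, read_edits_tsv, read_medium_tsv
from .flux import atp_yield_table, check_task, delete_genes, load_tasks_json
from .context import build_context_model
from .model import MetabolicModel
from .sampling import achr_sample, exchange_summary
from .stats import compare_exchanges, directionality_accuracy, results_frame
from .synthetic import rich_medium

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and simulation parameters of one study run."""

    model_path: str
    counts_path: str
    evidence_path: str
    medium_path: str | None = None  # ATP-screen minimal medium (TSV)
    tasks_path: str | None = None
    measured_rates_path: str | None = None
    edits_path: str | None = None

    count_threshold: int = 10
    epsilon: float = 1e-4
    alpha: float = 0.05
    fdr_threshold: float = 0.05
    lfc_threshold: float = 1.3
    biomass_minimum: float = 0.1

    n_total: int = 50_000
    thinning: int = 500
    n_kept: int = 10_000
    seed: int = 0

    # disease specification: the PHYH-style single-gene deletion with
    # literature pathway caps and forced substrate uptake
    delete_genes: list[str] = field(default_factory=lambda: ["G_PHYH"])
    pathway_caps: dict[str, float] = field(
        default_factory=lambda: {"CYP450phyt": 20.2176, "PHYHx": 48.7656}
    )
    forced_uptakes: dict[str, float] = field(
        default_factory=lambda: {"EX_phyt(e)": -0.1}
    )
    carbon_sources: list[str] = field(
        default_factory=lambda: ["EX_glc(e)", "EX_phyt(e)", "EX_srcs(e)"]
    )

    def __post_init__(self) -> None:
        for name in ("count_threshold", "epsilon", "alpha", "fdr_threshold",
                     "lfc_threshold", "n_total", "thinning", "n_kept"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if self.n_kept > self.n_total:
            raise ValueError("n_kept exceeds n_total")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return Path(path)

    def validate_against(self, model: MetabolicModel) -> None:
        """Fail before any compute when the config cites unknown reactions."""
        for rid in list(self.pathway_caps) + list(self.forced_uptakes):
            if not model.has_reaction(rid):
                raise PipelineError(f"config cites unknown reaction {rid!r}")
        for gene in self.delete_genes:
            if gene not in model.genes:
                raise PipelineError(f"config cites unknown gene {gene!r}")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def apply_disease(model: MetabolicModel, config: PipelineConfig) -> MetabolicModel:
    """Impose the disease condition: gene deletion, pathway caps, forced uptake."""
    config.validate_against(model)
    rd = delete_genes(model, config.delete_genes)
    for rid, cap in config.pathway_caps.items():
        rxn = rd.get_reaction(rid)
        rxn.upper_bound = min(rxn.upper_bound, float(cap))
    for rid, ub in config.forced_uptakes.items():
        rxn = rd.get_reaction(rid)
        rxn.upper_bound = float(ub)
        rxn.lower_bound = min(rxn.lower_bound, float(ub))
    rd.id = f"{model.id}_RD"
    return rd


def _condition_model(
    extracted: MetabolicModel, config: PipelineConfig, disease: bool
) -> MetabolicModel:
    """CTRL/RD sampling condition: rich medium, biomass minimum, forced
    phytanate uptake; the RD branch additionally carries the gene deletion."""
    work = apply_medium(extracted, rich_medium(extracted), close_others=False)
    if work.has_reaction("biomass_reaction"):
        work.get_reaction("biomass_reaction").lower_bound = config.biomass_minimum
    if disease:
        work = apply_disease(work, config)
    else:
        for rid, cap in config.pathway_caps.items():
            if work.has_reaction(rid):
                rxn = work.get_reaction(rid)
                rxn.upper_bound = min(rxn.upper_bound, float(cap))
        for rid, ub in config.forced_uptakes.items():
            if work.has_reaction(rid):
                rxn = work.get_reaction(rid)
                rxn.upper_bound = float(ub)
                rxn.lower_bound = min(rxn.lower_bound, float(ub))
        work.id = f"{extracted.id}_CTRL"
    return work


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full study; artifacts land in ``outdir``.

    Returns a report dict (also written as report.json) with per-stage
    outputs: gene decisions, extracted model size, task results, ATP
    yields, differential table path and directionality accuracy.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config)}

    @_stage("curate")
    def stage_curate() -> MetabolicModel:
        model = model_io.read_model(config.model_path)
        if config.edits_path:
            model = apply_edits(model, read_edits_tsv(config.edits_path))
        config.validate_against(model)
        return model

    model = stage_curate()

    @_stage("extract")
    def stage_extract():
        counts = pd.read_csv(config.counts_path, sep="\t", index_col="gene_id")
        evidence = pd.read_csv(config.evidence_path, sep="\t")
        extracted, table = build_context_model(
            model, counts, evidence,
            threshold=config.count_threshold, epsilon=config.epsilon,
        )
        table.to_csv(out / "gene_activity.tsv", sep="\t", index=False)
        model_io.write_model(extracted, out / "model_context.json")
        return extracted, table

    extracted, gene_table = stage_extract()
    report["n_reactions_input"] = len(model.reactions)
    report["n_reactions_context"] = len(extracted.reactions)
    report["n_genes_active"] = int(gene_table.final_active.sum())

    @_stage("characterise")
    def stage_characterise():
        task_rows = []
        if config.tasks_path:
            for task in load_tasks_json(config.tasks_path):
                res = check_task(extracted, task)
                task_rows.append((task.id, res.passed, res.reason))
            pd.DataFrame(task_rows, columns=["task_id", "passed", "reason"]).to_csv(
                out / "tasks.tsv", sep="\t", index=False
            )
        medium = (
            read_medium_tsv(config.medium_path)
            if config.medium_path
            else MediumSpec(rows={})
        )
        yields = atp_yield_table(extracted, config.carbon_sources, medium)
        pd.DataFrame(
            [(k, "infeasible" if v is None else v) for k, v in yields.items()],
            columns=["carbon_source", "net_atp_yield"],
        ).to_csv(out / "atp_yields.tsv", sep="\t", index=False)
        return task_rows, yields

    task_rows, yields = stage_characterise()
    report["tasks_passed"] = sum(1 for _, passed, _ in task_rows if passed)
    report["tasks_total"] = len(task_rows)
    report["atp_yields"] = {k: (None if v is None else v) for k, v in yields.items()}

    @_stage("sample")
    def stage_sample():
        ctrl_model = _condition_model(extracted, config, disease=False)
        rd_model = _condition_model(extracted, config, disease=True)
        ctrl = achr_sample(
            ctrl_model, n_total=config.n_total, thinning=config.thinning,
            n_kept=config.n_kept, seed=config.seed,
        )
        rd = achr_sample(
            rd_model, n_total=config.n_total, thinning=config.thinning,
            n_kept=config.n_kept, seed=config.seed + 1,
        )
        ctrl.save(out / "samples_ctrl.tsv")
        rd.save(out / "samples_rd.tsv")
        exchange_summary(ctrl).to_csv(out / "summary_ctrl.tsv", sep="\t")
        exchange_summary(rd).to_csv(out / "summary_rd.tsv", sep="\t")
        return ctrl, rd

    ctrl, rd = stage_sample()

    @_stage("diff")
    def stage_diff():
        results = compare_exchanges(
            ctrl, rd, alpha=config.alpha,
            fdr_threshold=config.fdr_threshold, lfc_threshold=config.lfc_threshold,
        )
        frame = results_frame(results)
        frame.to_csv(out / "differential.tsv", sep="\t", index=False)
        return results, frame

    results, frame = stage_diff()
    report["n_exchanges_tested"] = len(results)
    report["n_significant"] = int(frame.significant.sum())
    report["n_higher_extracellular"] = int(
        (frame.concentration_call == "higher_extracellular").sum()
    )
    report["n_lower_extracellular"] = int(
        (frame.concentration_call == "lower_extracellular").sum()
    )

    if config.measured_rates_path:

        @_stage("directionality")
        def stage_directionality():
            rates = pd.read_csv(config.measured_rates_path, sep="\t")
            ctrl_rates = rates[rates.group == "CTRL"]
            measured = pd.Series(
                ctrl_rates.rate.values, index=ctrl_rates.reaction_id.values
            )
            predicted = pd.Series(
                {
                    rid: float(ctrl.column(rid).mean())
                    for rid in measured.index
                    if rid in ctrl.reaction_ids
                }
            )
            accuracy, table = directionality_accuracy(predicted, measured)
            table.to_csv(out / "directionality.tsv", sep="\t", index=False)
            return accuracy

        report["directionality_accuracy"] = stage_directionality()

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    return report
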