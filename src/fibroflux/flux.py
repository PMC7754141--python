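"""Linear-programming core: FBA, FVA, flux consistency, deletions, screens.

All optimisation goes through HiGHS via :func:`scipy.optimize.linprog` on
the steady-state polytope {v : S v = 0, lb ≤ v ≤ ub}.  Infeasibility and
unboundedness are reported in the returned status, never as silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel, evaluate_gpr, gpr_genes

__all__ = [
    "FluxVector",
    "TaskDefinition",
    "TaskResult",
    "fba",
    "fva",
    "consistent_reactions",
    "blocked_reactions_naive",
    "delete_genes",
    "max_atp_yield",
    "atp_yield_table",
    "check_task",
    "load_tasks_json",
]

#: solver feasibility/optimality tolerance
SOLVER_TOL = 1e-9
#: tolerance used when asserting Sv = 0 on returned solutions
ASSERT_TOL = 1e-6
#: default flux-consistency threshold (FASTCORE-family convention)
DEFAULT_EPSILON = 1e-4

_LP_OPTIONS = {"presolve": True, "primal_feasibility_tolerance": SOLVER_TOL,
               "dual_feasibility_tolerance": SOLVER_TOL}


@dataclass
class FluxVector:
    """A steady-state flux assignment with solver status."""

    fluxes: dict[str, float]
    objective_value: float | None
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]


def _status_name(code: int) -> str:
    return {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(code, f"solver_error_{code}")


def _solve(S, lb, ub, c, sense="max", extra_ub=None):
    """min/max c·v over {Sv=0, lb≤v≤ub} (+ optional A_ub v ≤ b_ub)."""
    n = S.shape[1]
    cost = -np.asarray(c, dtype=float) if sense == "max" else np.asarray(c, dtype=float)
    A_ub = b_ub = None
    if extra_ub is not None:
        A_ub, b_ub = extra_ub
    res = linprog(
        cost,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
        options=_LP_OPTIONS,
    )
    value = None
    if res.status == 0:
        value = -res.fun if sense == "max" else res.fun
    return res, value


def fba(
    model: MetabolicModel,
    objective: str | None = None,
    sense: str | None = None,
) -> FluxVector:
    """Flux balance analysis: optimise one reaction flux at steady state."""
    objective = objective or model.objective
    sense = sense or model.objective_sense
    if objective is None:
        raise ValueError("no objective reaction given and none set on the model")
    rids = model.reaction_ids()
    j = rids.index(objective)
    S = sparse.csr_matrix(model.stoichiometric_matrix())
    lb, ub = model.bounds_arrays()
    c = np.zeros(len(rids))
    c[j] = 1.0
    res, value = _solve(S, lb, ub, c, sense)
    if res.status != 0:
        return FluxVector(fluxes={}, objective_value=None, status=_status_name(res.status))
    v = res.x
    resid = np.abs(S @ v).max() if S.shape[0] else 0.0
    if resid > ASSERT_TOL:
        raise ArithmeticError(f"FBA solution violates Sv=0 (|resid|={resid:.2e})")
    return FluxVector(
        fluxes=dict(zip(rids, v.tolist())), objective_value=value, status="optimal"
    )


def fva(
    model: MetabolicModel,
    reactions: list[str] | None = None,
    fraction_of_optimum: float | None = None,
) -> dict[str, tuple[float, float]]:
    """Flux variability analysis: per-reaction (min, max) over the polytope.

    With ``fraction_of_optimum`` the model objective is first optimised and
    constrained to at least that fraction of its optimum.
    """
    rids = model.reaction_ids()
    targets = reactions if reactions is not None else rids
    S = sparse.csr_matrix(model.stoichiometric_matrix())
    lb, ub = model.bounds_arrays()
    extra = None
    if fraction_of_optimum is not None:
        sol = fba(model)
        if sol.status != "optimal":
            raise ValueError(f"model is {sol.status}; cannot anchor FVA to its optimum")
        j = rids.index(model.objective)
        row = np.zeros(len(rids))
        if model.objective_sense == "max":
            row[j] = -1.0
            rhs = -fraction_of_optimum * sol.objective_value
        else:
            row[j] = 1.0
            rhs = fraction_of_optimum * sol.objective_value
        extra = (row.reshape(1, -1), np.array([rhs]))
    out: dict[str, tuple[float, float]] = {}
    for rid in targets:
        j = rids.index(rid)
        c = np.zeros(len(rids))
        c[j] = 1.0
        res_min, vmin = _solve(S, lb, ub, c, "min", extra)
        res_max, vmax = _solve(S, lb, ub, c, "max", extra)
        if res_min.status != 0 or res_max.status != 0:
            raise ValueError(
                f"FVA subproblem for {rid!r} returned "
                f"{_status_name(res_min.status)}/{_status_name(res_max.status)}"
            )
        out[rid] = (vmin, vmax)
    return out


# ------------------------------------------------------------- consistency
def blocked_reactions_naive(model: MetabolicModel, epsilon: float = DEFAULT_EPSILON):
    """Naive two-LP-per-reaction consistency oracle (slow, exact).

    A reaction is flux-consistent iff some steady-state mode carries
    |v_r| ≥ epsilon.
    """
    consistent = set()
    rids = model.reaction_ids()
    S = sparse.csr_matrix(model.stoichiometric_matrix())
    lb, ub = model.bounds_arrays()
    for j, rid in enumerate(rids):
        c = np.zeros(len(rids))
        c[j] = 1.0
        _, vmax = _solve(S, lb, ub, c, "max")
        if vmax is not None and vmax >= epsilon * 0.99:
            consistent.add(rid)
            continue
        _, vmin = _solve(S, lb, ub, c, "min")
        if vmin is not None and vmin <= -epsilon * 0.99:
            consistent.add(rid)
    return set(rids) - consistent


def _lp7(S, lb, ub, J, epsilon):
    """Maximise the number of reactions in J carrying flux ≥ epsilon.

    max Σ_{j∈J} z_j  s.t.  Sv = 0, lb ≤ v ≤ ub, 0 ≤ z_j ≤ epsilon, z_j ≤ v_j.
    Returns the v part of the optimum.
    """
    m, n = S.shape
    k = len(J)
    if k == 0:
        return np.zeros(n)
    # variables x = [v; z]
    S_ext = sparse.hstack([S, sparse.csr_matrix((m, k))], format="csr")
    # z_j - v_j <= 0
    rows = sparse.lil_matrix((k, n + k))
    for i, j in enumerate(J):
        rows[i, j] = -1.0
        rows[i, n + i] = 1.0
    c = np.zeros(n + k)
    c[n:] = -1.0  # maximise Σ z
    bounds = list(zip(lb, ub)) + [(0.0, epsilon)] * k
    res = linprog(
        c,
        A_ub=rows.tocsr(),
        b_ub=np.zeros(k),
        A_eq=S_ext,
        b_eq=np.zeros(m),
        bounds=bounds,
        method="highs",
        options=_LP_OPTIONS,
    )
    if res.status != 0:
        raise ValueError(f"LP7 failed with status {_status_name(res.status)}")
    return res.x[:n]


def consistent_reactions(
    model: MetabolicModel, epsilon: float = DEFAULT_EPSILON
) -> set[str]:
    """The flux-consistent subnetwork, by the fastcc LP scheme.

    Returns ids of reactions that can carry |v| ≥ epsilon in some
    steady-state mode within bounds.  Equivalent to (and validated against)
    the naive two-LP-per-reaction oracle, but solves far fewer LPs by
    testing whole candidate sets at once and flipping reversible reactions.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    rids = model.reaction_ids()
    n = len(rids)
    S = sparse.csr_matrix(model.stoichiometric_matrix()).tolil()
    lb, ub = model.bounds_arrays()
    irreversible = {j for j in range(n) if lb[j] >= 0}

    def flip(js):
        nonlocal S
        for j in js:
            S[:, j] = -S[:, j]
            lb[j], ub[j] = -ub[j], -lb[j]

    A: set[int] = set()
    J = set(irreversible)
    v = _lp7(S.tocsr(), lb, ub, sorted(J), epsilon)
    A |= {j for j in range(n) if abs(v[j]) >= 0.99 * epsilon}
    J = set(range(n)) - A - (set(irreversible) - A)
    flipped = False
    singleton = False
    while J:
        Ji = [min(J)] if singleton else sorted(J)
        v = _lp7(S.tocsr(), lb, ub, Ji, epsilon)
        A |= {j for j in range(n) if abs(v[j]) >= 0.99 * epsilon}
        if J & A:
            J -= A
            flipped = False
        else:
            Ji_rev = [j for j in Ji if j not in irreversible]
            if flipped or not Ji_rev:
                flipped = False
                if singleton:
                    J -= set(Ji)  # blocked in both orientations
                else:
                    singleton = True
            else:
                flip(Ji_rev)
                flipped = True
    return {rids[j] for j in sorted(A)}


# ----------------------------------------------------------------- deletion
def delete_genes(model: MetabolicModel, genes: list[str] | set[str]) -> MetabolicModel:
    """Knock out genes: reactions whose GPR becomes false get bounds (0, 0)."""
    genes = set(genes)
    unknown = genes - set(model.genes)
    if unknown:
        raise KeyError(f"unknown genes: {sorted(unknown)}")
    remaining = set(model.genes) - genes
    out = model.copy()
    out.id = f"{model.id}_d{'_'.join(sorted(genes))}"
    for rxn in out.reactions:
        if rxn.gpr and not evaluate_gpr(rxn.gpr, remaining):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


# --------------------------------------------------------------- ATP screen
def _find_atp_demand(model: MetabolicModel, atp_demand: str | None) -> str:
    candidates = [atp_demand] if atp_demand else ["DM_atp_c", "DM_atp_c_"]
    for rid in candidates:
        if rid and model.has_reaction(rid):
            return rid
    raise KeyError(
        f"model {model.id!r} has no ATP demand reaction (looked for {candidates})"
    )


def max_atp_yield(
    model: MetabolicModel,
    carbon_source: str,
    medium,
    atp_demand: str | None = None,
    oxygen_exchange: str = "EX_o2(e)",
    relax_biomass: bool = True,
) -> float | None:
    """Maximum net ATP demand flux at unit uptake of one carbon source.

    Procedure: close every exchange uptake, open the minimal medium at
    ±1000, force oxygen uptake open, fix the carbon source uptake at
    exactly −1 mmol·gDW⁻¹·h⁻¹, then maximise the ATP demand flux.  The
    demand reaction hydrolyses ATP, so its optimum is the *net* yield after
    the model's internal ATP costs.  Returns None when no steady state
    exists (the carbon source cannot be catabolised under that medium).
    """
    from .curation import apply_medium

    dm = _find_atp_demand(model, atp_demand)
    if not model.has_reaction(carbon_source):
        raise KeyError(f"no exchange reaction {carbon_source!r}")
    # medium components pruned out of a context-specific model are simply
    # unavailable to it; the screen does not fail on their absence
    from .curation import MediumSpec

    present = {r.id for r in model.exchanges}
    medium = MediumSpec(rows={k: v for k, v in medium.rows.items() if k in present})
    work = apply_medium(model, medium, close_others=True)
    if oxygen_exchange in {r.id for r in work.exchanges}:
        ox = work.get_reaction(oxygen_exchange)
        ox.lower_bound = -1000.0
        ox.upper_bound = max(ox.upper_bound, 1000.0)
    if relax_biomass:
        for rxn in work.reactions:
            if rxn.id.startswith("biomass") and rxn.lower_bound > 0:
                rxn.lower_bound = 0.0
    carbon = work.get_reaction(carbon_source)
    carbon.lower_bound = -1.0
    carbon.upper_bound = -1.0
    sol = fba(work, objective=dm, sense="max")
    if sol.status != "optimal":
        return None
    return sol.objective_value


def atp_yield_table(
    model: MetabolicModel, carbon_sources: list[str], medium, **kwargs
) -> dict[str, float | None]:
    """Net-ATP screen over carbon sources; None marks an infeasible source."""
    return {c: max_atp_yield(model, c, medium, **kwargs) for c in carbon_sources}


# -------------------------------------------------------------------- tasks
@dataclass
class TaskDefinition:
    """A metabolic-function feasibility query: can the network convert the
    allowed inputs into at least the required outputs?"""

    id: str
    inputs: list[tuple[str, float]]  # (metabolite id, max uptake)
    outputs: list[tuple[str, float]]  # (metabolite id, min production)
    description: str = ""

    def __post_init__(self) -> None:
        if not self.outputs:
            raise ValueError(f"task {self.id!r} has no outputs")


@dataclass
class TaskResult:
    task_id: str
    passed: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.passed


def check_task(model: MetabolicModel, task: TaskDefinition) -> TaskResult:
    """Run one metabolic task: close all exchanges, allow only the task's
    inputs, demand its outputs, and test steady-state feasibility."""
    missing = [
        m
        for m, _ in list(task.inputs) + list(task.outputs)
        if not model.has_metabolite(m)
    ]
    if missing:
        return TaskResult(task.id, False, f"missing metabolite: {', '.join(missing)}")
    work = model.copy()
    for rxn in work.reactions:
        if rxn.is_exchange:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    from .model import Reaction

    for met, max_uptake in task.inputs:
        work.reactions.append(
            Reaction(
                id=f"TASK_IN_{met}",
                stoichiometry={met: 1.0},
                lower_bound=0.0,
                upper_bound=float(max_uptake),
            )
        )
    for met, min_production in task.outputs:
        work.reactions.append(
            Reaction(
                id=f"TASK_OUT_{met}",
                stoichiometry={met: -1.0},
                lower_bound=float(min_production),
                upper_bound=1000.0,
            )
        )
    first_out = f"TASK_OUT_{task.outputs[0][0]}"
    sol = fba(work, objective=first_out, sense="max")
    if sol.status == "optimal":
        return TaskResult(task.id, True)
    return TaskResult(task.id, False, f"LP {sol.status}")


def load_tasks_json(path) -> list[TaskDefinition]:
    """Task file: JSON list of {id, inputs:[{met,max_uptake}], outputs:[{met,min_production}]}."""
    import json
    from pathlib import Path

    doc = json.loads(Path(path).read_text())
    tasks = []
    for entry in doc:
        tasks.append(
            TaskDefinition(
                id=entry["id"],
                inputs=[(d["met"], float(d["max_uptake"])) for d in entry.get("inputs", [])],
                outputs=[(d["met"], float(d["min_production"])) for d in entry["outputs"]],
                description=entry.get("description", ""),
            )
        )
    return tasks
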