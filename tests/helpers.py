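"""Independent oracles and random-fixture generators used across tests.

Everything here deliberately avoids the package's fast-path algorithms:
the consistency oracle runs two LPs per reaction, the FVA oracle
enumerates vertices, and the minimal-subnetwork oracle searches subsets by
increasing cardinality.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from fibroflux.model import MetabolicModel, Metabolite, Reaction


def random_network(rng: np.random.Generator, n_reactions: int = 20) -> MetabolicModel:
    """A random small stoichiometric network with exchanges.

    Metabolites are chained by random sparse reactions; roughly a third of
    the metabolites get an exchange, and reversibility is random, so the
    fixtures contain blocked reactions, dead ends and reversible cycles.
    """
    n_mets = max(3, n_reactions // 2)
    mets = [Metabolite(id=f"m{i}_c", compartment="c") for i in range(n_mets)]
    rxns = []
    n_exchanges = max(2, n_mets // 3)
    exchanged = rng.choice(n_mets, size=n_exchanges, replace=False)
    for k, i in enumerate(exchanged):
        rev = rng.random() < 0.7
        rxns.append(
            Reaction(
                id=f"EX_m{i}",
                stoichiometry={f"m{i}_c": -1.0},
                lower_bound=-10.0 if rev else 0.0,
                upper_bound=10.0,
            )
        )
    j = 0
    while len(rxns) < n_reactions:
        size = int(rng.integers(1, 4))
        chosen = rng.choice(n_mets, size=min(size + 1, n_mets), replace=False)
        stoich = {}
        for idx, i in enumerate(chosen):
            coeff = float(rng.integers(1, 3))
            stoich[f"m{i}_c"] = -coeff if idx < len(chosen) // 2 + 1 else coeff
        rev = rng.random() < 0.5
        rxns.append(
            Reaction(
                id=f"r{j}",
                stoichiometry=stoich,
                lower_bound=-10.0 if rev else 0.0,
                upper_bound=10.0,
            )
        )
        j += 1
    model = MetabolicModel(id="random_fixture", metabolites=mets, reactions=rxns)
    model.validate()
    return model


def consistency_oracle(model: MetabolicModel, epsilon: float) -> set[str]:
    """Two LPs per reaction: consistent iff max v_r ≥ ε or min v_r ≤ −ε."""
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    rids = model.reaction_ids()
    out = set()
    kwargs = dict(
        A_eq=S if S.shape[0] else None,
        b_eq=np.zeros(S.shape[0]) if S.shape[0] else None,
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    for j, rid in enumerate(rids):
        c = np.zeros(len(rids))
        c[j] = 1.0
        res = linprog(-c, **kwargs)
        if res.status == 0 and -res.fun >= 0.99 * epsilon:
            out.add(rid)
            continue
        res = linprog(c, **kwargs)
        if res.status == 0 and res.fun <= -0.99 * epsilon:
            out.add(rid)
    return out


def fva_oracle_enumerate(model: MetabolicModel) -> dict[str, tuple[float, float]]:
    """Brute-force FVA by vertex enumeration of {Sv=0, lb≤v≤ub}.

    Only viable for a handful of reactions: enumerates candidate vertices
    as solutions with n − rank(S) active bounds.
    """
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n = len(lb)
    rank = np.linalg.matrix_rank(S) if S.size else 0
    free = n - rank
    vertices = []
    for fixed_idx in itertools.combinations(range(n), free):
        for pattern in itertools.product([0, 1], repeat=free):
            v_fixed = np.array(
                [lb[j] if p == 0 else ub[j] for j, p in zip(fixed_idx, pattern)]
            )
            others = [j for j in range(n) if j not in fixed_idx]
            if not others:
                v = np.zeros(n)
                v[list(fixed_idx)] = v_fixed
            else:
                A = S[:, others]
                b = -S[:, list(fixed_idx)] @ v_fixed if S.size else np.zeros(0)
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
                if S.size and np.linalg.norm(A @ sol - b) > 1e-9:
                    continue
                v = np.zeros(n)
                v[list(fixed_idx)] = v_fixed
                v[others] = sol
            if np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9):
                vertices.append(v)
    if not vertices:
        raise ValueError("no feasible vertex found")
    V = np.array(vertices)
    return {
        rid: (float(V[:, j].min()), float(V[:, j].max()))
        for j, rid in enumerate(model.reaction_ids())
    }


def minimal_subnetwork_oracle(
    model: MetabolicModel, core: set[str], epsilon: float
) -> int:
    """Cardinality of the smallest reaction subset ⊇ core that supports a
    steady-state mode with |v_r| ≥ ε on every core reaction.

    Exhaustive search by increasing subset size; only for ≤ ~12 reactions.
    """
    rids = model.reaction_ids()
    others = [r for r in rids if r not in core]
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    index = {rid: j for j, rid in enumerate(rids)}

    def feasible(subset: set[str]) -> bool:
        lo, hi = lb.copy(), ub.copy()
        for rid in rids:
            if rid not in subset:
                lo[index[rid]] = hi[index[rid]] = 0.0
        # each core reaction individually must reach |v| ≥ ε in the subnet
        for rid in core:
            j = index[rid]
            ok = False
            for sign in (1.0, -1.0):
                c = np.zeros(len(rids))
                c[j] = -sign
                res = linprog(
                    c,
                    A_eq=S if S.shape[0] else None,
                    b_eq=np.zeros(S.shape[0]) if S.shape[0] else None,
                    bounds=list(zip(lo, hi)),
                    method="highs",
                )
                if res.status == 0 and sign * res.x[j] >= 0.99 * epsilon:
                    ok = True
                    break
            if not ok:
                return False
        return True

    for extra in range(len(others) + 1):
        for combo in itertools.combinations(others, extra):
            subset = core | set(combo)
            if feasible(subset):
                return len(subset)
    raise ValueError("core cannot be supported by any subnetwork")
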