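"""Artificial-centering hit-and-run (ACHR) sampling of the flux polytope.

The steady-state solution space {v : S v = 0, lb ≤ v ≤ ub} of a bounded
model is a convex polytope; ACHR explores it by repeatedly stepping from
the current point along the direction towards a randomly chosen warmup
point relative to a running centre, with the step drawn uniformly on the
feasible chord.  Every recorded point is re-checked against the
steady-state and bound invariants — violations raise, they are never
silently tolerated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import null_space

from .flux import _solve
from .model import MetabolicModel

__all__ = ["SampleMatrix", "generate_warmup", "achr_sample", "exchange_summary"]

#: allowed steady-state residual on kept points
STEADY_TOL = 1e-6
#: allowed bound violation on kept points
BOUND_SLACK = 1e-8


@dataclass
class SampleMatrix:
    """Sampled steady-state flux ensemble: n_kept × n_reactions."""

    points: np.ndarray
    reaction_ids: list[str]
    metadata: dict = field(default_factory=dict)

    def column(self, rid: str) -> np.ndarray:
        return self.points[:, self.reaction_ids.index(rid)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=self.reaction_ids)

    def save(self, path: str | Path) -> Path:
        """Persist as TSV plus a JSON sidecar holding the metadata."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(self.metadata, indent=1, sort_keys=True) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SampleMatrix":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t")
        sidecar = path.with_suffix(path.suffix + ".json")
        metadata = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(points=frame.values, reaction_ids=list(frame.columns), metadata=metadata)


def _matrices(model: MetabolicModel):
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    return S, lb, ub


def generate_warmup(
    model: MetabolicModel, n_warmup: int | None = None, seed: int = 0
) -> np.ndarray:
    """Warmup points: FVA extrema for every reaction plus random-objective
    LP optima up to ``n_warmup`` (default 2 × n_reactions).  Raises when the
    model is infeasible."""
    S, lb, ub = _matrices(model)
    Ssp = sparse.csr_matrix(S) if S.shape[0] else sparse.csr_matrix((0, len(lb)))
    n = len(lb)
    n_warmup = n_warmup or 2 * n
    rng = np.random.default_rng(seed)
    points = []
    for j in range(n):
        c = np.zeros(n)
        c[j] = 1.0
        for sense in ("min", "max"):
            res, _ = _solve(Ssp, lb, ub, c, sense)
            if res.status != 0:
                raise ValueError(
                    f"model infeasible/unbounded while generating warmup "
                    f"(reaction index {j}, {sense})"
                )
            points.append(res.x)
    while len(points) < n_warmup:
        c = rng.standard_normal(n)
        res, _ = _solve(Ssp, lb, ub, c, "max")
        if res.status != 0:
            raise ValueError("model infeasible/unbounded during random-objective warmup")
        points.append(res.x)
    return np.asarray(points)


def achr_sample(
    model: MetabolicModel,
    n_total: int = 50_000,
    thinning: int = 500,
    n_kept: int = 10_000,
    seed: int = 0,
    warmup: np.ndarray | None = None,
    reproject_every: int = 1_000,
) -> SampleMatrix:
    """ACHR chain over the steady-state polytope.

    One point is recorded every ``thinning`` iterations until ``n_total``
    points are stored; a uniformly random ``n_kept``-subset (without
    replacement) is returned.  Numerical drift off the null space of S is
    corrected by re-projection every ``reproject_every`` iterations.
    Chords of numerically zero length trigger a direction resample, counted
    in the metadata.
    """
    if n_kept > n_total:
        raise ValueError(f"n_kept ({n_kept}) exceeds n_total ({n_total})")
    S, lb, ub = _matrices(model)
    n = len(lb)
    rng = np.random.default_rng(seed)
    if warmup is None:
        warmup = generate_warmup(model, seed=seed)
    W = np.asarray(warmup, dtype=float)
    basis = null_space(S) if S.shape[0] else None

    def project(x: np.ndarray) -> np.ndarray:
        if basis is None or basis.size == 0:
            return x
        return basis @ (basis.T @ x)

    center = W.mean(axis=0)
    x = center.copy()
    if np.ptp(W, axis=0).max() < 1e-12:
        # zero-dimensional polytope: every feasible point is the same point
        kept = np.tile(center, (n_kept, 1))
        np.clip(kept, lb, ub, out=kept)
        _assert_feasible(S, lb, ub, kept)
        return SampleMatrix(
            points=kept,
            reaction_ids=model.reaction_ids(),
            metadata={
                "model_id": model.id, "seed": int(seed), "n_total": int(n_total),
                "thinning": int(thinning), "n_kept": int(n_kept),
                "zero_length_chords": 0, "iterations": 0, "degenerate": True,
            },
        )
    n_points_in_center = W.shape[0]
    recorded = np.empty((n_total, n), dtype=float)
    n_recorded = 0
    iteration = 0
    zero_chords = 0
    dtol = 1e-10
    while n_recorded < n_total:
        iteration += 1
        for _attempt in range(100):
            w = W[rng.integers(W.shape[0])]
            d = w - center
            norm = np.linalg.norm(d)
            if norm < 1e-12:
                zero_chords += 1
                continue
            d = d / norm
            big = np.abs(d) > dtol
            if not big.any():
                zero_chords += 1
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                t_lo = (lb - x)[big] / d[big]
                t_hi = (ub - x)[big] / d[big]
            tmin = np.maximum(np.minimum(t_lo, t_hi), -1e30).max()
            tmax = np.minimum(np.maximum(t_lo, t_hi), 1e30).min()
            if tmax - tmin < 1e-12:
                zero_chords += 1
                continue
            t = rng.uniform(tmin, tmax)
            x = x + t * d
            break
        else:
            raise RuntimeError("could not find a feasible chord after 100 attempts")
        if iteration % reproject_every == 0:
            x = project(x)
            np.clip(x, lb, ub, out=x)
        center = (center * n_points_in_center + x) / (n_points_in_center + 1)
        n_points_in_center += 1
        if iteration % thinning == 0:
            recorded[n_recorded] = project(x)
            n_recorded += 1
    keep_idx = np.sort(rng.choice(n_total, size=n_kept, replace=False))
    kept = recorded[keep_idx]
    np.clip(kept, lb, ub, out=kept)
    _assert_feasible(S, lb, ub, kept)
    return SampleMatrix(
        points=kept,
        reaction_ids=model.reaction_ids(),
        metadata={
            "model_id": model.id,
            "seed": int(seed),
            "n_total": int(n_total),
            "thinning": int(thinning),
            "n_kept": int(n_kept),
            "zero_length_chords": int(zero_chords),
            "iterations": int(iteration),
        },
    )


def _assert_feasible(S, lb, ub, points) -> None:
    """Hard feasibility check on every kept point."""
    if S.shape[0]:
        resid = np.abs(points @ S.T).max()
        if resid > STEADY_TOL:
            raise ArithmeticError(
                f"sampled points violate Sv=0 (max residual {resid:.2e} > {STEADY_TOL})"
            )
    lo = (lb - points).max()
    hi = (points - ub).max()
    worst = max(lo, hi)
    if worst > BOUND_SLACK:
        raise ArithmeticError(
            f"sampled points violate bounds by {worst:.2e} > {BOUND_SLACK}"
        )


def exchange_summary(
    samples: SampleMatrix, reactions: list[str] | None = None
) -> pd.DataFrame:
    """Deterministic per-reaction summaries of the kept points.

    Defaults to boundary reactions (``EX_`` / ``DM_`` / ``sink_`` prefixes),
    the quantities drawn as box-and-whisker plots: mean, sd, min, q05,
    median, q95, max.
    """
    if reactions is None:
        reactions = [
            r for r in samples.reaction_ids
            if r.startswith(("EX_", "DM_", "sink_"))
        ]
    rows = []
    for rid in reactions:
        col = samples.column(rid)
        rows.append(
            {
                "reaction_id": rid,
                "mean": col.mean(),
                "sd": col.std(ddof=1) if len(col) > 1 else 0.0,
                "min": col.min(),
                "q05": np.quantile(col, 0.05),
                "median": np.quantile(col, 0.5),
                "q95": np.quantile(col, 0.95),
                "max": col.max(),
            }
        )
    return pd.DataFrame(rows).set_index("reaction_id")
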