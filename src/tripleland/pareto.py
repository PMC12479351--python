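"""Frontier analysis: normalisation bounds, non-dominated sets, pairwise
frontiers, and the position of the current state relative to the frontier.

Aggregate performances are normalised per objective to [0, 1] against the
unlimited-conversion bounds: 0 at the aggregate performance when that
objective alone is minimised everywhere, 1 when it is maximised everywhere.
The weak dominance convention is used throughout: point a dominates b when
a >= b in every objective and a > b in at least one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .allocate import PerformanceTriple
from .benefits import BenefitMaps
from .categories import Objective
from .errors import DegenerateBoundsError


@dataclass
class NormalizationBounds:
    """Aggregate performance bounds under unlimited conversion.

    ``min_agg[o]`` / ``max_agg[o]`` are the aggregate performances when
    objective ``o`` alone is minimised / maximised in every cell.
    """

    min_agg: np.ndarray  # (3,)
    max_agg: np.ndarray  # (3,)


@dataclass
class ImprovementResult:
    """Outcome of a guarded frontier search (see constrained_improvement)."""

    feasible: bool
    best_value: float | None = None
    witness_index: int | None = None
    deltas: dict[int, float] | None = None


def compute_bounds(maps: BenefitMaps) -> NormalizationBounds:
    """Per-objective aggregate min/max over all possible allocations:
    the sum over cells of the per-cell min/max over categories."""
    m = maps.convertible
    vals = maps.raw[:, :, m]  # (4, 3, n_cells)
    return NormalizationBounds(min_agg=vals.min(axis=0).sum(axis=1),
                               max_agg=vals.max(axis=0).sum(axis=1))


def normalize_performance(triple: PerformanceTriple | Sequence[float],
                          bounds: NormalizationBounds) -> np.ndarray:
    """Map a raw performance triple onto the [0, 1] scale set by ``bounds``."""
    span = bounds.max_agg - bounds.min_agg
    if np.any(span <= 0):
        bad = [Objective(i).name.lower() for i in np.nonzero(span <= 0)[0]]
        raise DegenerateBoundsError(f"degenerate bounds for {bad}")
    return (np.asarray(triple, dtype=float) - bounds.min_agg) / span


def _dominates(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise weak-dominance matrix: D[i, j] = point i dominates point j."""
    ge = (a[:, None, :] >= b[None, :, :]).all(axis=2)
    gt = (a[:, None, :] > b[None, :, :]).any(axis=2)
    return ge & gt


def pareto_filter(points: Sequence[Sequence[float]]) -> np.ndarray:
    """Indices of the non-dominated points (first occurrence of duplicates).

    A point is retained when no other point is >= it in every objective and
    > in at least one. Duplicate coordinates are retained once.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        return np.array([], dtype=int)
    uniq, first = np.unique(pts, axis=0, return_index=True)
    dom = _dominates(uniq, uniq)
    keep_uniq = ~dom.any(axis=0)
    return np.sort(first[keep_uniq])


def pairwise_frontier(points: Sequence[Sequence[float]], obj_i: int,
                      obj_j: int) -> np.ndarray:
    """2-D frontier of the (obj_i, obj_j) projection.

    Returns the non-dominated projected points (deduplicated) sorted by
    obj_i ascending; obj_j is strictly decreasing along the result.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))[:, [obj_i, obj_j]]
    uniq = np.unique(pts, axis=0)
    dom = _dominates(uniq, uniq)
    front = uniq[~dom.any(axis=0)]
    return front[np.argsort(front[:, 0], kind="stable")]


def strictly_better(points: Sequence[Sequence[float]],
                    current: Sequence[float]) -> np.ndarray:
    """Indices of points >= the current state in all three objectives."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    cur = np.asarray(current, dtype=float)
    return np.nonzero((pts >= cur).all(axis=1))[0]


def constrained_improvement(points: Sequence[Sequence[float]],
                            current: Sequence[float], target_obj: int,
                            guard_objs: Sequence[int]) -> ImprovementResult:
    """Best achievable value of one objective without losing on the guards.

    Among points whose guarded objectives are all >= the current values,
    returns the maximum of ``target_obj``, the witness point's index, and
    the change in every non-target objective. An empty feasible set yields a
    "no intersection" result rather than an exception.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    cur = np.asarray(current, dtype=float)
    feasible = np.ones(len(pts), dtype=bool)
    for g in guard_objs:
        feasible &= pts[:, g] >= cur[g]
    idx = np.nonzero(feasible)[0]
    if idx.size == 0:
        return ImprovementResult(feasible=False)
    best = idx[np.argmax(pts[idx, target_obj])]
    deltas = {o: float(pts[best, o] - cur[o])
              for o in range(pts.shape[1]) if o != target_obj}
    return ImprovementResult(feasible=True,
                             best_value=float(pts[best, target_obj]),
                             witness_index=int(best), deltas=deltas)
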