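"""Weighted-sum allocation: per-cell optimal and budget-constrained scenarios.

The aggregate performance of an allocation is a sum of independent per-cell
terms, so for any weighting the allocation maximising the weighted overall
benefit is found by choosing, in every cell, the category with the maximal
weighted per-cell benefit (per-cell argmax is globally optimal by
separability). A conversion budget caps the fraction of convertible cells
allowed to change; cells are then converted in order of decreasing
improvement over keeping their current use, with ties broken by a seeded
random shuffle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .benefits import BenefitMaps
from .categories import N_CATEGORIES, Objective
from .errors import AlignmentError, ConfigError, DataError
from .weights import WeightVector


class PerformanceTriple(NamedTuple):
    """Aggregate raw performance: t CO2-eq/yr, GBP/yr, unitless indicator."""

    carbon: float
    production: float
    biodiversity: float


@dataclass
class NormalizedBenefits:
    """Per-objective globally min-max normalised benefit stack.

    ``norm`` has shape (4, 3, n_rows, n_cols) with values in [0, 1]; the
    min/max are taken over all cells x all four categories, separately per
    objective. ``bounds`` records the (min, max) used.
    """

    norm: np.ndarray
    convertible: np.ndarray
    current_use: np.ndarray
    bounds: dict[Objective, tuple[float, float]] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.norm.shape[2:]


@dataclass
class Scenario:
    """A per-cell category assignment and its aggregate performance."""

    assignment: np.ndarray           # int8 grid, -1 outside convertible mask
    weighting: WeightVector
    convertible: np.ndarray
    current_use: np.ndarray
    budget: float | None = None
    seed: int | None = None
    performance_raw: PerformanceTriple | None = None

    @property
    def converted(self) -> np.ndarray:
        return self.convertible & (self.assignment != self.current_use)

    @property
    def conversion_rate(self) -> float:
        n = int(self.convertible.sum())
        return float(self.converted.sum()) / n if n else 0.0


def normalize_benefits(maps: BenefitMaps) -> NormalizedBenefits:
    """Min-max normalise each objective over all cells and categories.

    A constant layer normalises to all zeros (with a warning). Non-finite
    input raises.
    """
    m = maps.convertible
    if not np.isfinite(maps.raw[:, :, m]).all():
        raise DataError("non-finite raw benefit inside convertible mask")
    norm = np.zeros_like(maps.raw)
    bounds: dict[Objective, tuple[float, float]] = {}
    for obj in Objective:
        layer = maps.raw[:, obj]
        vals = layer[:, m]
        lo, hi = float(vals.min()), float(vals.max())
        bounds[obj] = (lo, hi)
        if hi > lo:
            norm[:, obj] = (layer - lo) / (hi - lo)
        else:
            warnings.warn(f"constant {obj.name.lower()} benefit layer; "
                          "normalised to zeros", stacklevel=2)
    norm = np.clip(norm, 0.0, 1.0)
    return NormalizedBenefits(norm=norm, convertible=m.copy(),
                              current_use=maps.current_use.copy(), bounds=bounds)


def weighted_benefit(norm: NormalizedBenefits, w: WeightVector) -> np.ndarray:
    """Weighted per-cell, per-category benefit b_{n,k} in [0, 1]:
    the convex combination of the three normalised layers."""
    fc, fp, fb = WeightVector(*w).validate().fractions
    n = norm.norm
    return (n[:, Objective.CARBON] * fc + n[:, Objective.PRODUCTION] * fp
            + n[:, Objective.BIODIVERSITY] * fb)


def _argmax_with_ties(b: np.ndarray, current_use: np.ndarray,
                      tie_rule: str) -> np.ndarray:
    """Per-cell argmax over categories; exact ties resolved by ``tie_rule``:
    'incumbent' prefers the current category then ascending category order,
    'order' uses ascending category order only."""
    if tie_rule not in ("incumbent", "order"):
        raise ConfigError(f"unknown tie rule {tie_rule!r}")
    best = b.max(axis=0)
    choice = b.argmax(axis=0).astype(np.int8)  # first (lowest) index on ties
    if tie_rule == "incumbent":
        cur = np.clip(current_use, 0, N_CATEGORIES - 1)
        b_cur = np.take_along_axis(b, cur[None].astype(np.intp), axis=0)[0]
        choice = np.where(b_cur >= best, cur, choice).astype(np.int8)
    return choice


def evaluate_scenario(scenario: Scenario, maps: BenefitMaps) -> PerformanceTriple:
    """Sum the raw benefits of the assigned categories over convertible cells."""
    if scenario.assignment.shape != maps.shape:
        raise AlignmentError(
            f"assignment shape {scenario.assignment.shape} != maps {maps.shape}")
    m = scenario.convertible
    k = scenario.assignment[m].astype(np.intp)
    vals = maps.raw[:, :, m]                       # (4, 3, n_cells)
    picked = vals[k, :, np.arange(k.size)]         # (n_cells, 3)
    total = picked.sum(axis=0)
    return PerformanceTriple(*map(float, total))


def optimal_allocation(norm: NormalizedBenefits, w: WeightVector,
                       maps: BenefitMaps | None = None,
                       tie_rule: str = "incumbent") -> Scenario:
    """Unconstrained optimum: per-cell argmax of the weighted benefit."""
    b = weighted_benefit(norm, w)
    choice = _argmax_with_ties(b, norm.current_use, tie_rule)
    assignment = np.where(norm.convertible, choice, -1).astype(np.int8)
    sc = Scenario(assignment=assignment, weighting=WeightVector(*w),
                  convertible=norm.convertible, current_use=norm.current_use)
    if maps is not None:
        sc.performance_raw = evaluate_scenario(sc, maps)
    return sc


def budget_allocation(norm: NormalizedBenefits, w: WeightVector, budget: float,
                      seed: int | None = 0, maps: BenefitMaps | None = None,
                      tie_rule: str = "incumbent") -> Scenario:
    """Budget-constrained allocation.

    Cells are ranked by the improvement delta of switching to their best
    category over keeping the current one; the top floor(budget x
    n_convertible) positive-delta cells are converted (all of them if fewer
    remain, leaving the realised conversion rate below the budget). Ties in
    delta are broken by a seeded uniform shuffle.
    """
    if not 0.0 <= budget <= 1.0:
        raise ConfigError(f"budget outside [0, 1]: {budget}")
    b = weighted_benefit(norm, w)
    choice = _argmax_with_ties(b, norm.current_use, tie_rule)
    m = norm.convertible
    cur = norm.current_use
    b_best = np.take_along_axis(b, choice[None].astype(np.intp), axis=0)[0]
    b_cur = np.take_along_axis(b, np.clip(cur, 0, N_CATEGORIES - 1)[None].astype(np.intp),
                               axis=0)[0]
    delta = b_best - b_cur

    cand = m & (delta > 0) & (choice != cur)
    rows, cols = np.nonzero(cand)
    deltas = delta[rows, cols]
    n_budget = int(np.floor(budget * int(m.sum())))
    n_convert = min(n_budget, rows.size)

    assignment = np.where(m, cur, -1).astype(np.int8)
    if n_convert > 0:
        rng = np.random.default_rng(seed)
        shuffle_key = rng.permutation(rows.size)
        order = np.lexsort((shuffle_key, -deltas))
        take = order[:n_convert]
        assignment[rows[take], cols[take]] = choice[rows[take], cols[take]]
    sc = Scenario(assignment=assignment, weighting=WeightVector(*w),
                  convertible=m, current_use=cur, budget=budget, seed=seed)
    if maps is not None:
        sc.performance_raw = evaluate_scenario(sc, maps)
    return sc


def current_scenario(norm: NormalizedBenefits,
                     maps: BenefitMaps | None = None) -> Scenario:
    """The all-keep scenario: every cell retains its current use."""
    assignment = np.where(norm.convertible, norm.current_use, -1).astype(np.int8)
    sc = Scenario(assignment=assignment, weighting=WeightVector(0, 0, 100),
                  convertible=norm.convertible, current_use=norm.current_use,
                  budget=0.0)
    if maps is not None:
        sc.performance_raw = evaluate_scenario(sc, maps)
    return sc
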