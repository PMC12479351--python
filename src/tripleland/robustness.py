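"""Robustness of conversions to changing priorities.

Overlaying the scenario ensemble cell by cell gives, for every cell, the
share of scenarios in which it is converted at all and the share converting
it to each target category. Conversions that recur across many weightings
are robust to shifting priorities; cells whose fate flips with the weighting
mark the strongest trade-offs. Ensembles can be filtered to one of the four
priority groups before aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .allocate import Scenario
from .categories import Category, N_CATEGORIES
from .errors import AlignmentError, DataError
from .weights import GROUP_LABELS, classify_weighting


@dataclass
class FrequencyMap:
    """Per-cell conversion shares over a scenario ensemble.

    ``share_to_category[k]`` is the fraction of the ensemble converting the
    cell to category k (relative to the full ensemble, so the category
    shares plus the unchanged share sum to 1 on every convertible cell).
    """

    share_changed: np.ndarray          # (R, C) in [0, 1]
    share_to_category: np.ndarray      # (4, R, C) in [0, 1]
    n_scenarios: int
    group: str = "all"

    @property
    def share_unchanged(self) -> np.ndarray:
        return 1.0 - self.share_changed


def _check_ensemble(scenarios: Sequence[Scenario]) -> None:
    if len(scenarios) == 0:
        raise DataError("empty scenario ensemble")
    shape = scenarios[0].assignment.shape
    for sc in scenarios:
        if sc.assignment.shape != shape:
            raise AlignmentError("scenarios do not share one landscape grid")


def conversion_frequency(scenarios: Sequence[Scenario],
                         group: str = "all") -> FrequencyMap:
    """Per-cell conversion frequencies over a (group-filtered) ensemble."""
    if group != "all" and group not in GROUP_LABELS:
        raise DataError(f"unknown priority group {group!r}")
    if group != "all":
        scenarios = [sc for sc in scenarios
                     if group in classify_weighting(sc.weighting)]
    _check_ensemble(scenarios)
    base = scenarios[0]
    m = base.convertible
    cur = base.current_use
    changed = np.zeros(base.assignment.shape)
    to_cat = np.zeros((N_CATEGORIES, *base.assignment.shape))
    for sc in scenarios:
        conv = sc.converted
        changed += conv
        for k in Category:
            to_cat[k] += conv & (sc.assignment == k)
    n = len(scenarios)
    fm = FrequencyMap(share_changed=np.where(m, changed / n, 0.0),
                      share_to_category=np.where(m, to_cat / n, 0.0),
                      n_scenarios=n, group=group)
    return fm


def common_conversions(scenarios: Sequence[Scenario]
                       ) -> tuple[np.ndarray, np.ndarray]:
    """(cells converted identically in every scenario, cells never converted).

    The first mask marks cells that every scenario converts to the same
    non-current category; the second marks cells no scenario converts. The
    two masks are disjoint by construction.
    """
    _check_ensemble(scenarios)
    base = scenarios[0]
    m = base.convertible
    first = scenarios[0].assignment
    all_same = np.ones(first.shape, dtype=bool)
    any_conv = np.zeros(first.shape, dtype=bool)
    all_conv = np.ones(first.shape, dtype=bool)
    for sc in scenarios:
        all_same &= sc.assignment == first
        conv = sc.converted
        any_conv |= conv
        all_conv &= conv
    same_conversion = m & all_conv & all_same
    never_converted = m & ~any_conv
    return same_conversion, never_converted
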