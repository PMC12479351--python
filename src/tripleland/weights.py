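"""Discrete weight simplex and priority grouping.

Scenario weightings are points on the 3-objective percent simplex
(w_C + w_P + w_B = 100), enumerated on a regular grid (step 5 by default,
giving 231 combinations). Weights are stored as exact integer percents so
enumeration and grouping involve no floating point; they are converted to
fractions only inside the weighted-benefit sum.

Weightings are classified into four priority groups: carbon-, production-
or biodiversity-prioritising when that objective's weight is >= 50, and
balanced when all three are <= 50. Weightings with an objective at exactly
50 sit on the boundary and belong to both that objective's group and the
balanced group, so each group drawn from the step-5 grid has 66 members.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

from .categories import Objective
from .errors import ConfigError

GROUP_LABELS = ("carbon", "production", "biodiversity", "balanced")


class WeightVector(NamedTuple):
    """Integer-percent weights (carbon, production, biodiversity)."""

    w_c: int
    w_p: int
    w_b: int

    def validate(self, step: int | None = None) -> "WeightVector":
        if min(self) < 0 or sum(self) != 100:
            raise ConfigError(f"weights must be >= 0 and sum to 100: {self}")
        if step is not None and any(w % step for w in self):
            raise ConfigError(f"weights {self} not multiples of step {step}")
        return self

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (self.w_c / 100.0, self.w_p / 100.0, self.w_b / 100.0)


def enumerate_weights(step: int = 5) -> list[WeightVector]:
    """All non-negative multiples of ``step`` summing to 100, in
    lexicographic order. Count is (m+1)(m+2)/2 with m = 100/step."""
    if step <= 0 or 100 % step != 0:
        raise ConfigError(f"step must divide 100, got {step}")
    out = []
    for w_c in range(0, 101, step):
        for w_p in range(0, 101 - w_c, step):
            out.append(WeightVector(w_c, w_p, 100 - w_c - w_p))
    return out


def classify_weighting(w: WeightVector) -> frozenset[str]:
    """Priority-group membership of a weighting (total function).

    ``{X}`` if w_X > 50; boundary weights (w_X == 50) join both X's group
    and the balanced group; if no weight exceeds 50 the balanced group is
    included.
    """
    w = WeightVector(*w).validate()
    groups = set()
    for label, val in zip(("carbon", "production", "biodiversity"), w):
        if val >= 50:
            groups.add(label)
    if max(w) <= 50:
        groups.add("balanced")
    return frozenset(groups)


def group_members(weights: Iterable[WeightVector], label: str) -> list[WeightVector]:
    """Subset of ``weights`` belonging to priority group ``label``."""
    if label == "all":
        return list(weights)
    if label not in GROUP_LABELS:
        raise ConfigError(f"unknown priority group {label!r}")
    return [w for w in weights if label in classify_weighting(w)]


#: Column order used when exporting weights: one objective per column.
OBJECTIVE_OF_INDEX = {0: Objective.CARBON, 1: Objective.PRODUCTION,
                      2: Objective.BIODIVERSITY}
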