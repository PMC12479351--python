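"""Land-use categories, semi-natural sub-habitats and objectives.

Four convertible land-use categories are modelled: arable land, pasture
(improved grassland), plantation forest (coniferous), and an aggregate
semi-natural habitat class. Semi-natural land carries a sub-habitat label
(natural grassland, heath, fen/bog, broadleaved woodland) because carbon
stocks and habitat-condition scores differ between them; conversions between
semi-natural sub-habitats are not modelled.
"""

from __future__ import annotations

from enum import IntEnum


class Category(IntEnum):
    ARABLE = 0
    PASTURE = 1
    PLANTATION = 2
    SEMINATURAL = 3


class SubHabitat(IntEnum):
    """Sub-types of the aggregate semi-natural category."""

    GRASSLAND = 0
    HEATH = 1
    FENBOG = 2
    BROADLEAVED = 3


class Objective(IntEnum):
    CARBON = 0
    PRODUCTION = 1
    BIODIVERSITY = 2


N_CATEGORIES = len(Category)
N_OBJECTIVES = len(Objective)

CATEGORY_NAMES = {c: c.name.lower() for c in Category}
SUBHABITAT_NAMES = {s: s.name.lower() for s in SubHabitat}
OBJECTIVE_NAMES = {o: o.name.lower() for o in Objective}

#: Fixed tie-break order for the per-cell argmax (after "prefer incumbent"):
#: arable < pasture < plantation < seminatural, i.e. ascending enum value.
TIE_ORDER = tuple(Category)
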