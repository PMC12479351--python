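"""The spatial state of the model: one :class:`Landscape` per study area.

A landscape is a regular grid of square cells (nominally 500 m, i.e. 25 ha).
Each convertible cell carries its current land-use category, a semi-natural
sub-habitat label where applicable, a peat-soil flag, and the continuous
attribute surfaces the benefit engine consumes (arable revenue potential,
pasture suitability and revenue, forest yield class) plus per-species,
per-category occurrence-probability surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .categories import Category, N_CATEGORIES, SubHabitat
from .errors import AlignmentError, DataError


@dataclass
class Landscape:
    """Per-cell state and attributes on a (n_rows, n_cols) grid.

    Attributes
    ----------
    current_use:
        Integer grid of :class:`~tripleland.categories.Category` codes.
    subhabitat:
        Integer grid of :class:`~tripleland.categories.SubHabitat` codes on
        cells whose current use is semi-natural; -1 elsewhere.
    convertible:
        Boolean grid; cells outside the mask (water, urban, rock in the real
        data) take no part in allocation.
    arable_yield:
        Potential arable revenue surface, GBP/ha/yr.
    pasture_suitability:
        Pasture suitability index in [0, 100].
    pasture_revenue:
        Potential livestock revenue surface, GBP/ha/yr.
    forest_yield_class:
        Forest productivity (yield class, m^3/ha/yr of maximum mean annual
        increment) surface.
    peat:
        Boolean peaty-soil grid.
    occurrence:
        float array of shape (n_species, 4, n_rows, n_cols): probability of
        occurrence of each species under each land-use category.
    cell_area:
        Cell area in hectares (25 ha for a 500 m grid).
    """

    current_use: np.ndarray
    subhabitat: np.ndarray
    convertible: np.ndarray
    arable_yield: np.ndarray
    pasture_suitability: np.ndarray
    pasture_revenue: np.ndarray
    forest_yield_class: np.ndarray
    peat: np.ndarray
    occurrence: np.ndarray
    cell_area: float = 25.0
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.current_use.shape

    @property
    def n_species(self) -> int:
        return self.occurrence.shape[0]

    @property
    def n_convertible(self) -> int:
        return int(self.convertible.sum())

    def validate(self) -> None:
        """Check the structural invariants; raise on violation."""
        shape = self.shape
        for name in ("subhabitat", "convertible", "arable_yield",
                     "pasture_suitability", "pasture_revenue",
                     "forest_yield_class", "peat"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise AlignmentError(f"{name} shape {arr.shape} != grid {shape}")
        if self.occurrence.ndim != 4 or self.occurrence.shape[1:] != (N_CATEGORIES, *shape):
            raise AlignmentError(
                f"occurrence shape {self.occurrence.shape} != (n_species, 4, {shape[0]}, {shape[1]})")
        m = self.convertible
        if not np.isfinite(self.arable_yield[m]).all():
            raise DataError("non-finite arable_yield inside convertible mask")
        if (self.arable_yield[m] < 0).any():
            raise DataError("negative arable_yield")
        ps = self.pasture_suitability[m]
        if (ps < 0).any() or (ps > 100).any():
            raise DataError("pasture_suitability outside [0, 100]")
        occ = self.occurrence[:, :, m]
        if not np.isfinite(occ).all() or (occ < 0).any() or (occ > 1).any():
            raise DataError("occurrence probabilities outside [0, 1]")
        cu = self.current_use[m]
        if (cu < 0).any() or (cu >= N_CATEGORIES).any():
            raise DataError("current_use undefined on a convertible cell")
        sn = (self.current_use == Category.SEMINATURAL) & m
        sh = self.subhabitat[sn]
        if sh.size and ((sh < 0) | (sh >= len(SubHabitat))).any():
            raise DataError("semi-natural cell without sub-habitat label")
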