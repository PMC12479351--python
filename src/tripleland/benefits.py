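"""Benefit engine: raw per-cell benefits of keeping or converting each cell.

For every convertible cell and each of the four target land-use categories,
three benefit values are computed:

* carbon — net mean annual greenhouse-gas balance in t CO2-eq/yr per cell:
  the annualised vegetation+soil stock change of the conversion, minus
  recurring emissions of the target state (fertiliser N2O on arable,
  livestock CH4/N2O on pasture), peat-state fluxes on peaty soils, and mean
  annual forest sequestration (plantation sequestration discounted by the
  long-term wood-product storage share);
* production — mean annual revenue in GBP/yr per cell: arable crop revenue
  (outlier-smoothed), livestock revenue above a pasture-suitability
  threshold, timber revenue from harvested biomass; semi-natural land
  produces nothing;
* biodiversity — a unitless [0, 1] indicator per cell: the geometric mean of
  the min-max normalised summed species-occurrence probability and a
  land-use-specific habitat-condition score.

The result is a :class:`BenefitMaps` container holding the 4 x 3 stack of
surfaces (12 benefit maps).
"""

from __future__ import annotations


from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from scipy import ndimage

from .categories import (Category, N_CATEGORIES, N_OBJECTIVES, Objective,
                         SubHabitat, SUBHABITAT_NAMES)
from .errors import (AlignmentError, AssignmentError, ConfigError, DataError,
                     SmoothingError)
from .forest import ForestModel
from .landscape import Landscape

C_TO_CO2 = 44.0 / 12.0
N2O_N_TO_N2O = 44.0 / 28.0

#: Carbon stock (soil + vegetation, t C/ha) per land-cover class. Synthetic
#: stand-in values of realistic magnitude for a temperate landscape; the real
#: analysis reads these from a published lookup table.
DEFAULT_STOCK: dict[str, float] = {
    "arable": 85.0,
    "pasture": 110.0,
    "plantation": 160.0,
    "grassland": 120.0,
    "heath": 130.0,
    "fenbog": 300.0,
    "broadleaved": 180.0,
}

#: Net flux on peaty soils by target state, t CO2-eq/ha/yr (positive =
#: sequestration). Drained agricultural peat is a large source; rewetted
#: bog/fen a small sink. Synthetic stand-in magnitudes.
DEFAULT_PEAT_FLUX: dict[str, float] = {
    "cropland": -30.0,
    "grassland": -22.0,
    "forestry": -10.0,
    "rewetted": 1.5,
}

_PEAT_STATE_OF_CATEGORY = {
    Category.ARABLE: "cropland",
    Category.PASTURE: "grassland",
    Category.PLANTATION: "forestry",
    Category.SEMINATURAL: "rewetted",
}

#: Habitat condition scores (effective habitat area, 0 = fully degraded,
#: 1 = intact) by class and whether the habitat already exists or would be
#: newly created. Production classes take one published score each; newly
#: created semi-natural habitat scores 0.33, established sub-habitats more.
DEFAULT_CONDITION: dict[tuple[str, str], float] = {
    ("arable", "existing"): 0.08, ("arable", "new"): 0.08,
    ("pasture", "existing"): 0.10, ("pasture", "new"): 0.10,
    ("plantation", "existing"): 0.23, ("plantation", "new"): 0.23,
    ("grassland", "existing"): 0.30, ("grassland", "new"): 0.33,
    ("heath", "existing"): 0.45, ("heath", "new"): 0.33,
    ("fenbog", "existing"): 0.55, ("fenbog", "new"): 0.33,
    ("broadleaved", "existing"): 0.70, ("broadleaved", "new"): 0.33,
}


@dataclass
class CarbonParams:
    """Parameters of the carbon-benefit calculation (units in field docs)."""

    stock: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_STOCK))
    fertiliser_n2o_n: float = 1460.67   # g N2O-N/ha/yr on arable
    gwp_n2o: float = 273.0              # GWP-100 of N2O
    livestock_emissions: float = 7.62   # t CO2-eq/ha/yr on pasture
    peat_flux: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PEAT_FLUX))
    wood_product_share: float = 0.482   # long-term storage share of harvested wood
    horizon: float = 30.0               # years (2020-2050)
    forest: ForestModel = field(default_factory=ForestModel)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.stock.values()):
            raise ConfigError("carbon stocks must be >= 0")
        if not 0.0 <= self.wood_product_share <= 1.0:
            raise ConfigError("wood_product_share outside [0, 1]")
        if self.horizon <= 0:
            raise ConfigError("horizon must be positive")


@dataclass
class ProductionParams:
    suitability_threshold: float = 20.0  # pasture suitability index cut-off
    timber_price: float = 60.0           # GBP/t harvested biomass
    carbon_density: float = 0.5          # t C per t biomass
    forest: ForestModel = field(default_factory=ForestModel)

    def __post_init__(self) -> None:
        if not 0.0 <= self.suitability_threshold <= 100.0:
            raise ConfigError("suitability_threshold outside [0, 100]")
        if self.timber_price < 0 or not 0 < self.carbon_density <= 1:
            raise ConfigError("invalid timber price or carbon density")


@dataclass
class BiodiversityParams:
    condition: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION))

    def __post_init__(self) -> None:
        for k, v in self.condition.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"condition score {k} outside [0, 1]: {v}")


@dataclass
class BenefitMaps:
    """Raw benefit of assigning each cell to each category, per objective.

    ``raw`` has shape (4 categories, 3 objectives, n_rows, n_cols); carbon in
    t CO2-eq/yr per cell, production in GBP/yr per cell, biodiversity
    unitless in [0, 1]. ``provenance`` snapshots the parameters used.
    """

    raw: np.ndarray
    convertible: np.ndarray
    current_use: np.ndarray
    cell_area: float
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.raw.shape[2:]

    def layer(self, objective: Objective) -> np.ndarray:
        """(4, n_rows, n_cols) view of one objective's maps."""
        return self.raw[:, int(objective)]


def fertiliser_emissions(rate: float, gwp: float = 273.0) -> float:
    """Convert a fertiliser N2O-N emission rate to kg CO2-eq/ha/yr.

    ``rate`` is in g N2O-N/ha/yr; N is converted to N2O mass by the
    stoichiometric factor 44/28 and then to CO2-eq with the GWP-100.
    """
    if rate < 0:
        raise DataError(f"negative emission rate: {rate}")
    return rate * N2O_N_TO_N2O * gwp / 1000.0


def assign_future_habitat(landscape: Landscape) -> np.ndarray:
    """Semi-natural sub-habitat each cell would become if restored.

    Every cell takes the sub-habitat of its nearest existing semi-natural
    cell (Euclidean distance between cell centres). Peaty cells are forced
    to bog/fen regardless of the nearest donor, and existing semi-natural
    cells keep their own sub-type. Peat cells are excluded as donors so
    bog/fen only spreads through the peat mask itself.
    """
    donors = (landscape.current_use == Category.SEMINATURAL) & ~landscape.peat
    out = np.empty(landscape.shape, dtype=np.int8)
    if donors.any():
        _, (ri, ci) = ndimage.distance_transform_edt(~donors, return_indices=True)
        out[:] = landscape.subhabitat[ri, ci]
    elif landscape.peat.any():
        out[:] = SubHabitat.FENBOG
    else:
        raise AssignmentError("no existing semi-natural habitat and no peat: "
                              "nothing to seed future-habitat assignment")
    out[landscape.peat] = SubHabitat.FENBOG
    sn = landscape.current_use == Category.SEMINATURAL
    out[sn] = landscape.subhabitat[sn]
    return out


def smooth_outliers(surface: np.ndarray) -> np.ndarray:
    """Replace extreme outliers (beyond 1.5 IQR outside the quartiles) with
    the mean of their finite, non-outlier 8-neighbours.

    Boundary cells use the neighbours they have. An outlier with no valid
    neighbour falls back to the global mean of valid cells. A constant
    surface has no cell outside the (degenerate) fence and is returned
    unchanged.
    """
    surface = np.asarray(surface, dtype=float)
    if surface.size < 9:
        raise DataError("smooth_outliers needs a surface of at least 9 cells")
    finite = np.isfinite(surface)
    vals = surface[finite]
    if vals.size == 0:
        raise SmoothingError("no finite cells to smooth")
    q1, q3 = np.percentile(vals, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outlier = finite & ((surface < lo) | (surface > hi))
    valid = finite & ~outlier
    if not valid.any():
        raise SmoothingError("every cell is an outlier; no valid neighbours")
    if not outlier.any():
        return surface.copy()
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    vsum = ndimage.convolve(np.where(valid, surface, 0.0), kernel, mode="constant")
    vcnt = ndimage.convolve(valid.astype(float), kernel, mode="constant")
    out = surface.copy()
    with np.errstate(invalid="ignore"):
        repl = vsum / vcnt
    repl = np.where(vcnt > 0, repl, surface[valid].mean())
    out[outlier] = repl[outlier]
    return out


def _stock_name(cat: Category, subhab: np.ndarray | None = None) -> str:
    return cat.name.lower()


def _per_cell_stock(landscape: Landscape, params: CarbonParams,
                    habitat_assignment: np.ndarray) -> np.ndarray:
    """Current stock (t C/ha) per cell, resolving semi-natural sub-types."""
    stock = np.empty(landscape.shape)
    cu = landscape.current_use
    for cat in (Category.ARABLE, Category.PASTURE, Category.PLANTATION):
        stock[cu == cat] = params.stock[cat.name.lower()]
    sn = cu == Category.SEMINATURAL
    if sn.any():
        sub_stock = np.array([params.stock[SUBHABITAT_NAMES[s]] for s in SubHabitat])
        stock[sn] = sub_stock[landscape.subhabitat[sn]]
    return stock


def carbon_benefit(landscape: Landscape, params: CarbonParams,
                   habitat_assignment: np.ndarray) -> np.ndarray:
    """Carbon layer: (4, n_rows, n_cols) in t CO2-eq/yr per cell.

    Per target category: the linearly amortised stock change
    (stock_target - stock_current) x 44/12 / horizon, plus recurring annual
    terms of the target state (fertiliser, livestock, peat flux, forest
    growth). Keeping the current category carries zero stock change but
    keeps the recurring terms.
    """
    try:
        current_stock = _per_cell_stock(landscape, params, habitat_assignment)
        sub_stock = np.array([params.stock[SUBHABITAT_NAMES[s]] for s in SubHabitat])
    except KeyError as e:  # pragma: no cover - config mistake
        raise ConfigError(f"missing carbon stock entry: {e}") from e
    area = landscape.cell_area
    shape = landscape.shape
    out = np.zeros((N_CATEGORIES, *shape))
    fert_t = fertiliser_emissions(params.fertiliser_n2o_n, params.gwp_n2o) / 1000.0
    yc = landscape.forest_yield_class
    cu = landscape.current_use

    for cat in Category:
        if cat == Category.SEMINATURAL:
            target_stock = sub_stock[habitat_assignment]
        else:
            target_stock = np.full(shape, params.stock[cat.name.lower()])
        delta = (target_stock - current_stock) * C_TO_CO2 / params.horizon
        layer = delta * area

        if cat == Category.ARABLE:
            layer -= fert_t * area
        elif cat == Category.PASTURE:
            layer -= params.livestock_emissions * area
        elif cat == Category.PLANTATION:
            seq = params.forest.mean_annual_sequestration(
                yc, managed=True, new_planting=cu != Category.PLANTATION)
            layer += seq * params.wood_product_share * area
        else:  # semi-natural: broadleaved assignments sequester via growth
            broad = habitat_assignment == SubHabitat.BROADLEAVED
            already = broad & (cu == Category.SEMINATURAL) & \
                (landscape.subhabitat == SubHabitat.BROADLEAVED)
            seq = params.forest.mean_annual_sequestration(
                yc, managed=False, new_planting=~already)
            layer += np.where(broad, seq, 0.0) * area

        # peat-state flux replaces nothing: it is the recurring soil term
        try:
            flux = params.peat_flux[_PEAT_STATE_OF_CATEGORY[cat]]
        except KeyError as e:
            raise ConfigError(f"missing peat flux entry: {e}") from e
        layer += np.where(landscape.peat, flux, 0.0) * area
        out[cat] = layer
    return out


def production_benefit(landscape: Landscape,
                       params: ProductionParams) -> np.ndarray:
    """Production layer: (4, n_rows, n_cols) in GBP/yr per cell, >= 0."""
    if landscape.pasture_suitability is None:  # pragma: no cover
        raise DataError("pasture suitability surface missing")
    area = landscape.cell_area
    shape = landscape.shape
    out = np.zeros((N_CATEGORIES, *shape))

    out[Category.ARABLE] = smooth_outliers(landscape.arable_yield) * area

    pasture = np.where(landscape.pasture_suitability >= params.suitability_threshold,
                       landscape.pasture_revenue, 0.0)
    out[Category.PASTURE] = pasture * area

    harvest_co2 = params.forest.mean_annual_harvest(
        landscape.forest_yield_class,
        new_planting=landscape.current_use != Category.PLANTATION)
    biomass = harvest_co2 / C_TO_CO2 / params.carbon_density
    out[Category.PLANTATION] = biomass * params.timber_price * area

    # semi-natural: no production by assumption
    return np.maximum(out, 0.0)


def biodiversity_benefit(landscape: Landscape, params: BiodiversityParams,
                         habitat_assignment: np.ndarray) -> np.ndarray:
    """Biodiversity layer: (4, n_rows, n_cols), unitless in [0, 1].

    The summed occurrence probability S of all species under each category is
    min-max normalised globally (over all cells x categories inside the
    convertible mask) and combined with the habitat-condition score by
    geometric mean. The condition is the "existing" score when the target
    equals the current use (and sub-type, for semi-natural), else the
    "newly created" score.
    """
    S = landscape.occurrence.sum(axis=0)  # (4, R, C)
    m = landscape.convertible
    vals = S[:, m]
    smin, smax = vals.min(), vals.max()
    if smax > smin:
        S_norm = np.clip((S - smin) / (smax - smin), 0.0, 1.0)
    else:
        S_norm = np.zeros_like(S)
    cond = np.empty_like(S)
    cu = landscape.current_use
    try:
        for cat in (Category.ARABLE, Category.PASTURE, Category.PLANTATION):
            name = cat.name.lower()
            cond[cat] = np.where(cu == cat,
                                 params.condition[(name, "existing")],
                                 params.condition[(name, "new")])
        exist_sub = np.array([params.condition[(SUBHABITAT_NAMES[s], "existing")]
                              for s in SubHabitat])
        new_sub = np.array([params.condition[(SUBHABITAT_NAMES[s], "new")]
                            for s in SubHabitat])
    except KeyError as e:
        raise ConfigError(f"missing habitat condition entry: {e}") from e
    is_existing_sn = (cu == Category.SEMINATURAL) & \
        (landscape.subhabitat == habitat_assignment)
    cond[Category.SEMINATURAL] = np.where(is_existing_sn,
                                          exist_sub[habitat_assignment],
                                          new_sub[habitat_assignment])
    return np.sqrt(S_norm * cond)


def assemble_benefit_maps(carbon: np.ndarray, production: np.ndarray,
                          biodiversity: np.ndarray, landscape: Landscape,
                          provenance: dict | None = None) -> BenefitMaps:
    """Stack the three objective layers into a :class:`BenefitMaps`."""
    shapes = {carbon.shape, production.shape, biodiversity.shape}
    if len(shapes) != 1 or carbon.shape != (N_CATEGORIES, *landscape.shape):
        raise AlignmentError(f"layer shapes disagree: {sorted(map(str, shapes))}")
    raw = np.empty((N_CATEGORIES, N_OBJECTIVES, *landscape.shape))
    raw[:, Objective.CARBON] = carbon
    raw[:, Objective.PRODUCTION] = production
    raw[:, Objective.BIODIVERSITY] = biodiversity
    m = landscape.convertible
    if not np.isfinite(raw[:, :, m]).all():
        raise DataError("non-finite benefit values inside the convertible mask")
    return BenefitMaps(raw=raw, convertible=m.copy(),
                       current_use=landscape.current_use.copy(),
                       cell_area=landscape.cell_area,
                       provenance=provenance or {})


def compute_benefit_maps(landscape: Landscape,
                         carbon_params: CarbonParams | None = None,
                         production_params: ProductionParams | None = None,
                         biodiversity_params: BiodiversityParams | None = None,
                         ) -> BenefitMaps:
    """Convenience: habitat assignment + all three layers + assembly."""
    cp = carbon_params or CarbonParams()
    pp = production_params or ProductionParams()
    bp = biodiversity_params or BiodiversityParams()
    hab = assign_future_habitat(landscape)
    maps = assemble_benefit_maps(
        carbon_benefit(landscape, cp, hab),
        production_benefit(landscape, pp),
        biodiversity_benefit(landscape, bp, hab),
        landscape,
        provenance={
            "carbon": {k: v for k, v in asdict(cp).items() if not isinstance(v, Mapping)},
            "production": asdict(pp),
            "biodiversity": "condition-table",
        },
    )
    return maps
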