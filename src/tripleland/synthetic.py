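"""Seeded synthetic landscape generator.

Generates landscapes with the statistical structure of the national inputs
the analysis was designed for — a categorical land-cover grid with spatial
autocorrelation and configurable class shares, continuous yield/suitability
surfaces, a peat-soil mask co-located with semi-natural cover, and per-species
occurrence-probability surfaces that respond to land cover — so that every
downstream stage (benefit maps, allocation, frontier, robustness) is testable
without any external download.

Spatial autocorrelation is produced by Gaussian smoothing of white noise
(kernel width = ``correlation_length`` cells). Land-cover classes are assigned
by thresholding the smoothed field at its empirical quantiles, which matches
the requested class shares up to integer rounding while preserving spatial
coherence. The peat mask is drawn from a second smoothed field biased towards
cells in the semi-natural band of the land-cover field, mimicking the
concentration of peaty soils under bog and fen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .categories import Category, N_CATEGORIES, SubHabitat
from .errors import ConfigError, DimensionError
from .landscape import Landscape

#: Current land-cover shares of convertible land in the study system
#: (arable, pasture, plantation forest, semi-natural).
DEFAULT_CLASS_SHARES: dict[Category, float] = {
    Category.ARABLE: 0.2577,
    Category.PASTURE: 0.3159,
    Category.PLANTATION: 0.0649,
    Category.SEMINATURAL: 0.3615,
}

#: Split of existing semi-natural land into sub-habitats (free parameter of
#: the generator; the four sub-types all occur at non-trivial frequency).
DEFAULT_SUBHABITAT_SHARES: dict[SubHabitat, float] = {
    SubHabitat.GRASSLAND: 0.35,
    SubHabitat.HEATH: 0.25,
    SubHabitat.FENBOG: 0.20,
    SubHabitat.BROADLEAVED: 0.20,
}

#: Mean category affinity of a species' occurrence probability. Semi-natural
#: habitat is systematically favoured, as for priority species.
DEFAULT_AFFINITY: dict[Category, float] = {
    Category.ARABLE: 0.20,
    Category.PASTURE: 0.30,
    Category.PLANTATION: 0.35,
    Category.SEMINATURAL: 0.70,
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic landscape generator.

    ``cell_area`` defaults to 25 ha (500 m x 500 m cells). ``class_shares``
    must sum to 1. ``correlation_length`` is the Gaussian kernel width in
    cells. ``peat_fraction`` is the fraction of cells given peaty soil.
    ``affinity`` maps category -> mean occurrence affinity in [0, 1]; a
    per-species jitter of sd ``affinity_jitter`` is applied (clipped to
    [0, 1]). ``exclusion_fraction`` masks that share of cells as
    non-convertible (water/urban/rock analogue).
    """

    n_rows: int
    n_cols: int
    seed: int = 0
    cell_area: float = 25.0
    class_shares: Mapping[Category, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SHARES))
    correlation_length: float = 5.0
    peat_fraction: float = 0.12
    n_species: int = 86
    subhabitat_shares: Mapping[SubHabitat, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBHABITAT_SHARES))
    affinity: Mapping[Category, float] = field(
        default_factory=lambda: dict(DEFAULT_AFFINITY))
    affinity_jitter: float = 0.10
    exclusion_fraction: float = 0.0
    peat_bias: float = 1.5

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise DimensionError(
                f"grid dimensions must be >= 1, got {self.n_rows}x{self.n_cols}")
        if self.n_species < 1:
            raise ConfigError("n_species must be >= 1")
        self.class_shares = {Category(k): float(v) for k, v in self.class_shares.items()}
        for cat in Category:
            self.class_shares.setdefault(cat, 0.0)
        total = sum(self.class_shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class_shares sum to {total!r}, expected 1")
        for k, v in self.class_shares.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"class share for {k.name} outside [0, 1]: {v}")
        for name in ("peat_fraction", "exclusion_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} outside [0, 1]: {v}")
        if self.cell_area <= 0:
            raise ConfigError("cell_area must be positive")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Standardised Gaussian-smoothed white noise (zero mean, unit sd)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    sd = f.std()
    if sd > 0:
        f = (f - f.mean()) / sd
    return f


def _largest_remainder_counts(shares: np.ndarray, n: int) -> np.ndarray:
    """Integer counts summing to n, proportional to shares (largest remainder)."""
    exact = shares * n
    counts = np.floor(exact).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(exact - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def _assign_by_rank(fld: np.ndarray, shares: np.ndarray) -> np.ndarray:
    """Threshold a field at its empirical quantiles to match shares exactly
    (up to integer rounding); classes occupy ascending bands of the field."""
    flat = fld.ravel()
    counts = _largest_remainder_counts(shares, flat.size)
    order = np.argsort(flat, kind="stable")
    codes = np.empty(flat.size, dtype=np.int8)
    codes[order] = np.repeat(np.arange(len(shares), dtype=np.int8), counts)
    return codes.reshape(fld.shape)


def generate_occurrence_surfaces(config: SyntheticConfig,
                                 landscape: Landscape) -> np.ndarray:
    """Per-species, per-category occurrence-probability surfaces.

    Each species gets one smooth spatial base field squashed to (0, 1),
    multiplied by a per-species category affinity so that high-affinity
    categories receive pointwise higher probabilities. Returns an array of
    shape (n_species, 4, n_rows, n_cols) with values in [0, 1].
    """
    if config.n_species < 1:
        raise ConfigError("n_species must be >= 1")
    shape = landscape.shape
    ss = np.random.SeedSequence([config.seed, 0x0CC])
    rng = np.random.default_rng(ss)
    base_affinity = np.array([config.affinity.get(c, 0.5) for c in Category])
    occ = np.empty((config.n_species, N_CATEGORIES, *shape), dtype=np.float64)
    for s in range(config.n_species):
        base = 1.0 / (1.0 + np.exp(-_smooth_field(rng, shape, config.correlation_length)))
        aff = np.clip(base_affinity + config.affinity_jitter * rng.standard_normal(N_CATEGORIES),
                      0.0, 1.0)
        # multiplicative modulation keeps [0, 1] and preserves the pointwise
        # ordering implied by the affinities at every cell
        occ[s] = np.clip(base[None] * (0.3 + 0.7 * aff)[:, None, None], 0.0, 1.0)
    return occ


def generate_landscape(config: SyntheticConfig) -> Landscape:
    """Generate a complete, validated synthetic :class:`Landscape`.

    Deterministic for a fixed config (all randomness is derived from
    ``config.seed`` through independent seed-sequence streams).
    """
    shape = (config.n_rows, config.n_cols)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x1A4D]))
    sigma = config.correlation_length

    shares = np.array([config.class_shares[c] for c in Category])
    cover_field = _smooth_field(rng, shape, sigma)
    current_use = _assign_by_rank(cover_field, shares)

    # peat: second smoothed field, biased towards the semi-natural band
    peat_field = _smooth_field(rng, shape, sigma)
    peat_field = peat_field + config.peat_bias * (current_use == Category.SEMINATURAL)
    n_peat = int(round(config.peat_fraction * peat_field.size))
    peat = np.zeros(shape, dtype=bool)
    if n_peat > 0:
        idx = np.argsort(peat_field.ravel(), kind="stable")[-n_peat:]
        peat.ravel()[idx] = True

    # sub-habitat labels on existing semi-natural cells; peat forces fen/bog
    subhabitat = np.full(shape, -1, dtype=np.int8)
    sn_mask = current_use == Category.SEMINATURAL
    if sn_mask.any():
        sub_field = _smooth_field(rng, shape, sigma)
        sub_shares = np.array([config.subhabitat_shares.get(s, 0.0) for s in SubHabitat])
        sub_shares = sub_shares / sub_shares.sum()
        codes = _assign_by_rank(sub_field[sn_mask][None, :], sub_shares)[0]
        subhabitat[sn_mask] = codes
        subhabitat[sn_mask & peat] = SubHabitat.FENBOG

    # attribute surfaces: log-normal revenue potentials, bounded suitability,
    # yield classes in the range of conifer yield tables (4-24 m^3/ha/yr)
    arable_yield = 600.0 * np.exp(0.35 * _smooth_field(rng, shape, sigma))
    pasture_suitability = np.clip(55.0 + 25.0 * _smooth_field(rng, shape, sigma), 0.0, 100.0)
    pasture_revenue = 450.0 * np.exp(0.30 * _smooth_field(rng, shape, sigma))
    forest_yield_class = np.clip(14.0 + 5.0 * _smooth_field(rng, shape, sigma), 4.0, 24.0)

    convertible = np.ones(shape, dtype=bool)
    if config.exclusion_fraction > 0:
        excl_field = _smooth_field(rng, shape, sigma)
        n_excl = int(round(config.exclusion_fraction * excl_field.size))
        if n_excl > 0:
            idx = np.argsort(excl_field.ravel(), kind="stable")[-n_excl:]
            convertible.ravel()[idx] = False

    landscape = Landscape(
        current_use=current_use,
        subhabitat=subhabitat,
        convertible=convertible,
        arable_yield=arable_yield,
        pasture_suitability=pasture_suitability,
        pasture_revenue=pasture_revenue,
        forest_yield_class=forest_yield_class,
        peat=peat,
        occurrence=np.empty((config.n_species, N_CATEGORIES, *shape)),
        cell_area=config.cell_area,
        meta={"seed": config.seed, "correlation_length": sigma},
    )
    landscape.occurrence = generate_occurrence_surfaces(config, landscape)
    landscape.validate()
    return landscape
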