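"""Benefit engine: fertiliser stoichiometry, habitat assignment, outlier
smoothing, and the three objective layers."""

import numpy as np
import pytest

import tripleland as tl
from tripleland.benefits import DEFAULT_CONDITION
from tripleland.categories import Category, N_CATEGORIES, Objective, SubHabitat
from tripleland.errors import (AlignmentError, AssignmentError, DataError,
                               SmoothingError)


def make_landscape(current_use, subhabitat=None, peat=None, yield_class=0.0,
                   suitability=50.0, n_species=1, occurrence=None,
                   cell_area=25.0):
    """Hand-built landscape from a current-use array."""
    cu = np.asarray(current_use, dtype=np.int8)
    shape = cu.shape
    if subhabitat is None:
        subhabitat = np.where(cu == Category.SEMINATURAL,
                              SubHabitat.GRASSLAND, -1).astype(np.int8)
    if peat is None:
        peat = np.zeros(shape, dtype=bool)
    if occurrence is None:
        occurrence = np.full((n_species, N_CATEGORIES, *shape), 0.5)
    return tl.Landscape(
        current_use=cu, subhabitat=np.asarray(subhabitat, dtype=np.int8),
        convertible=np.ones(shape, dtype=bool),
        arable_yield=np.full(shape, 500.0),
        pasture_suitability=np.full(shape, float(suitability)),
        pasture_revenue=np.full(shape, 400.0),
        forest_yield_class=np.full(shape, float(yield_class)),
        peat=np.asarray(peat, dtype=bool), occurrence=occurrence,
        cell_area=cell_area)


# ---------------------------------------------------------------- fertiliser

@pytest.mark.parametrize("rate,gwp,expected,tol", [
    (1460.67, 273.0, 626.63, 0.01),      # published conversion
    (0.0, 273.0, 0.0, 1e-12),
    (28.0, 273.0, 12.012, 1e-9),         # 44 x 273 / 1000 by hand
])
def test_fertiliser_emission_conversion(rate, gwp, expected, tol):
    assert tl.fertiliser_emissions(rate, gwp) == pytest.approx(expected, abs=tol)


def test_fertiliser_negative_rate_rejected():
    with pytest.raises(DataError):
        tl.fertiliser_emissions(-1.0)


# ------------------------------------------------------- habitat assignment

def test_single_donor_assigns_everywhere():
    cu = np.zeros((4, 4), dtype=int)
    cu[2, 2] = Category.SEMINATURAL
    sub = np.full((4, 4), -1, dtype=int)
    sub[2, 2] = SubHabitat.BROADLEAVED
    ls = make_landscape(cu, subhabitat=sub)
    assert (tl.assign_future_habitat(ls) == SubHabitat.BROADLEAVED).all()


def test_peat_overrides_nearest_donor():
    cu = np.zeros((1, 3), dtype=int)
    cu[0, 0] = Category.SEMINATURAL
    sub = np.full((1, 3), -1, dtype=int)
    sub[0, 0] = SubHabitat.BROADLEAVED
    peat = np.array([[False, True, False]])
    ls = make_landscape(cu, subhabitat=sub, peat=peat)
    hab = tl.assign_future_habitat(ls)
    assert hab[0, 1] == SubHabitat.FENBOG       # peat beats the donor
    assert hab[0, 2] == SubHabitat.BROADLEAVED


def test_assignment_matches_brute_force_nearest_donor():
    rng = np.random.default_rng(0)
    cu = np.zeros((5, 5), dtype=int)
    cu[0, 0] = cu[4, 4] = Category.SEMINATURAL
    sub = np.full((5, 5), -1, dtype=int)
    sub[0, 0], sub[4, 4] = SubHabitat.HEATH, SubHabitat.GRASSLAND
    ls = make_landscape(cu, subhabitat=sub)
    hab = tl.assign_future_habitat(ls)
    donors = [(0, 0, SubHabitat.HEATH), (4, 4, SubHabitat.GRASSLAND)]
    for r in range(5):
        for c in range(5):
            dists = [(np.hypot(r - dr, c - dc), s) for dr, dc, s in donors]
            dmin = min(d for d, _ in dists)
            allowed = {s for d, s in dists if d == dmin}
            assert hab[r, c] in allowed
    # existing donors keep their own sub-type
    assert hab[0, 0] == SubHabitat.HEATH and hab[4, 4] == SubHabitat.GRASSLAND


def test_no_donor_no_peat_raises():
    ls = make_landscape(np.zeros((3, 3), dtype=int))
    with pytest.raises(AssignmentError):
        tl.assign_future_habitat(ls)


def test_no_donor_but_peat_gives_fenbog():
    peat = np.zeros((3, 3), dtype=bool)
    peat[1, 1] = True
    ls = make_landscape(np.zeros((3, 3), dtype=int), peat=peat)
    assert (tl.assign_future_habitat(ls) == SubHabitat.FENBOG).all()


# --------------------------------------------------------- outlier smoothing

def test_constant_surface_unchanged():
    s = np.full((5, 5), 3.0)
    assert np.array_equal(tl.smooth_outliers(s), s)


def test_center_outlier_replaced_by_neighbour_mean():
    s = np.ones((3, 3))
    s[1, 1] = 1000.0
    out = tl.smooth_outliers(s)
    assert out[1, 1] == pytest.approx(1.0)
    assert np.array_equal(out[s != 1000.0], s[s != 1000.0])


def test_replacement_averages_only_finite_neighbours():
    s = np.linspace(1.0, 2.0, 12).reshape(3, 4)
    s[0, 0] = np.nan
    s[0, 1] = 1000.0
    out = tl.smooth_outliers(s)
    expected = np.mean([s[0, 2], s[1, 0], s[1, 1], s[1, 2]])
    assert out[0, 1] == pytest.approx(expected)   # NaN neighbour excluded
    assert np.isnan(out[0, 0])


def test_idempotent_when_no_new_outliers():
    rng = np.random.default_rng(1)
    s = rng.uniform(10, 12, size=(8, 8))
    s[3, 3] = 100.0
    once = tl.smooth_outliers(s)
    assert np.allclose(tl.smooth_outliers(once), once)


def test_too_small_surface_rejected():
    with pytest.raises(DataError):
        tl.smooth_outliers(np.ones((2, 2)))


# -------------------------------------------------------------- carbon layer

def test_identity_conversion_is_zero_without_recurring_terms():
    ls = make_landscape(np.full((3, 3), Category.SEMINATURAL, dtype=int))
    params = tl.CarbonParams()
    hab = tl.assign_future_habitat(ls)
    carbon = tl.carbon_benefit(ls, params, hab)
    # grassland cells kept as grassland: no stock delta, no recurring flux
    assert np.allclose(carbon[Category.SEMINATURAL], 0.0)


def test_arable_recurring_fertiliser_term():
    ls = make_landscape(np.full((2, 2), Category.ARABLE, dtype=int))
    ls2 = make_landscape(np.full((2, 2), Category.SEMINATURAL, dtype=int))
    carbon = tl.carbon_benefit(ls, tl.CarbonParams(),
                               np.full((2, 2), SubHabitat.GRASSLAND, dtype=np.int8))
    # arable kept arable: only the fertiliser term, -0.62663 t/ha x 25 ha
    assert np.allclose(carbon[Category.ARABLE], -0.62662743 * 25.0, rtol=1e-6)
    del ls2


def test_pasture_recurring_livestock_term():
    ls = make_landscape(np.full((2, 2), Category.PASTURE, dtype=int))
    carbon = tl.carbon_benefit(ls, tl.CarbonParams(),
                               np.full((2, 2), SubHabitat.GRASSLAND, dtype=np.int8))
    assert np.allclose(carbon[Category.PASTURE], -7.62 * 25.0)


def test_stock_component_antisymmetry():
    """delta(a->b) = -delta(b->a) for the stock term (recurring terms off)."""
    params = tl.CarbonParams(fertiliser_n2o_n=0.0, livestock_emissions=0.0)
    hab = np.full((1, 1), SubHabitat.GRASSLAND, dtype=np.int8)
    ls_a = make_landscape(np.full((1, 1), Category.ARABLE, dtype=int))
    ls_p = make_landscape(np.full((1, 1), Category.PASTURE, dtype=int))
    c_a = tl.carbon_benefit(ls_a, params, hab)
    c_p = tl.carbon_benefit(ls_p, params, hab)
    assert c_a[Category.PASTURE, 0, 0] == pytest.approx(
        -c_p[Category.ARABLE, 0, 0])


def test_peat_flux_applies_on_peat_cells():
    peat = np.array([[True, False]])
    ls = make_landscape(np.full((1, 2), Category.PASTURE, dtype=int), peat=peat)
    params = tl.CarbonParams(livestock_emissions=0.0)
    hab = np.full((1, 2), SubHabitat.FENBOG, dtype=np.int8)
    carbon = tl.carbon_benefit(ls, params, hab)
    flux = params.peat_flux["grassland"]
    assert carbon[Category.PASTURE, 0, 0] == pytest.approx(flux * 25.0)
    assert carbon[Category.PASTURE, 0, 1] == pytest.approx(0.0)


# ---------------------------------------------------------- production layer

def test_seminatural_production_is_zero(small_landscape):
    prod = tl.production_benefit(small_landscape, tl.ProductionParams())
    assert np.allclose(prod[Category.SEMINATURAL], 0.0)
    assert (prod >= 0).all()


def test_pasture_suitability_threshold_semantics():
    below = make_landscape(np.zeros((3, 3), dtype=int), suitability=19.0)
    at = make_landscape(np.zeros((3, 3), dtype=int), suitability=20.0)
    p_below = tl.production_benefit(below, tl.ProductionParams())
    p_at = tl.production_benefit(at, tl.ProductionParams())
    assert np.allclose(p_below[Category.PASTURE], 0.0)
    assert (p_at[Category.PASTURE] > 0).all()


def test_zero_forest_growth_zero_timber_revenue():
    ls = make_landscape(np.zeros((3, 3), dtype=int), yield_class=0.0)
    prod = tl.production_benefit(ls, tl.ProductionParams())
    assert np.allclose(prod[Category.PLANTATION], 0.0)


def test_arable_yield_monotonicity():
    ls = make_landscape(np.zeros((4, 4), dtype=int))
    ls.arable_yield = np.linspace(400, 600, 16).reshape(4, 4)
    base = tl.production_benefit(ls, tl.ProductionParams())
    ls.arable_yield = ls.arable_yield.copy()
    ls.arable_yield[2, 2] += 50.0
    bumped = tl.production_benefit(ls, tl.ProductionParams())
    assert bumped[Category.ARABLE, 2, 2] >= base[Category.ARABLE, 2, 2]
    others = np.ones((4, 4), dtype=bool)
    others[2, 2] = False
    assert np.allclose(bumped[Category.ARABLE][others],
                       base[Category.ARABLE][others])


# -------------------------------------------------------- biodiversity layer

def test_zero_occurrence_annihilates_condition():
    occ = np.zeros((1, N_CATEGORIES, 2, 2))
    occ[0, Category.SEMINATURAL] = 1.0  # spread so normalisation is non-trivial
    ls = make_landscape(np.full((2, 2), Category.SEMINATURAL, dtype=int),
                        occurrence=occ)
    hab = tl.assign_future_habitat(ls)
    bio = tl.biodiversity_benefit(ls, tl.BiodiversityParams(), hab)
    assert np.allclose(bio[Category.ARABLE], 0.0)  # S_norm = 0 there


def test_max_occurrence_arable_condition():
    occ = np.zeros((1, N_CATEGORIES, 1, 2))
    occ[0, Category.ARABLE, 0, 0] = 1.0   # this cell-category pair is the max
    cu = np.array([[Category.ARABLE, Category.SEMINATURAL]], dtype=int)
    ls = make_landscape(cu, occurrence=occ)
    hab = tl.assign_future_habitat(ls)
    bio = tl.biodiversity_benefit(ls, tl.BiodiversityParams(), hab)
    assert bio[Category.ARABLE, 0, 0] == pytest.approx(np.sqrt(0.08), abs=1e-9)


def test_established_seminatural_beats_newly_created():
    assert DEFAULT_CONDITION[("grassland", "existing")] < \
        DEFAULT_CONDITION[("broadleaved", "existing")]
    occ = np.full((1, N_CATEGORIES, 1, 2), 0.5)
    occ[0, 0, 0, 0] = 1.0
    occ[0, 0, 0, 1] = 0.0  # spread for normalisation
    cu = np.array([[Category.SEMINATURAL, Category.ARABLE]], dtype=int)
    sub = np.array([[SubHabitat.BROADLEAVED, -1]], dtype=int)
    ls = make_landscape(cu, subhabitat=sub, occurrence=occ)
    hab = tl.assign_future_habitat(ls)
    bio = tl.biodiversity_benefit(ls, tl.BiodiversityParams(), hab)
    # same S_norm (0.5 everywhere for seminatural), existing broadleaved
    # (0.70) beats a new broadleaved conversion (0.33)
    assert bio[Category.SEMINATURAL, 0, 0] > bio[Category.SEMINATURAL, 0, 1]


def test_biodiversity_layer_in_unit_interval(small_maps):
    bio = small_maps.layer(Objective.BIODIVERSITY)
    m = small_maps.convertible
    assert bio[:, m].min() >= 0 and bio[:, m].max() <= 1


# ------------------------------------------------------------------ assembly

def test_assemble_shape_contract(small_landscape):
    shape = (N_CATEGORIES, *small_landscape.shape)
    maps = tl.assemble_benefit_maps(np.zeros(shape), np.zeros(shape),
                                    np.zeros(shape), small_landscape)
    assert maps.raw.shape == (N_CATEGORIES, 3, *small_landscape.shape)


def test_assemble_mismatched_shapes_error(small_landscape):
    shape = (N_CATEGORIES, *small_landscape.shape)
    with pytest.raises(AlignmentError):
        tl.assemble_benefit_maps(np.zeros(shape), np.zeros((N_CATEGORIES, 2, 2)),
                                 np.zeros(shape), small_landscape)
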