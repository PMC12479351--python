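"""Allocator: normalisation, weighted benefit, per-cell argmax optimality
against exhaustive search, and the budget-constrained variant."""

import itertools

import numpy as np
import pytest

import tripleland as tl
from tripleland.categories import Category, N_CATEGORIES, Objective
from tripleland.errors import ConfigError
from tripleland.weights import WeightVector

from conftest import random_maps


def brute_force_best(maps, w, max_conversions=None):
    """Exhaustive search over all 4^n allocations (optionally capped at
    max_conversions changes); returns the maximal total weighted benefit."""
    norm = tl.normalize_benefits(maps)
    b = tl.weighted_benefit(norm, w)          # (4, 1, n)
    n = b.shape[2]
    cur = maps.current_use[0]
    best = -np.inf
    for alloc in itertools.product(range(N_CATEGORIES), repeat=n):
        if max_conversions is not None:
            if sum(k != cur[i] for i, k in enumerate(alloc)) > max_conversions:
                continue
        total = sum(b[k, 0, i] for i, k in enumerate(alloc))
        best = max(best, total)
    return best


def weighted_total(scenario, norm, w):
    b = tl.weighted_benefit(norm, w)
    m = scenario.convertible
    k = scenario.assignment[m].astype(int)
    return float(b[:, m][k, np.arange(k.size)].sum())


# ------------------------------------------------------------- normalisation

def test_normalize_midpoint_and_endpoints():
    rng = np.random.default_rng(0)
    maps = random_maps(10, rng)
    maps.raw[:, 0] = 0.0
    maps.raw[0, 0, 0, 0], maps.raw[1, 0, 0, 0] = -5.0, 5.0
    norm = tl.normalize_benefits(maps)
    assert norm.norm[2, 0, 0, 1] == pytest.approx(0.5)   # raw 0 between -5, 5
    assert norm.norm[1, 0, 0, 0] == pytest.approx(1.0)
    assert norm.norm[0, 0, 0, 0] == pytest.approx(0.0)
    assert norm.norm.min() >= 0 and norm.norm.max() <= 1


def test_constant_layer_warns_and_zeroes():
    rng = np.random.default_rng(1)
    maps = random_maps(6, rng)
    maps.raw[:, Objective.CARBON] = 3.14
    with pytest.warns(UserWarning, match="constant carbon"):
        norm = tl.normalize_benefits(maps)
    assert (norm.norm[:, Objective.CARBON] == 0).all()


# ---------------------------------------------------------- weighted benefit

def test_corner_weight_projects_single_layer(small_norm):
    b = tl.weighted_benefit(small_norm, WeightVector(100, 0, 0))
    assert np.array_equal(b, small_norm.norm[:, Objective.CARBON])


def test_weighted_benefit_hand_arithmetic():
    rng = np.random.default_rng(2)
    maps = random_maps(1, rng)
    norm = tl.normalize_benefits(maps)
    norm.norm[0, :, 0, 0] = [0.2, 0.4, 0.6]
    b = tl.weighted_benefit(norm, WeightVector(50, 30, 20))
    assert b[0, 0, 0] == pytest.approx(0.1 + 0.12 + 0.12)


def test_equal_layers_invariant_to_weights(small_norm):
    norm = tl.NormalizedBenefits(
        norm=np.full_like(small_norm.norm, 0.37),
        convertible=small_norm.convertible, current_use=small_norm.current_use)
    for w in [(100, 0, 0), (20, 30, 50), (0, 0, 100)]:
        assert np.allclose(tl.weighted_benefit(norm, WeightVector(*w)), 0.37)


# -------------------------------------------------------- optimal allocation

def test_unique_max_chosen():
    rng = np.random.default_rng(3)
    maps = random_maps(1, rng, current_use=np.array([[0]]))
    norm = tl.normalize_benefits(maps)
    norm.norm[:, :, 0, 0] = 0.0
    norm.norm[:, Objective.CARBON, 0, 0] = [0.1, 0.9, 0.3, 0.2]
    sc = tl.optimal_allocation(norm, WeightVector(100, 0, 0))
    assert sc.assignment[0, 0] == Category.PASTURE


def test_exact_tie_keeps_incumbent():
    rng = np.random.default_rng(4)
    maps = random_maps(1, rng, current_use=np.array([[Category.ARABLE]]))
    norm = tl.normalize_benefits(maps)
    norm.norm[:, :, 0, 0] = 0.0
    norm.norm[Category.ARABLE, Objective.CARBON, 0, 0] = 0.8
    norm.norm[Category.PASTURE, Objective.CARBON, 0, 0] = 0.8
    sc = tl.optimal_allocation(norm, WeightVector(100, 0, 0))
    assert sc.assignment[0, 0] == Category.ARABLE


@pytest.mark.parametrize("n_cells", [4, 6])
def test_optimal_matches_exhaustive_search(n_cells):
    rng = np.random.default_rng(5)
    maps = random_maps(n_cells, rng)
    norm = tl.normalize_benefits(maps)
    for w in [WeightVector(100, 0, 0), WeightVector(0, 0, 100),
              WeightVector(35, 35, 30), WeightVector(5, 90, 5)]:
        sc = tl.optimal_allocation(norm, w, maps)
        assert weighted_total(sc, norm, w) == pytest.approx(
            brute_force_best(maps, w), abs=1e-12)


def test_optimal_beats_random_allocations(small_norm, small_maps):
    rng = np.random.default_rng(6)
    w = WeightVector(40, 35, 25)
    sc = tl.optimal_allocation(small_norm, w, small_maps)
    best = weighted_total(sc, small_norm, w)
    m = small_norm.convertible
    n = int(m.sum())
    b = tl.weighted_benefit(small_norm, w)[:, m]
    for _ in range(200):
        alloc = rng.integers(0, N_CATEGORIES, size=n)
        assert b[alloc, np.arange(n)].sum() <= best + 1e-12


def test_corner_weight_attains_global_carbon_max(small_norm, small_maps):
    sc = tl.optimal_allocation(small_norm, WeightVector(100, 0, 0), small_maps)
    m = small_maps.convertible
    max_carbon = small_maps.raw[:, Objective.CARBON][:, m].max(axis=0).sum()
    assert sc.performance_raw.carbon == pytest.approx(max_carbon)


# --------------------------------------------------------- budget allocation

def test_budget_zero_keeps_current(small_norm, small_maps):
    sc = tl.budget_allocation(small_norm, WeightVector(30, 30, 40), 0.0,
                              maps=small_maps)
    assert sc.conversion_rate == 0.0
    assert np.array_equal(sc.assignment[sc.convertible],
                          sc.current_use[sc.convertible])


def test_budget_one_equals_unconstrained(small_norm, small_maps):
    w = WeightVector(25, 45, 30)
    full = tl.budget_allocation(small_norm, w, 1.0, maps=small_maps)
    opt = tl.optimal_allocation(small_norm, w, small_maps)
    assert np.array_equal(full.assignment, opt.assignment)


def test_budget_matches_exhaustive_search_two_conversions():
    rng = np.random.default_rng(7)
    maps = random_maps(8, rng)
    norm = tl.normalize_benefits(maps)
    for w in [WeightVector(100, 0, 0), WeightVector(30, 30, 40)]:
        sc = tl.budget_allocation(norm, w, budget=0.25, seed=0, maps=maps)
        assert sc.converted.sum() <= 2
        assert weighted_total(sc, norm, w) == pytest.approx(
            brute_force_best(maps, w, max_conversions=2), abs=1e-12)


def test_budget_monotonicity_and_rate_cap(small_norm, small_maps):
    rng = np.random.default_rng(8)
    for _ in range(5):
        parts = rng.multinomial(20, [1 / 3] * 3) * 5
        w = WeightVector(*parts)
        prev = -np.inf
        for budget in np.linspace(0, 1, 11):
            sc = tl.budget_allocation(small_norm, w, float(budget), seed=1,
                                      maps=small_maps)
            total = weighted_total(sc, small_norm, w)
            assert total >= prev - 1e-12
            assert sc.conversion_rate <= budget + 1e-12
            prev = total


def test_budget_rate_below_budget_when_no_gains_left():
    rng = np.random.default_rng(9)
    maps = random_maps(10, rng, current_use=np.zeros((1, 10), dtype=int))
    norm = tl.normalize_benefits(maps)
    # make arable (current) the best category everywhere: no positive delta
    norm.norm[:] = 0.0
    norm.norm[Category.ARABLE] = 1.0
    sc = tl.budget_allocation(norm, WeightVector(34, 33, 33), 0.8, maps=maps)
    assert sc.conversion_rate == 0.0


def test_budget_tie_break_seeded():
    rng = np.random.default_rng(10)
    maps = random_maps(30, rng, current_use=np.zeros((1, 30), dtype=int))
    norm = tl.normalize_benefits(maps)
    norm.norm[:] = 0.0
    norm.norm[Category.PASTURE] = 0.5  # identical delta on every cell
    a1 = tl.budget_allocation(norm, WeightVector(50, 25, 25), 0.3, seed=1)
    a2 = tl.budget_allocation(norm, WeightVector(50, 25, 25), 0.3, seed=1)
    b = tl.budget_allocation(norm, WeightVector(50, 25, 25), 0.3, seed=2)
    assert np.array_equal(a1.assignment, a2.assignment)  # same seed, same pick
    assert a1.converted.sum() == b.converted.sum() == 9  # floor(0.3 x 30)
    assert not np.array_equal(a1.assignment, b.assignment)  # ties reshuffled


def test_budget_out_of_range_rejected(small_norm):
    with pytest.raises(ConfigError):
        tl.budget_allocation(small_norm, WeightVector(100, 0, 0), 1.5)


# ------------------------------------------------------------------ evaluate

def test_evaluate_single_cell_equals_raw_row():
    rng = np.random.default_rng(11)
    maps = random_maps(1, rng)
    norm = tl.normalize_benefits(maps)
    sc = tl.optimal_allocation(norm, WeightVector(0, 100, 0), maps)
    k = sc.assignment[0, 0]
    assert sc.performance_raw == pytest.approx(tuple(maps.raw[k, :, 0, 0]))


def test_evaluate_additive_over_disjoint_halves(small_maps, small_norm):
    sc = tl.optimal_allocation(small_norm, WeightVector(30, 40, 30), small_maps)
    whole = np.array(sc.performance_raw)
    m = small_maps.convertible
    half = np.zeros_like(m)
    half[:10] = True
    parts = []
    for piece in (half & m, ~half & m):
        k = sc.assignment[piece].astype(int)
        vals = small_maps.raw[:, :, piece]
        parts.append(vals[k, :, np.arange(k.size)].sum(axis=0))
    assert np.allclose(parts[0] + parts[1], whole)
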