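"""Shared study setup for the analysis scripts.

One synthetic landscape stands in for the national datasets throughout the
analysis: a 50 x 50 grid (2,500 convertible cells of 25 ha) with the
observed land-cover shares, peaty soils under semi-natural cover, and a
12-species occurrence stack. Every script rebuilds it from the same seed, so
all steps are reproducible and mutually consistent.
"""

from pathlib import Path

import tripleland as tl

GRID = 50
SEED = 7
N_SPECIES = 12
WEIGHT_STEP = 5

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def study_config() -> tl.SyntheticConfig:
    return tl.SyntheticConfig(n_rows=GRID, n_cols=GRID, seed=SEED,
                              n_species=N_SPECIES)


def build():
    """Landscape, benefit maps, normalised benefits and bounds."""
    landscape = tl.generate_landscape(study_config())
    maps = tl.compute_benefit_maps(landscape)
    norm = tl.normalize_benefits(maps)
    bounds = tl.compute_bounds(maps)
    return landscape, maps, norm, bounds


def unbudgeted_scenarios(norm, maps):
    return [tl.optimal_allocation(norm, w, maps)
            for w in tl.enumerate_weights(WEIGHT_STEP)]
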