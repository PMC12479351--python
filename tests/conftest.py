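import numpy as np
import pytest

import tripleland as tl
from tripleland.categories import N_CATEGORIES, N_OBJECTIVES


@pytest.fixture(scope="session")
def small_config():
    return tl.SyntheticConfig(n_rows=20, n_cols=20, seed=42, n_species=6)


@pytest.fixture(scope="session")
def small_landscape(small_config):
    return tl.generate_landscape(small_config)


@pytest.fixture(scope="session")
def small_maps(small_landscape):
    return tl.compute_benefit_maps(small_landscape)


@pytest.fixture(scope="session")
def small_norm(small_maps):
    return tl.normalize_benefits(small_maps)


def random_maps(n_cells: int, rng: np.random.Generator,
                current_use: np.ndarray | None = None) -> tl.BenefitMaps:
    """A 1 x n_cells BenefitMaps with i.i.d. benefit values, for oracle tests."""
    raw = rng.standard_normal((N_CATEGORIES, N_OBJECTIVES, 1, n_cells))
    raw[:, 1] = np.abs(raw[:, 1])                       # production >= 0
    raw[:, 2] = 1 / (1 + np.exp(-raw[:, 2]))            # biodiversity in [0,1]
    if current_use is None:
        current_use = rng.integers(0, N_CATEGORIES, size=(1, n_cells))
    return tl.BenefitMaps(raw=raw,
                          convertible=np.ones((1, n_cells), dtype=bool),
                          current_use=current_use.astype(np.int8),
                          cell_area=25.0)
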