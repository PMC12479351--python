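"""End-to-end pipeline: synthetic landscape -> benefit maps -> scenario grid
-> frontier tables -> robustness maps.

Configuration lives in a single YAML file (see :class:`PipelineConfig`);
every stage logs its timing to stderr and all outputs are plain text (ASCII
grids and CSV). The pipeline is fully reproducible from (config, seeds).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gridio
from .allocate import (NormalizedBenefits, Scenario, budget_allocation,
                       current_scenario, normalize_benefits, optimal_allocation)
from .benefits import BenefitMaps, compute_benefit_maps
from .categories import CATEGORY_NAMES, Category
from .errors import ConfigError
from .landscape import Landscape
from .pareto import compute_bounds, normalize_performance, pareto_filter
from .robustness import conversion_frequency
from .synthetic import SyntheticConfig, generate_landscape
from .weights import GROUP_LABELS, classify_weighting, enumerate_weights

log = logging.getLogger("tripleland")

DEFAULT_BUDGETS = (0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)

SCENARIO_COLUMNS = [
    "w_carbon_pct", "w_production_pct", "w_biodiversity_pct",
    "budget_fraction", "seed",
    "carbon_tco2e_per_yr", "production_gbp_per_yr", "biodiversity_index",
    "carbon_norm_0to1", "production_norm_0to1", "biodiversity_norm_0to1",
    "conversion_rate_fraction", "groups", "is_pareto", "is_strictly_better",
]


@dataclass
class PipelineConfig:
    """Pipeline settings: landscape generator, weight grid, budgets, seeds."""

    synthetic: SyntheticConfig
    weight_step: int = 5
    budgets: tuple[float, ...] = DEFAULT_BUDGETS
    tie_rule: str = "incumbent"
    allocation_seed: int = 0

    def __post_init__(self) -> None:
        if self.weight_step <= 0 or 100 % self.weight_step != 0:
            raise ConfigError(f"weight_step must divide 100: {self.weight_step}")
        b = tuple(float(x) for x in self.budgets)
        if any(not 0.0 <= x <= 1.0 for x in b):
            raise ConfigError(f"budgets outside [0, 1]: {b}")
        if list(b) != sorted(set(b)):
            raise ConfigError("budgets must be sorted and unique")
        self.budgets = b

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        syn = SyntheticConfig(**data.pop("synthetic", {"n_rows": 50, "n_cols": 50}))
        return cls(synthetic=syn, **data)

    def to_yaml(self) -> str:
        syn = {k: (dict((int(kk), vv) for kk, vv in v.items())
                   if isinstance(v, dict) else v)
               for k, v in vars(self.synthetic).items()}
        return yaml.safe_dump({"synthetic": syn, "weight_step": self.weight_step,
                               "budgets": list(self.budgets),
                               "tie_rule": self.tie_rule,
                               "allocation_seed": self.allocation_seed},
                              sort_keys=False)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kw):
            t0 = time.perf_counter()
            out = fn(*args, **kw)
            log.info("stage %-12s %6.2f s", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def scenario_row(sc: Scenario, norm_perf, groups, is_pareto: bool,
                 is_better: bool) -> list:
    p = sc.performance_raw
    return [*sc.weighting, sc.budget, sc.seed, p.carbon, p.production,
            p.biodiversity, *norm_perf, sc.conversion_rate,
            "|".join(sorted(groups)), is_pareto, is_better]


@_stage("scenarios")
def build_scenarios(norm: NormalizedBenefits, maps: BenefitMaps,
                    config: PipelineConfig) -> list[Scenario]:
    """All weightings x all budgets (budget 1.0 == unconstrained optimum)."""
    out = []
    for w in enumerate_weights(config.weight_step):
        for budget in config.budgets:
            out.append(budget_allocation(norm, w, budget,
                                         seed=config.allocation_seed,
                                         maps=maps, tie_rule=config.tie_rule))
    return out


def scenario_table(scenarios: list[Scenario], maps: BenefitMaps,
                   current: Scenario) -> pd.DataFrame:
    """Tabulate scenarios with normalised performance, grouping, frontier
    and strictly-better flags (flags computed within each budget level)."""
    bounds = compute_bounds(maps)
    cur_norm = normalize_performance(current.performance_raw, bounds)
    rows = []
    by_budget: dict[float, list[int]] = {}
    norm_perfs = []
    for i, sc in enumerate(scenarios):
        norm_perfs.append(normalize_performance(sc.performance_raw, bounds))
        by_budget.setdefault(sc.budget, []).append(i)
    is_pareto = np.zeros(len(scenarios), dtype=bool)
    for budget, idx in by_budget.items():
        pts = np.array([norm_perfs[i] for i in idx])
        keep = pareto_filter(pts)
        # flag every scenario whose triple matches a retained frontier point
        frontier_pts = pts[keep]
        for j, i in enumerate(idx):
            is_pareto[i] = bool((np.isclose(frontier_pts, pts[j]).all(axis=1)).any())
    for i, sc in enumerate(scenarios):
        better = bool((norm_perfs[i] >= cur_norm - 1e-12).all())
        rows.append(scenario_row(sc, norm_perfs[i],
                                 classify_weighting(sc.weighting),
                                 bool(is_pareto[i]), better))
    df = pd.DataFrame(rows, columns=SCENARIO_COLUMNS)
    return df


@_stage("robustness")
def robustness_outputs(scenarios: list[Scenario], out_dir: Path,
                       budget: float = 1.0) -> pd.DataFrame:
    """Frequency maps for the full ensemble and each priority group at one
    budget level; writes one multi-grid set per group plus a CSV summary."""
    ens = [sc for sc in scenarios if sc.budget == budget]
    summary = []
    for group in ("all",) + GROUP_LABELS:
        fm = conversion_frequency(ens, group=group)
        gdir = out_dir / f"frequency_{group}"
        gdir.mkdir(parents=True, exist_ok=True)
        gridio.write_ascii_grid(gdir / "share_changed.asc", fm.share_changed)
        for cat in Category:
            gridio.write_ascii_grid(gdir / f"share_to_{CATEGORY_NAMES[cat]}.asc",
                                    fm.share_to_category[cat])
        m = ens[0].convertible
        summary.append({
            "group": group, "n_scenarios": fm.n_scenarios,
            "mean_share_changed_fraction": float(fm.share_changed[m].mean()),
            **{f"mean_share_to_{CATEGORY_NAMES[c]}_fraction":
               float(fm.share_to_category[c][m].mean()) for c in Category},
        })
    return pd.DataFrame(summary)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline and write all tables/grids under out_dir.

    Returns a dict with the in-memory products (landscape, maps, scenarios,
    tables) for programmatic use.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    landscape: Landscape = _stage("synth")(generate_landscape)(config.synthetic)
    maps: BenefitMaps = _stage("benefits")(compute_benefit_maps)(landscape)
    gridio.write_benefit_maps(out / "benefit_maps", maps)

    norm = normalize_benefits(maps)
    current = current_scenario(norm, maps)
    scenarios = build_scenarios(norm, maps, config)
    df = _stage("pareto")(scenario_table)(scenarios, maps, current)
    df.to_csv(out / "scenarios.csv", index=False)

    bounds = compute_bounds(maps)
    cur_norm = normalize_performance(current.performance_raw, bounds)
    pd.DataFrame([{
        "carbon_tco2e_per_yr": current.performance_raw.carbon,
        "production_gbp_per_yr": current.performance_raw.production,
        "biodiversity_index": current.performance_raw.biodiversity,
        "carbon_norm_0to1": cur_norm[0], "production_norm_0to1": cur_norm[1],
        "biodiversity_norm_0to1": cur_norm[2],
    }]).to_csv(out / "current_performance.csv", index=False)

    frontier = df[df.is_pareto].reset_index(drop=True)
    frontier.to_csv(out / "frontier.csv", index=False)

    freq = robustness_outputs(scenarios, out, budget=config.budgets[-1])
    freq.to_csv(out / "frequency_summary.csv", index=False)

    log.info("pipeline done in %.2f s (%d scenarios)",
             time.perf_counter() - t0, len(scenarios))
    return {"landscape": landscape, "maps": maps, "norm": norm,
            "current": current, "scenarios": scenarios,
            "scenario_table": df, "frontier": frontier,
            "frequency_summary": freq, "bounds": bounds,
            "current_norm": cur_norm}
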