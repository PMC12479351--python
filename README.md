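# tripleland

Where should land-use change happen if a country wants more carbon
sequestration, more food and timber production, and more biodiversity — and
how do these three goals trade off against each other?

`tripleland` is an analysis pipeline for exploring exactly that question on
a gridded landscape. It is aimed at spatial ecologists and land-use
modellers who want a fully testable, self-contained implementation of the
weighted-sum multi-objective allocation approach: every grid cell can keep
its current land use (arable, pasture, plantation forest, semi-natural
habitat) or be converted to any of the other three, each option carrying a
pre-computed benefit for each of the three objectives. Because national
input datasets (land-cover maps, yield surfaces, species-occurrence models,
peat-soil maps) cannot be bundled, a seeded synthetic-landscape generator
reproduces their statistical structure, so the whole pipeline runs and is
verified end to end offline.

## The model

For cell *n* and land-use category *k*, three raw benefits are computed
(t CO₂-eq yr⁻¹, £ yr⁻¹, and a unitless 0–1 indicator), min–max normalised
per objective over all cells × categories to b̄ᴼₙₖ, and combined with
objective weights *w*ᴼ (w_C + w_P + w_B = 1):

    b_{n,k} = b̄ᶜ_{n,k} w_C + b̄ᴾ_{n,k} w_P + b̄ᴮ_{n,k} w_B
    k_n     = argmax_k b_{n,k}

Because the aggregate performance is a sum of independent per-cell terms,
the per-cell argmax is the exact global optimum for each weighting. The
weight simplex is enumerated at a step of 5 percentage points (231
weightings); each optimum is evaluated in raw units, normalised against the
unlimited-conversion aggregate bounds, and the non-dominated (Pareto) set,
pairwise frontiers, strictly-better-than-current set, conversion budgets
(greedy most-beneficial-first, seeded random tie-breaks) and per-cell
conversion-frequency maps are derived from the scenario ensemble.

## Worked example

```python
import tripleland as tl

cfg = tl.SyntheticConfig(n_rows=50, n_cols=50, seed=7, n_species=12)
landscape = tl.generate_landscape(cfg)
maps   = tl.compute_benefit_maps(landscape)     # 4 categories x 3 objectives
norm   = tl.normalize_benefits(maps)
bounds = tl.compute_bounds(maps)

w  = tl.WeightVector(35, 35, 30)                # percent weights, sum 100
sc = tl.optimal_allocation(norm, w, maps)
print(sc.performance_raw, f"{sc.conversion_rate:.1%}")
```

prints (for this seed)

```
PerformanceTriple(carbon=127518.22277871282, production=21295915.751786243,
biodiversity=953.172118234529) 54.3%
```

i.e. this near-balanced weighting converts 54.3% of the 2,500 cells and
yields ~0.13 Mt CO₂-eq yr⁻¹ net sequestration, ~£21.3 M yr⁻¹ of production
and a summed biodiversity indicator of 953 (cf. the bounds from
`tl.compute_bounds(maps)` for what 0 and 1 mean per objective).

The scripted analysis lives under `analysis/` and runs in order:

```bash
cd analysis
python 01_simulate_landscape.py   # calibrated synthetic landscape
python 02_benefit_maps.py         # the 12 benefit maps + aggregate bounds
python 03_optimal_scenarios.py    # 231 weighted-sum optima
python 04_pareto_frontier.py      # non-dominated set, pairwise frontiers
python 05_budget_sweep.py         # conversion budgets 1%-100%
python 06_conversion_robustness.py# per-cell conversion frequencies
```

Each script prints what it found and writes its tables under `results/`
(bulky rasters go to `scratch/`). There is also a CLI (`tripleland
run-all --config cfg.yaml --out outdir`) wrapping the same pipeline.

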