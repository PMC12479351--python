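"""Run the 231 weighted-sum optima (step-5 weight grid, no budget).

For each weighting, every cell takes the category maximising the weighted
normalised benefit; the scenario's aggregate raw performance is normalised
against the unlimited-conversion bounds. Writes the full scenario table to
results/scenarios_unbudgeted.csv and prints the corner scenarios, which must
reach the per-objective aggregate maxima exactly, plus the current state's
normalised position.
"""


import pandas as pd

import tripleland as tl
from tripleland.categories import Objective

from common import RESULTS, WEIGHT_STEP, build, unbudgeted_scenarios

landscape, maps, norm, bounds = build()
scenarios = unbudgeted_scenarios(norm, maps)
current = tl.current_scenario(norm, maps)
cur_norm = tl.normalize_performance(current.performance_raw, bounds)

rows = []
for sc in scenarios:
    p = sc.performance_raw
    n = tl.normalize_performance(p, bounds)
    rows.append([*sc.weighting, p.carbon, p.production, p.biodiversity,
                 *n, sc.conversion_rate,
                 "|".join(sorted(tl.classify_weighting(sc.weighting)))])
df = pd.DataFrame(rows, columns=[
    "w_carbon_pct", "w_production_pct", "w_biodiversity_pct",
    "carbon_tco2e_per_yr", "production_gbp_per_yr", "biodiversity_index",
    "carbon_norm_0to1", "production_norm_0to1", "biodiversity_norm_0to1",
    "conversion_rate_fraction", "groups"])
RESULTS.mkdir(exist_ok=True)
df.to_csv(RESULTS / "scenarios_unbudgeted.csv", index=False)

print(f"{len(df)} scenarios on the step-{WEIGHT_STEP} weight grid")
print("\ncorner scenarios attain the aggregate bound of their objective:")
for obj, w in zip(Objective, [(100, 0, 0), (0, 100, 0), (0, 0, 100)]):
    row = df[(df.w_carbon_pct == w[0]) & (df.w_production_pct == w[1])].iloc[0]
    col = ["carbon_tco2e_per_yr", "production_gbp_per_yr",
           "biodiversity_index"][obj]
    print(f"  w={w}: {col} = {row[col]:,.2f} "
          f"(bound {bounds.max_agg[obj]:,.2f})")
print(f"\ncurrent state normalised (0 = objective minimised everywhere, "
      f"1 = maximised): carbon {cur_norm[0]:.3f}, production "
      f"{cur_norm[1]:.3f}, biodiversity {cur_norm[2]:.3f}")
print(f"conversion rates across scenarios: "
      f"{100 * df.conversion_rate_fraction.min():.1f}% - "
      f"{100 * df.conversion_rate_fraction.max():.1f}%")
print(f"table -> {RESULTS / 'scenarios_unbudgeted.csv'}")
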