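"""Compute the 12 benefit maps (4 target categories x 3 objectives).

Writes the full raster stack to scratch/benefit_maps/ and per-map summary
statistics to results/benefit_summary.csv. Carbon is in t CO2-eq/yr per
25-ha cell (negative = net source, e.g. drained peat under cropland or the
livestock term on pasture), production in GBP/yr per cell, biodiversity a
unitless [0, 1] indicator.
"""

import pandas as pd

import tripleland as tl
from tripleland import gridio
from tripleland.categories import CATEGORY_NAMES, Category, OBJECTIVE_NAMES, Objective

from common import RESULTS, SCRATCH, build

landscape, maps, norm, bounds = build()
gridio.write_benefit_maps(SCRATCH / "benefit_maps", maps)

m = maps.convertible
rows = []
for cat in Category:
    for obj in Objective:
        vals = maps.raw[cat, obj][m]
        rows.append({"target_category": CATEGORY_NAMES[cat],
                     "objective": OBJECTIVE_NAMES[obj],
                     "min": vals.min(), "mean": vals.mean(),
                     "max": vals.max()})
summary = pd.DataFrame(rows)
RESULTS.mkdir(exist_ok=True)
summary.to_csv(RESULTS / "benefit_summary.csv", index=False)

print("per-cell benefit ranges (units: t CO2-eq/yr, GBP/yr, unitless):")
print(summary.to_string(index=False, float_format=lambda v: f"{v:,.2f}"))
print("\naggregate bounds if each objective alone were min/maximised:")
for obj in Objective:
    print(f"  {OBJECTIVE_NAMES[obj]:>13}: min {bounds.min_agg[obj]:,.1f}  "
          f"max {bounds.max_agg[obj]:,.1f}")
print(f"stack -> {SCRATCH / 'benefit_maps'}, summary -> "
      f"{RESULTS / 'benefit_summary.csv'}")
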