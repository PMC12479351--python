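"""Robustness of conversions to the priority weighting.

Overlays all 231 scenarios and, per cell, computes the share converted at
all and the share converted to each category — overall and within the four
priority groups (carbon / production / biodiversity prioritising, each 66
scenarios including the weight-50 boundary, and balanced). Frequency grids
go to scratch/frequency_maps/, the summary to results/robustness_summary.csv.
"""

import pandas as pd

import tripleland as tl
from tripleland import gridio
from tripleland.categories import CATEGORY_NAMES, Category
from tripleland.weights import GROUP_LABELS

from common import RESULTS, SCRATCH, build, unbudgeted_scenarios

landscape, maps, norm, bounds = build()
scenarios = unbudgeted_scenarios(norm, maps)
m = norm.convertible

rows = []
for group in ("all",) + GROUP_LABELS:
    fm = tl.conversion_frequency(scenarios, group=group)
    gdir = SCRATCH / "frequency_maps" / group
    gdir.mkdir(parents=True, exist_ok=True)
    gridio.write_ascii_grid(gdir / "share_changed.asc", fm.share_changed)
    for cat in Category:
        gridio.write_ascii_grid(gdir / f"share_to_{CATEGORY_NAMES[cat]}.asc",
                                fm.share_to_category[cat])
    rows.append({
        "group": group, "n_scenarios": fm.n_scenarios,
        "mean_share_changed_fraction": fm.share_changed[m].mean(),
        **{f"mean_share_to_{CATEGORY_NAMES[c]}_fraction":
           fm.share_to_category[c][m].mean() for c in Category}})

summary = pd.DataFrame(rows)
RESULTS.mkdir(exist_ok=True)
summary.to_csv(RESULTS / "robustness_summary.csv", index=False)

same, never = tl.common_conversions(scenarios)
n = int(m.sum())
print("mean conversion shares by priority group "
      "(fraction of the ensemble converting a cell):")
print(summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"\ncells converted identically in all 231 scenarios: "
      f"{100 * same.sum() / n:.2f}% of convertible land")
print(f"cells never converted in any scenario: "
      f"{100 * never.sum() / n:.2f}%")
print(f"grids -> {SCRATCH / 'frequency_maps'}, summary -> "
      f"{RESULTS / 'robustness_summary.csv'}")
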