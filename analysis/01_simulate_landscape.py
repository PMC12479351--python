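"""Generate the synthetic study landscape and check its calibration.

Writes the landscape rasters to scratch/landscape/ and a calibration summary
to results/landscape_summary.csv. The realised land-cover shares should
match the configured national shares (25.77% arable, 31.59% pasture, 6.49%
plantation, 36.15% semi-natural) to within rounding, and peat should sit
preferentially under semi-natural cover.
"""

import pandas as pd

import tripleland as tl
from tripleland import gridio
from tripleland.categories import CATEGORY_NAMES, Category, SUBHABITAT_NAMES, SubHabitat

from common import RESULTS, SCRATCH, study_config

cfg = study_config()
ls = tl.generate_landscape(cfg)

rows = []
for cat in Category:
    share = float((ls.current_use == cat).mean())
    rows.append({"category": CATEGORY_NAMES[cat],
                 "requested_share_fraction": cfg.class_shares[cat],
                 "realised_share_fraction": share})
summary = pd.DataFrame(rows)

out = SCRATCH / "landscape"
out.mkdir(parents=True, exist_ok=True)
gridio.write_categorical_grid(out / "current_use.asc", ls.current_use,
                              {int(c): CATEGORY_NAMES[c] for c in Category})
gridio.write_categorical_grid(out / "subhabitat.asc", ls.subhabitat,
                              {int(s): SUBHABITAT_NAMES[s] for s in SubHabitat})
for name in ("arable_yield", "pasture_suitability", "pasture_revenue",
             "forest_yield_class"):
    gridio.write_ascii_grid(out / f"{name}.asc", getattr(ls, name))
gridio.write_ascii_grid(out / "peat.asc", ls.peat.astype(float))

RESULTS.mkdir(exist_ok=True)
summary.to_csv(RESULTS / "landscape_summary.csv", index=False)

sn = ls.current_use == Category.SEMINATURAL
print(f"landscape {cfg.n_rows}x{cfg.n_cols}, seed {cfg.seed}: "
      f"{ls.n_convertible} convertible cells of {ls.cell_area:.0f} ha")
print(summary.to_string(index=False))
print(f"peat fraction overall {ls.peat.mean():.3f}, "
      f"under semi-natural {ls.peat[sn].mean():.3f} "
      "(peat co-locates with semi-natural cover)")
print(f"rasters -> {out}, summary -> {RESULTS / 'landscape_summary.csv'}")
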