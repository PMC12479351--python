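"""Frontier analysis: non-dominated scenarios, pairwise frontiers, and the
current state's distance to the frontier.

Writes the three pairwise frontier polylines to results/ and a figure with
the three panels to results/figures/. Reports how many of the 231 scenarios
are non-dominated, the strictly-better set (scenarios at least as good as
the current state in all three objectives), and the axis-parallel
improvements available while guarding the other two objectives.
"""

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

import tripleland as tl
from tripleland.categories import OBJECTIVE_NAMES, Objective

from common import RESULTS, build, unbudgeted_scenarios

landscape, maps, norm, bounds = build()
scenarios = unbudgeted_scenarios(norm, maps)
current = tl.current_scenario(norm, maps)
cur_norm = tl.normalize_performance(current.performance_raw, bounds)
pts = np.array([tl.normalize_performance(s.performance_raw, bounds)
                for s in scenarios])

kept = tl.pareto_filter(pts)
kept_set = {tuple(p) for p in pts[kept]}
n_nondom = sum(tuple(p) in kept_set for p in pts)
better = tl.strictly_better(pts, cur_norm)

print(f"{n_nondom} of {len(pts)} weighted-sum optima are non-dominated")
print(f"{len(better)} scenarios perform at least as well as the current "
      "state in all three objectives")

print("\naxis-parallel improvements over the current state "
      "(other two objectives held at least constant):")
for obj in Objective:
    guards = [int(o) for o in Objective if o != obj]
    res = tl.constrained_improvement(pts, cur_norm, int(obj), guards)
    if res.feasible:
        print(f"  {OBJECTIVE_NAMES[obj]:>13}: {cur_norm[obj]:.3f} -> "
              f"{res.best_value:.3f} (+{res.best_value - cur_norm[obj]:.3f} "
              "normalised points)")
    else:
        print(f"  {OBJECTIVE_NAMES[obj]:>13}: no intersection")

RESULTS.mkdir(exist_ok=True)
(RESULTS / "figures").mkdir(exist_ok=True)
fig, axes = plt.subplots(1, 3, figsize=(13, 4))
pairs = [(0, 1), (0, 2), (1, 2)]
for ax, (i, j) in zip(axes, pairs):
    front = tl.pairwise_frontier(pts, i, j)
    ni, nj = OBJECTIVE_NAMES[Objective(i)], OBJECTIVE_NAMES[Objective(j)]
    pd.DataFrame(front, columns=[f"{ni}_norm_0to1", f"{nj}_norm_0to1"]).to_csv(
        RESULTS / f"frontier_{ni}_{nj}.csv", index=False)
    ax.scatter(pts[:, i], pts[:, j], s=8, c="lightgray", label="scenarios")
    ax.plot(front[:, 0], front[:, 1], "o-", ms=3, c="tab:blue",
            label="pairwise frontier")
    ax.plot(*cur_norm[[i, j]], "r*", ms=12, label="current state")
    ax.set_xlabel(f"{ni} (normalised)")
    ax.set_ylabel(f"{nj} (normalised)")
axes[0].legend(fontsize=8)
fig.tight_layout()
fig.savefig(RESULTS / "figures" / "pairwise_frontiers.png", dpi=150)
print(f"\nfrontier polylines -> {RESULTS}/frontier_*.csv; "
      f"figure -> {RESULTS / 'figures' / 'pairwise_frontiers.png'}")
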