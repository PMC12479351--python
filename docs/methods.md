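# Methods

## Problem and model

The pipeline explores land-use change options on a regular grid of square
cells (nominally 500 m, 25 ha). Each convertible cell currently carries one
of four land-use categories — arable, pasture (improved grassland),
plantation forest (coniferous), or an aggregate semi-natural class
(natural grassland, heath, fen/bog, broadleaved woodland) — and may be kept
or converted to any of the other three. For every (cell, target category)
pair, three raw benefits are pre-computed and held fixed (a static benefit
map, not a dynamic simulation):

* **carbon** (t CO₂-eq yr⁻¹ per cell) — net mean annual greenhouse-gas
  balance over a 30-year accounting horizon;
* **production** (£ yr⁻¹ per cell) — mean annual revenue from crops,
  livestock or timber; semi-natural land produces nothing;
* **biodiversity** (unitless, 0–1 per cell) — geometric mean of a
  normalised summed species-occurrence probability and a land-use-specific
  habitat-condition score.

For a weighting *w* = (w_C, w_P, w_B) on the percent simplex, benefits are
min–max normalised per objective over all cells × categories and combined
per cell: b_{n,k} = Σ_O b̄ᴼ_{n,k} w_O. Because the scenario performance is a
plain sum over cells, the per-cell argmax is the exact global optimum of the
weighted aggregate — no search heuristic is involved. Enumerating the
simplex at step 5 gives 231 weightings whose optima trace out the Pareto
frontier; budget-constrained variants convert only the most beneficial
fraction of cells.

## Carbon accounting

The carbon benefit of assigning category *k* to cell *n* is the sum of:

* an amortised **stock change**: (stock_k − stock_current) × 44/12 / 30 yr,
  with stocks in t C ha⁻¹ (soil + vegetation) looked up per class (and per
  semi-natural sub-habitat). One-off stock changes are converted to annual
  flows by linear amortisation over the 30-year horizon, matching the
  forest averaging window, so all terms share one unit. Keeping the current
  category gives a zero stock term, and the stock component is antisymmetric
  (delta(a→b) = −delta(b→a));
* recurring **state emissions**: fertiliser N₂O on arable
  (1460.67 g N₂O-N ha⁻¹ yr⁻¹ × 44/28 × GWP-100 = 626.63 kg CO₂-eq ha⁻¹ yr⁻¹
  with GWP-100(N₂O) = 273) and livestock CH₄/N₂O on pasture
  (7.62 t CO₂-eq ha⁻¹ yr⁻¹, a uniform national herd mix — the spatial
  variation of stocking density is deliberately not modelled). These attach
  to the *target* state regardless of origin: they are state costs, not
  transition costs;
* a **peat-state flux** on peaty soils, keyed by the target category
  (drained cropland/grassland/forestry are sources, rewetted bog/fen a
  small sink). The flux table is a synthetic stand-in with realistic signs
  and magnitudes; the stock delta is kept alongside it, representing carbon
  accumulation of the restored soil profile;
* mean annual **forest sequestration** for plantation and broadleaved
  targets from the growth model below; plantation sequestration is
  multiplied by the long-term wood-product storage share (default 0.482),
  broadleaved is not.

Only peat and forest states carry recurring carbon terms for semi-natural
land; established non-forest habitats are treated as being at equilibrium.

## Forest growth model

Stand growth is summarised by a yield class YC (maximum mean annual volume
increment, m³ ha⁻¹ yr⁻¹) and a logistic cumulative-sequestration curve
anchored so that the mean annual increment at the felling age equals the
yield class; volume converts to CO₂ at 0.733 t CO₂ m⁻³ (density 0.4 t m⁻³,
carbon fraction 0.5). Felling occurs at the age of maximum mean annual
increment, approximated as clip(100 − 2.4·YC, 40, 85) years — faster-growing
stands are felled younger. Managed plantations are thinned (30% of the
cumulative increment removed along the way, counted as sequestered because
its fate is handled by the wood-product share) and replanted after felling;
broadleaved stands are unmanaged. Three stand states feed the benefit maps:
existing plantations (mean age 25), existing broadleaved woodland (mean age
60), and new plantings assumed to be established uniformly over the horizon
(cohort-averaged numerically). Timber revenue converts harvested CO₂ back
to biomass (÷ 44/12 ÷ 0.5 t C/t) at a flat timber price; new plantations
earn mostly thinning revenue because their felling age usually exceeds the
horizon — the "considerably lower returns of freshly planted woodland". The
curve and its parameters are a configurable stand-in for published
yield-class lookup tables.

## Production and biodiversity

Arable revenue is the landscape's aggregated crop-revenue surface (£ ha⁻¹
yr⁻¹), passed through outlier smoothing: cells outside the Tukey fence
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] are replaced by the mean of their finite,
non-outlier 8-neighbours (boundary cells use the neighbours they have; a
constant surface has no cell outside the degenerate fence and is returned
unchanged). Pasture revenue is zeroed where the 0–100 suitability index is
below 20 ("under 20" read strictly: 19 → no returns, 20 → returns).
Semi-natural land yields zero production by assumption.

The biodiversity indicator per (cell, category) is √(S̄ × condition), where
S is the summed occurrence probability of all species under that category,
S̄ its global min–max normalisation over cells × categories, and condition a
0–1 effective-habitat-area score: arable 0.08, pasture 0.10, plantation
0.23; newly created semi-natural 0.33; established semi-natural higher
(grassland 0.30, heath 0.45, fen/bog 0.55, broadleaved 0.70 — the published
anchors are 0.30, 0.33 and the 0.38–0.7 range; the per-sub-habitat values
inside that range are table-driven defaults). "Existing" condition applies
only when the target equals the current use and sub-type.

Cells converted to semi-natural receive the sub-habitat of their nearest
existing semi-natural cell (Euclidean distance between cell centres, via a
distance transform), except that peaty cells always become bog/fen — peat
restoration overrides the nearest neighbour — and peat cells are excluded as
donors so bog/fen does not propagate off the peat mask.

## Allocation details

* Normalisation of benefits is **global** per objective (min–max over all
  cells × 4 categories), not per cell: per-cell normalisation would erase
  the spatial signal the frontier analysis depends on. A constant layer
  normalises to zeros with a warning.
* Argmax ties prefer the incumbent category, then the fixed order arable <
  pasture < plantation < semi-natural — no phantom conversions at zero gain.
  Ties are measure-zero on the continuous synthetic surfaces.
* The budget ranks cells by the **improvement delta** over keeping the
  current use (cells whose best use is their current use are never
  converted); the cell count is floor(budget × n_convertible), so the
  budget is never exceeded, and the realised conversion rate falls below
  the budget once positive-delta cells run out. Delta ties are broken by a
  seeded uniform shuffle; the same seed reproduces the same pick.
* Weights are stored as exact integer percents; each objective group
  (weight ≥ 50) and the balanced group (all ≤ 50) then have exactly 66 of
  the 231 step-5 members, with boundary weightings in several groups
  (50-50-0 sits in both objective groups and balanced, the literal reading
  of the grouping rules).
* Frontier analysis uses weak dominance (≥ everywhere, > somewhere) on the
  discrete scenario set; duplicates are deduplicated before filtering.
  Pairwise frontiers are the componentwise non-dominated subsets of 2-D
  projections — monotone staircases; piecewise-linear interpolation is for
  plotting only. Scenario performances are normalised against the
  unlimited-conversion aggregate bounds (sum of per-cell minima/maxima),
  which the corner-weight scenarios reproduce exactly.

## Synthetic landscape generator

The generator emulates the statistical structure of the national inputs,
not their geography. Spatial autocorrelation comes from Gaussian smoothing
of white noise (kernel width = correlation length, default 5 cells, a free
parameter — no input's spatial covariance is published). Land-cover classes
are assigned by thresholding the smoothed field at its empirical quantiles,
matching the configured shares (defaults 25.77% arable, 31.59% pasture,
6.49% plantation, 36.15% semi-natural — the convertible-land distribution
of the study system) up to integer rounding. The peat mask (default 12% of
cells, the approximate national peatland share) comes from a second
smoothed field biased toward the semi-natural band, mimicking peat under
bog and fen. Yield, suitability and revenue surfaces are smooth log-normal
or clipped-Gaussian fields with realistic central values; occurrence
surfaces are per-species logistic-squashed smooth fields multiplied by
per-species category affinities that favour semi-natural habitat (default
86 species, matching the priority-species panel size; analyses here use 12
for speed). All randomness derives from one seed through independent
seed-sequence streams; regeneration is bitwise identical.

What the generator does **not** emulate: real geography and climate
gradients, correlations between yield and land cover, zero-revenue
marginal land (every synthetic cell has positive arable revenue, so —
unlike in the real study system — essentially no cell is converted
identically under *all* 231 weightings), species range structure, and
spatially varying stocking density. Passing tests therefore demonstrate the
correctness of the machinery (benefit assembly, optimality, frontier and
robustness logic), not any empirical claim about a real landscape.

## Problem sizes and numerical choices

The scripted analysis and the acceptance run use a 50 × 50 grid (2,500
cells) with 12 species; tests use 20 × 20 fixtures and 200 × 200 grids for
share calibration. Exhaustive-search oracles check optimality on ≤ 8-cell
grids (4⁸ allocations). Degenerate inputs are defined behaviour: a constant
benefit layer warns and normalises to zeros; equal aggregate bounds raise;
an empty guarded frontier search returns a "no intersection" result rather
than raising; a landscape with no semi-natural donor and no peat cannot
assign future habitats and raises.

## Known limitations

Benefits are static per cell (no succession dynamics, no interactions
between neighbouring cells — the objective is cell-separable by design);
conversion costs, urban expansion and dietary scenarios are out of scope;
the stock, peat-flux, condition-range and forest-curve tables are
configurable synthetic stand-ins for published lookup tables, so absolute
magnitudes are indicative only.
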