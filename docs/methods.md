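# Methods

`hanppcube` builds an annual, gridded land-use data cube under a
closed-budget constraint and quantifies land-use intensity per class with
the Human Appropriation of Net Primary Production (HANPP) framework.
This note documents the model, its assumptions, the tunable parameters,
what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Accounting framework

Four NPP quantities are tracked per land-use class and grid cell, all in
tC/yr (areas in km², NPP densities in gC/m²/yr; 1 gC/m²/yr over 1 km²
equals exactly 1 tC/yr):

* `NPP_pot` — productivity of the potential vegetation without land use,
  under current climate; the framework's reference point.
* `NPP_act` — productivity of the actually prevailing vegetation.
* `HANPP_harv` — biomass extracted or killed during harvest, including
  by-products and losses.
* `NPP_eco` — NPP remaining in the ecosystem after harvest.

They are tied by the identities `NPP_act = NPP_eco + HANPP_harv`,
`NPP_pot = NPP_act + HANPP_luc` and
`HANPP = HANPP_harv + HANPP_luc = NPP_pot − NPP_eco`.
`HANPP_luc` (the land-conversion flow) is sign-free: input-intensive
cropland can push actual NPP above potential. Aggregation always sums
flow components and recomputes ratios; a HANPP percentage is never
averaged. The assembly step (`accounts.assemble_accounts`) re-checks the
identities and fails hard on a violation beyond 1e−6 relative.

## Grid geometry

All layers share one regular latitude/longitude grid (row 0
northernmost, 0-based, row-major, half-open cell intervals). Cell areas
use a sphere of authalic radius 6371.0072 km: a cell's area is the
spherical band between its bounding parallels divided by the number of
cells in a full circle, so a full-planet grid sums to `4πR²` exactly
(relative error < 1e−9 in the tests) and a 30-arcsecond cell at the
equator comes out near 1 km². An ellipsoid would change cell areas by
well under the tolerances used anywhere downstream, and the sphere keeps
the areas closed-form. Grid resolution is configurable; the shipped
study conditions use 60×60 cells of 0.5° as a stand-in for the
30-arcsecond production resolution.

## Land-use allocation (closed budget)

Each year is allocated from scratch (stateless across years) in a fixed
priority order; earlier classes are never displaced by later ones:

1. **Built-up seed** — the urban-cover share of each cell.
2. **National cropland** — census totals distributed over three
   cover-derived suitability classes, most suitable first. If the target
   fits in class 1, class-1 cells are used proportionally to their
   available area; otherwise class 1 fills completely and the remainder
   spills into class 2 (then 3) by nondecreasing Euclidean distance (in
   cell units) to the nearest class-1-bearing cell. Cells at equal
   distance form a shell filled proportionally to stack area — this
   avoids scan-order artifacts and makes the rule oracle-checkable. A
   target beyond total capacity is reduced and logged.
3. **Built-up transfer** — 5% of each cell's cropland moves to built-up
   to represent dispersed settlement below the cover product's
   resolution. The transfer happens *after* census matching and reduces
   the cropland layer, so reported cropland deviates from the census by
   exactly the transfer; crop production is distributed over the reduced
   layer. (The source procedure does not state the ordering; this is the
   simplest reading.)
4. **Crop split** — cropland is differentiated into 22 crop classes plus
   fodder and fallow. The national fallow minimum is census cropland
   minus total harvested area (floored at zero). Each cell's harvesting
   share is the national harvested/cropland ratio; it is split across
   crops along the physical-area shares of coarse crop-pattern layers
   (epoch snapshots interpolated linearly in time, held constant outside
   the observed span, nearest-neighbour upsampled, gap-filled from
   donors within a 30-cell radius, dropped outside the cropland mask),
   then scaled per country-crop so national totals hit the census
   exactly. Census-only crops spread proportionally over all national
   cropland cells. Physical area = harvested / multicropping (per-cell
   where observed, country-median fill, global-median fallback, floored
   at 1). The residual cell area is split half into fodder production
   and half into true fallow. The per-cell identity
   Σ physical + fallow + fodder = cropland holds exactly; inconsistent
   inputs are rescaled per cell and logged.
5. **Wilderness** — cells with potential productivity below
   20 gC/m²/yr become unproductive wilderness outright. Elsewhere,
   inside the forest zone a cell is core wilderness when the human
   footprint is zero *and* an intact forest landscape is present, and
   periphery when exactly one criterion holds; outside the forest zone
   footprint zero alone makes core. The 1993 footprint layer (a
   different product than the annual series from 2000) is bridged: a
   cell counts as footprint-zero in 1993 only if the 1993/2000 mean is
   below 1 and the 2000 value is zero. Because built-up and cropland
   have already claimed their areas, the wilderness classes take each
   flagged cell's *remaining* land, which also covers the
   fractional-core case.
6. **National grazing** — permanent meadow/pasture totals distributed
   like cropland over three grazing suitability classes, net of the
   cropland already drawn from the shared source classes and capped by
   the still-unassigned land. A shortfall is met by reclassifying
   peripheral wilderness (proportionally across the country's periphery
   cells) and logged; reclassified periphery is booked to the
   open-wooded grazing class, since it is not class-1 grassland.
7. **Forestry** — closed-forest cover (coniferous / non-coniferous)
   takes its stack up to the remaining land.
8. **Open wooded land** — 15–40% tree-cover stacks join the open-wooded
   grazing class.
9. **Residual** — any land still unassigned becomes other grazing land
   (open-wooded class) beyond the census total.

After every year the budget check asserts Σ class areas = land area per
cell to 1e−6 km² (float64 accumulation safety); the pipeline fails hard
otherwise. For wood allocation the open-wooded class keeps an internal
coniferous/non-coniferous split: area from the coniferous stack is
"con"; everything else (non-coniferous stack, grazing spill, periphery,
residual) is "ncon".

## Potential-NPP surface

Coarse model output is brought to the working grid by mass-preserving
dasymetric downscaling: fine-cell values are proportional to an
empirical climate pattern — the minimum of a temperature-limited curve
`3000/(1+e^(1.315−0.119T))` and a precipitation-limited curve
`3000(1−e^(−0.000664P))`, in g dry matter/m²/yr, converted to carbon at
0.5 gC/gDM — rescaled within each ecoregion so the ecoregion NPP total
matches the coarse input exactly (uniform fallback where the pattern is
all zero). Negative inputs are clamped to zero, then a centred 5-year
moving average (shrinking windows at the series edges) damps annual
fluctuations. The climate-curve coefficients and the carbon conversion
are configuration: the source procedure defers them to its references,
so the package ships the standard literature values as defaults.

## Flow rules per land-use type

* **Cropland** — national harvest carbon per crop is production ×
  carbon content × an expansion factor (≥ 1) for by-products and
  harvest losses; factors live in an editable CSV
  (`data/crop_factors.csv`) with defaults in the literature's typical
  range, and every computation accepts an override table. Within a
  country the harvest follows the production pattern (harvested area ×
  yield); cropland cells the pattern does not cover get 80% of the
  country's 5th-percentile yield (a reduced yield even when one yield
  level covers the country); countries absent from the pattern use the
  global median yield; an optional moving-average pass blurs coarse
  pattern edges; a final rescaling restores national totals exactly
  (relative 1e−9 in tests). `NPP_act = HANPP_harv/(1 − pre-harvest
  share)`; `HANPP_luc` is the difference to potential NPP on the crop's
  physical area and may be negative.
* **Fodder** — production is not census-reported; the synthetic tables
  carry an explicit fodder production row and its harvest is distributed
  proportionally to the fodder area layer, using the fodder factor row.
* **Fallow** — no harvest; actual NPP is taken at potential, so the
  conversion flow is zero and all potential NPP stays in the ecosystem.
* **Built-up** — fixed fractions of potential NPP: 1/6 harvested, 2/3
  conversion loss, 1/6 remaining (urban green space). HANPP/NPP_pot is
  5/6 everywhere on built-up land.
* **Forestry and wood fuel** — reported industrial-roundwood (IR) and
  wood-fuel (WF) volumes (under bark) expand to whole-plant carbon via
  volume × wood density × carbon fraction × expansion (bark, branches,
  foliage, roots, felling losses; defaults 0.45/0.55 t/m³, 0.5, 2.0).
  On woodland pools NPP_act equals NPP_pot (closed forest) or the
  degradation-reduced potential (open wooded land), conversion flow
  zero on closed forest, and wood harvest is capped at 70% of NPP_act,
  so at least 30% of NPP always remains. Within a country demand is
  spread proportionally to NPP_act; because the cap is also proportional
  to NPP_act, a pool's cap binds for all its cells at once, which makes
  the proportional-with-cap rule exact rather than iterative. Demand
  cascades through a fixed waterfall (own closed forest → other type's
  closed forest, displacing wood fuel there → own open wooded land; wood
  fuel overflowing an open-wooded pool returns to closed forests, then
  the other type's open wooded land); any residual is reduced and
  logged, never raised as an exception. IR is placed before WF whenever
  both compete for the same capacity, as IR anchors the procedure.
* **Grazing** — national grazed-biomass demand is a residual "grazing
  gap": roughage feed demand (per-head daily intake from milk-yield and
  carcass-weight regressions, cattle using the minimum of the two
  estimates; fixed intakes for small ruminants) minus market feed
  (reported feed plus an oilcake supply estimated as production +
  imports − exports, importer-reported trade preferred, floored at
  zero, fully attributed to feed) minus crop residues — with floors
  guaranteeing ≥ 30% of demand from roughage and ≥ 15% from grazing
  alone. The gap is distributed along a grazing-intensity gradient over
  cell "grazing potentials" (grazable NPP — the palatable share of
  actual NPP — times a second-order polynomial response to population
  density, floored at zero): baseline intensity 0.40 for the
  lowest-potential 10% of cells, 0.80 (seasonal maximum) for the top
  15%, linear in rank between (rank percentile `rank/(n−1)`, ties by
  cell index). If baseline capacity covers the gap, one ≤ 1 scale
  factor applies to all cells; otherwise the gradient flattens stepwise
  (+1 point on the minimum intensity, +2 points on the top share per
  step — the step schedule is configuration) up to 0.75/85%.
  Fertilising countries (> 5% of fertiliser on grassland) may instead
  boost grazable NPP on the treeless class: flattening stops at the
  first step where a ≤ 2 boost closes the gap; if even full flattening
  needs more, the extreme fallback allows up to 3. Unfertilised
  countries are never boosted — their unmet demand is reduced and
  logged. Applied boosts raise NPP_act on the treeless class, so the
  conversion flow records the fertilisation gain as negative there.
* **Wilderness** — no flows; NPP_eco = NPP_pot.

## Synthetic worlds

The generator (`synthetic.make_world`) emulates every input stream with
known ground truth so each stage is testable without downloads. All
randomness flows from one seeded generator; the same seed reproduces the
world bit-identically. Default study conditions: 60×60 cells of 0.5°,
3 contiguous countries (nearest-seed partition of the land mass),
29 annual steps (1992–2020), 6 active crop classes, a 12-class cover
mixture built from smoothed Gaussian noise (spatially correlated patches
for the proximity rule), crop-pattern layers at a 5× coarser grid
(mirroring the production datasets' resolution gap), footprint layers
for 1993 and 2000–2018 with the 1993 layer derived from 2000 plus noise
so the bridging rule has work to do, intact-forest epochs
2000/2013/2016/2020, a 6×-coarser potential-NPP field with fine
temperature/precipitation covariates, population density and a
degradation factor map.

National tables are derived from the generated fields' own capacities:
cropland targets are 45–75% of each country's class-1 suitability,
grazing targets 35–65% of the net class-1 capacity, wood volumes 10–30%
of the closed-forest cap, livestock demand 30–60% of a rough grazable
capacity — so with the inconsistency switches off every census target is
attainable and the pipeline must recover the generator's intended
allocation exactly (national totals) and per cell (crop splits to
relative 1e−6 in the acceptance suite). Switches create a cropland
target beyond total suitability, wood demand beyond the 70% cap, or
grazing demand beyond full-flattening capacity, to exercise the logged
reduction paths; a fourth switch marks a fertilising country.

What the generator does *not* emulate: realistic geography or climate
(beyond what the climate-NPP curves need), census item-code systems,
sub-national statistics, inter-annual land-cover persistence (cover
drifts linearly between two correlated endmember states; water shares
are constant so the land mask is fixed), and trade reporting gaps.
Passing tests therefore demonstrate the correctness of the allocation
and accounting machinery under controlled conditions, not the realism
of any real-world data product.

## Numerical choices and degenerate inputs

* Budget tolerance 1e−6 km²; identity tolerance 1e−6 relative.
* Proximity ordering: exact Euclidean distance via a distance
  transform; equal-distance shells filled proportionally.
* Ranking ties in the grazing gradient broken by flat cell index; a
  single-cell country sits at rank 0 (minimum intensity).
* Division guards: zero-capacity stacks allocate nothing and report the
  full target as shortfall; a zero-pattern country falls back to a
  uniform spread over its cropland (logged); HANPP% is flagged NaN
  where NPP_pot is zero, never thrown.
* Epoch interpolation is linear with constant extrapolation on both
  ends; the 5-year NPP smoother shrinks its window at series edges.
* Rasters are written as plain single-band TIFF (north-up, row-major);
  the shared grid spec carries the geometry, and a missing-data sentinel
  distinct from true zero can be stored in the description tag.

## Known limitations

* The suitability table transcription has ambiguous column alignments
  for a few cover classes (grassland, sparse, shrubland, flooded tree
  cover); the shipped CSV flags them and is pure configuration, so a
  corrected transcription needs no code change.
* Factor values (crop expansion, wood density chains, feed regressions,
  palatable share, population-density polynomial) are defaults in the
  plausible literature range, not fitted values; all are configuration.
* On the open-wooded grazing class, grazing and wood-fuel harvest are
  capped independently (0.8 × grazable vs 0.7 × NPP_act); under
  simultaneous extreme overshoot their sum could exceed NPP_act and
  drive NPP_eco negative. This does not occur under the default study
  conditions and is asserted against in the shipped scenarios.
* Year-on-year class changes come solely from the drifting cover fields
  and census series; no change-detection smoothing or cell-level
  persistence constraint is imposed.
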