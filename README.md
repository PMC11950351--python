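# hanppcube

Closed-budget gridded land-use allocation with HANPP intensity
accounting.

Land-system science needs data that say not only *where* land is used
but *how intensively*. The Human Appropriation of Net Primary
Production (HANPP) framework measures intensity as the share of
potential plant productivity that land use diverts: through biomass
harvest (HANPP_harv) and through productivity changes caused by land
conversion (HANPP_luc). `hanppcube` implements the full construction
pipeline for an annual land-use data cube in this framework — for
researchers who want to study, extend or stress-test the method itself:
every stage runs at desk scale on synthetic worlds with known ground
truth, no multi-gigabyte downloads required.

## What it computes

**Areas.** Each grid cell's land area is assigned completely ("closed
budget") across 32 land-use classes — 22 crop classes plus fodder and
fallow, built-up land, two grazing classes (treeless / open wooded),
coniferous and non-coniferous forestry, and three wilderness classes —
by integrating fractional land cover with national census totals:
suitability-ranked sequential allocation with proximity-based spillover,
a 5% built-up transfer for dispersed settlement, crop splits matched
exactly to census harvested areas, footprint/intact-forest wilderness
rules, and periphery reclassification when grazing targets cannot be
met. Σ class areas = land area per cell, always, to 1e−6 km².

**Flows.** Per class and cell (tC/yr), tied by the identities

```
NPP_act = NPP_eco + HANPP_harv
NPP_pot = NPP_act + HANPP_luc
HANPP   = HANPP_harv + HANPP_luc = NPP_pot − NPP_eco
```

with a mass-preserving climate-pattern downscaling of coarse potential
NPP, fixed built-up fractions (1/6 harvest, 2/3 conversion), a wood
harvest waterfall capped at 70% of NPP_act, and a national feed-balance
"grazing gap" distributed along a population-weighted grazing-intensity
gradient. Details and all parameter defaults: [docs/methods.md](docs/methods.md).

## Worked example

```python
import hanppcube as h
from hanppcube.accounts import assemble_accounts, regional_table

world = h.make_world(h.WorldConfig(seed=1))   # 60×60 grid, 3 countries, 1992–2020
cube = h.build_cube(world)                    # all 32 classes, areas + flows
acc = assemble_accounts(cube.layers[2020], world.partition)
print(regional_table(acc, world.partition.region_map).head(5).to_string(index=False))
```

```
                             region  lu_type  area_Mkm2  npp_pot  hanpp_harv  hanpp_luc  hanpp  hanpp_pct
Central Asia and Russian Federation Cropland       0.11    22.49       19.86      -1.23  18.64         83
Central Asia and Russian Federation  Grazing       0.18    46.24        2.42       7.04   9.46         20
Central Asia and Russian Federation Forestry       0.07    19.27        8.38       0.00   8.38         44
Central Asia and Russian Federation Built-up       0.01     2.77        0.46       1.84   2.31         83
Central Asia and Russian Federation    Total       1.03   206.56       31.13       7.66  38.79         19
```

Flows are in MtC/yr, areas in Mkm². Reading the rows: this synthetic
region's cropland appropriates 83% of its potential NPP — mostly as
harvest, with a small *negative* conversion flow (input-boosted cropland
producing above potential); forestry's conversion flow is zero by
definition, so its HANPP is pure wood harvest; the wilderness share
pushes the region's total down to 19%. The `Total` row includes
wilderness, which carries no flows. Every reconciliation event —
census shortfalls, harvest reductions, periphery reclassification — is
in `cube.log.to_frame()`; on a default world that log shows every
census target met exactly.

A thin CLI wraps the same calls: `hanppcube synth` (write a synthetic
input bundle), `hanppcube build` (write all cube layers as TIFFs, named
`{year}{layer}_{class}.tif` in per-class folders), `hanppcube report`
(regional accounts CSV).

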