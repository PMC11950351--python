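"""Synthetic-world generator: complete, internally consistent input bundles.

Every data stream the pipeline consumes in a real run — fractional
land-cover, national census tables, coarse crop-pattern layers, human
footprint and intact-forest masks, coarse potential-NPP with fine climate
covariates, population density, livestock/feed/trade/wood statistics — is
emulated here on a small grid with known ground truth, so each stage of
the pipeline can be tested without any download.  All randomness flows
from one seeded generator: the same seed yields a bit-identical world.

Cover fields are spatially correlated (smoothed Gaussian noise turned
into class fractions), producing the contiguous patches the proximity
rule needs.  Crop-pattern layers are generated at a configurable factor
coarser than the working grid to exercise resampling and gap-filling,
mirroring the resolution mismatch of real crop-allocation products.

By default the national tables are consistent with the suitability
capacities implied by the cover fields, so census targets are always
attainable; dedicated inconsistency switches create a cropland target
exceeding suitable area, wood demand exceeding the harvest cap, or
grazing demand exceeding gradient capacity, to exercise the logged
reduction paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import CellAreaField, CountryPartition, GridSpec, land_area
from .npp import MiamiParams, downscale, miami_npp, smooth_series
from .suitability import cover_to_suitability, load_default_table
from .timeseries import footprint_for_year, make_epoch_series

__all__ = [
    "InconsistencySwitches",
    "WorldConfig",
    "NationalAccounts",
    "GroundTruth",
    "SyntheticWorld",
    "make_epoch_series",
    "make_world",
]

#: Cover classes used in the default mixture (codes of the packaged table).
DEFAULT_COVER_CLASSES = (210, 190, 10, 30, 130, 120, 50, 71, 72, 150, 200, 140)

#: Crop classes carried by the default synthetic worlds.
DEFAULT_CROPS = ("CL-WHEA", "CL-MAIZ", "CL-RICE", "CL-SOYB", "CL-VEFR", "CL-REST")

REGION_NAMES = (
    "Northern America", "Latin America & the Caribbean",
    "Central Asia and Russian Federation", "Europe", "Africa", "Asia",
)


@dataclass(frozen=True)
class InconsistencySwitches:
    cropland_overshoot: bool = False
    wood_overshoot: bool = False
    grazing_overshoot: bool = False
    fertilized_country: bool = False


@dataclass(frozen=True)
class WorldConfig:
    seed: int = 0
    grid: GridSpec = GridSpec(n_rows=60, n_cols=60, cell_size=0.5, origin_lat=60.0, origin_lon=0.0)
    n_countries: int = 3
    years: tuple[int, int] = (1992, 2020)
    crops: tuple[str, ...] = DEFAULT_CROPS
    cover_classes: tuple[int, ...] = DEFAULT_COVER_CLASSES
    cover_smooth_sigma: float = 5.0
    spam_factor: int = 5
    npp_factor: int = 6
    n_ecoregions: int = 5
    switches: InconsistencySwitches = InconsistencySwitches()
    all_ocean: bool = False

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


@dataclass
class NationalAccounts:
    """FAO-like national statistics tables (all years)."""

    land: pd.DataFrame        # country, year, cropland_km2, grazing_km2
    crops: pd.DataFrame       # country, year, crop, area_harvested_km2, production_t
    wood: pd.DataFrame        # country, year, product (IR/WF), tree_type, volume_m3
    livestock: pd.DataFrame   # country, year, species, heads, milk_yield_t, carcass_kg
    feed: pd.DataFrame        # country, year, market_feed_tC, residues_tC, oil_production_t
    trade: pd.DataFrame       # year, importer, exporter, reported_by, oilcake_t
    fertilized: dict[int, bool] = field(default_factory=dict)


@dataclass
class GroundTruth:
    """The generator's intended per-cell allocation, for recovery tests."""

    cropland_pre: dict[int, np.ndarray] = field(default_factory=dict)
    cropland_post: dict[int, np.ndarray] = field(default_factory=dict)
    builtup: dict[int, np.ndarray] = field(default_factory=dict)
    crop_harvested: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)
    crop_physical: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)
    grazing_capacity_suit1: dict[int, dict[int, float]] = field(default_factory=dict)


@dataclass
class SyntheticWorld:
    config: WorldConfig
    grid: GridSpec
    area: CellAreaField
    partition: CountryPartition
    cover: dict[int, dict[int, np.ndarray]]           # year -> class code -> fraction
    spam_physical: dict[str, dict[int, np.ndarray]]   # crop -> epoch -> coarse layer
    spam_multicropping: dict[str, dict[int, np.ndarray]]
    spam_yield: dict[str, dict[int, np.ndarray]]      # t fresh / km2 harvested
    footprint: dict[int, np.ndarray]                  # year (1993, 2000..2018) -> 0..50
    ifl: dict[int, np.ndarray]                        # epoch -> presence mask (0/1 float)
    forest_zone: np.ndarray
    coarse_npp: dict[int, np.ndarray]                 # year -> coarse NPP_pot (gC/m2/yr)
    ecoregions_fine: np.ndarray
    temperature: np.ndarray
    precipitation: np.ndarray
    population: np.ndarray                            # persons / km2
    degradation: np.ndarray                           # multiplicative NPP_act factor on grazing
    accounts: NationalAccounts
    ground_truth: GroundTruth

    def npp_pot_fine(self, params: MiamiParams = MiamiParams()) -> dict[int, np.ndarray]:
        """Fine-grid potential NPP per year: dasymetric downscaling of the
        coarse field along the climate pattern, then 5-year smoothing."""
        factor = self.config.npp_factor
        pattern = miami_npp(self.temperature, self.precipitation, params)
        coarse_area = self.area.area_total.reshape(
            self.grid.n_rows // factor, factor, self.grid.n_cols // factor, factor
        ).sum(axis=(1, 3))
        years = sorted(self.coarse_npp)
        fine = np.stack([
            downscale(self.coarse_npp[y], pattern, self.ecoregions_fine,
                      coarse_area, self.area.area_total, factor)
            for y in years
        ])
        fine = smooth_series(fine)
        return {y: fine[i] for i, y in enumerate(years)}


def _smooth(rng: np.random.Generator, shape, sigma) -> np.ndarray:
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")


def _make_cover(cfg: WorldConfig, rng: np.random.Generator) -> tuple[dict, np.ndarray]:
    """Per-year cover fractions.  The water share is fixed across years
    (land area is constant); land-class shares drift linearly between two
    correlated endmember states."""
    shape = cfg.grid.shape
    classes = list(cfg.cover_classes)
    land_classes = [c for c in classes if c != 210]

    # water: ocean in the grid corners/edges via a smoothed threshold field
    wfield = _smooth(rng, shape, cfg.cover_smooth_sigma * 1.5)
    if cfg.all_ocean:
        water = np.ones(shape)
    else:
        water = np.clip(1.0 / (1.0 + np.exp(-4.0 * (wfield - np.quantile(wfield, 0.75)))), 0.0, 1.0)
        water[water < 0.05] = 0.0
        water[water > 0.95] = 1.0

    bias = {190: -2.5, 10: 0.6, 30: -0.4, 130: 0.5, 120: 0.0, 50: 0.3,
            71: 0.2, 72: -0.3, 150: -0.2, 200: -0.8, 140: -1.5}
    logits_a = {c: _smooth(rng, shape, cfg.cover_smooth_sigma) * 1.6 + bias.get(c, 0.0)
                for c in land_classes}
    logits_b = {c: logits_a[c] + 0.35 * _smooth(rng, shape, cfg.cover_smooth_sigma)
                for c in land_classes}

    y0, y1 = cfg.years
    span = max(y1 - y0, 1)
    cover: dict[int, dict[int, np.ndarray]] = {}
    for y in cfg.year_list:
        w = (y - y0) / span
        expo = {c: np.exp((1 - w) * logits_a[c] + w * logits_b[c]) for c in land_classes}
        denom = sum(expo.values())
        fracs = {c: (1.0 - water) * expo[c] / denom for c in land_classes}
        fracs[210] = water
        cover[y] = fracs
    return cover, water


def _make_partition(cfg: WorldConfig, area: CellAreaField, rng: np.random.Generator) -> CountryPartition:
    shape = cfg.grid.shape
    cid = np.zeros(shape, dtype=int)
    land = area.area_land > 0
    if land.any() and cfg.n_countries > 0:
        rows, cols = np.nonzero(land)
        idx = rng.choice(len(rows), size=min(cfg.n_countries, len(rows)), replace=False)
        seeds = np.stack([rows[idx], cols[idx]], axis=1)
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        d = np.stack([(rr - s[0]) ** 2 + (cc - s[1]) ** 2 for s in seeds])
        cid = d.argmin(axis=0) + 1
        cid[~land] = 0
    regions = {i + 1: REGION_NAMES[i % len(REGION_NAMES)] for i in range(cfg.n_countries)}
    return CountryPartition(country_id=cid, region_map=regions)


def make_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a complete synthetic input bundle with known ground truth."""
    cfg = config
    if cfg.grid.n_rows % cfg.spam_factor or cfg.grid.n_cols % cfg.spam_factor:
        raise ValueError("spam_factor must divide the grid shape")
    if cfg.grid.n_rows % cfg.npp_factor or cfg.grid.n_cols % cfg.npp_factor:
        raise ValueError("npp_factor must divide the grid shape")
    rng = np.random.default_rng(cfg.seed)
    shape = cfg.grid.shape
    years = cfg.year_list

    cover, water = _make_cover(cfg, rng)
    area = land_area(water, cfg.grid)
    if not cfg.all_ocean and not np.any(area.area_land > 0):
        raise ValueError("configuration produced a world without land")
    partition = _make_partition(cfg, area, rng)

    # --- climate, ecoregions, coarse potential NPP -------------------------
    lat = np.linspace(cfg.grid.origin_lat, cfg.grid.origin_lat - cfg.grid.n_rows * cfg.grid.cell_size,
                      cfg.grid.n_rows)[:, None] * np.ones(shape)
    temperature = 28.0 - 0.55 * np.abs(lat) + 2.0 * _smooth(rng, shape, 4.0)
    precipitation = np.clip(1200.0 + 700.0 * _smooth(rng, shape, 5.0), 0.0, None)

    f = cfg.npp_factor
    coarse_shape = (shape[0] // f, shape[1] // f)
    eco_seeds = rng.integers(0, coarse_shape[0], size=(cfg.n_ecoregions, 2))
    rr, cc = np.meshgrid(np.arange(coarse_shape[0]), np.arange(coarse_shape[1]), indexing="ij")
    d = np.stack([(rr - s[0]) ** 2 + (cc - s[1]) ** 2 for s in eco_seeds])
    eco_coarse = d.argmin(axis=0) + 1
    ecoregions_fine = np.repeat(np.repeat(eco_coarse, f, axis=0), f, axis=1)

    # coarse NPP: climate-consistent base with regional scaling and a slow
    # trend; the northernmost band is pushed below the non-productive
    # threshold so unproductive wilderness exists
    t_c = temperature.reshape(coarse_shape[0], f, coarse_shape[1], f).mean(axis=(1, 3))
    p_c = precipitation.reshape(coarse_shape[0], f, coarse_shape[1], f).mean(axis=(1, 3))
    base = np.asarray(miami_npp(t_c, p_c)) * rng.uniform(0.7, 1.1, coarse_shape)
    base[0, :] = rng.uniform(2.0, 15.0, coarse_shape[1])
    coarse_npp = {}
    for y in years:
        drift = 1.0 + 0.002 * (y - years[0])
        coarse_npp[y] = np.clip(base * drift + rng.normal(0.0, 3.0, coarse_shape), 0.0, None)

    # --- human footprint, intact forest landscapes, forest zone ------------
    fp_base = np.clip(25.0 + 18.0 * _smooth(rng, shape, 4.0)
                      - 30.0 * (np.abs(lat) > np.abs(lat).max() - 6.0), 0.0, 50.0)
    wild_field = _smooth(rng, shape, 6.0)
    fp_base[wild_field > np.quantile(wild_field, 0.85)] = 0.0
    footprint = {}
    for y in range(2000, 2019):
        fp = np.clip(fp_base + 0.15 * (y - 2000) * (fp_base > 0), 0.0, 50.0)
        footprint[y] = fp
    fp93 = np.clip(fp_base + rng.normal(0.0, 2.0, shape), 0.0, 50.0)
    fp93[fp_base == 0] = np.clip(fp93[fp_base == 0], 0.0, 1.5)
    footprint[1993] = fp93

    forest_cover = cover[years[0]].get(50, 0) + cover[years[0]].get(71, 0)
    forest_zone = ndimage.gaussian_filter(np.asarray(forest_cover, float), 3.0) > 0.15
    ifl = {}
    for i, ep in enumerate((2000, 2013, 2016, 2020)):
        shrink = ndimage.gaussian_filter(wild_field, 1.0) > np.quantile(wild_field, 0.85 + 0.02 * i)
        ifl[ep] = (forest_zone & shrink).astype(float)

    # --- population and degradation ---------------------------------------
    pop_field = _smooth(rng, shape, 4.0)
    population = np.clip(80.0 * np.exp(1.5 * pop_field) * (fp_base > 0), 0.0, None)
    degradation = np.clip(0.85 + 0.1 * _smooth(rng, shape, 5.0), 0.6, 1.0)

    # --- SPAM-like crop pattern layers (coarse grid, 4 epochs) -------------
    sf = cfg.spam_factor
    spam_shape = (shape[0] // sf, shape[1] // sf)
    spam_physical: dict[str, dict[int, np.ndarray]] = {}
    spam_mc: dict[str, dict[int, np.ndarray]] = {}
    spam_yield: dict[str, dict[int, np.ndarray]] = {}
    for crop in cfg.crops:
        pat = np.clip(1.0 + _smooth(rng, spam_shape, 2.0), 0.1, None)
        mc = np.clip(1.0 + 0.4 * np.abs(_smooth(rng, spam_shape, 2.0)), 1.0, 2.0)
        yld = np.clip(300.0 * (1.0 + 0.5 * _smooth(rng, spam_shape, 2.0)), 50.0, None)
        spam_physical[crop] = {}
        spam_mc[crop] = {}
        spam_yield[crop] = {}
        for i, ep in enumerate((2000, 2005, 2010, 2020)):
            g = 1.0 + 0.05 * i
            spam_physical[crop][ep] = pat * g
            spam_mc[crop][ep] = mc
            spam_yield[crop][ep] = yld * g

    # --- national accounts consistent with the cover-derived capacities ----
    table = load_default_table()
    gt = GroundTruth()
    land_rows, crop_rows = [], []
    crop_share = {}
    for cid in partition.ids:
        w = rng.dirichlet(np.ones(len(cfg.crops)) * 2.0)
        crop_share[int(cid)] = dict(zip(cfg.crops, w))
    crop_frac = {int(cid): rng.uniform(0.45, 0.75) for cid in partition.ids}
    graz_frac = {int(cid): rng.uniform(0.35, 0.65) for cid in partition.ids}
    harv_frac = {int(cid): rng.uniform(0.7, 0.9) for cid in partition.ids}

    for y in years:
        stacks = cover_to_suitability(cover[y], table, area)
        cl_pre = np.zeros(shape)
        for cid in partition.ids:
            m = partition.mask(cid)
            s1 = np.where(m, stacks["crop1"], 0.0)
            cap1 = s1.sum()
            if cfg.switches.cropland_overshoot:
                cap123 = cap1 + stacks["crop2"][m].sum() + stacks["crop3"][m].sum()
                target = 1.5 * cap123
            else:
                target = crop_frac[int(cid)] * cap1
            land_rows.append({"country": int(cid), "year": y, "cropland_km2": target})
            if cap1 > 0:
                cl_pre += s1 * (min(target, cap1) / cap1)
        bu = stacks["builtup"] + 0.05 * cl_pre
        cl_post = 0.95 * cl_pre
        gt.cropland_pre[y] = cl_pre
        gt.cropland_post[y] = cl_post
        gt.builtup[y] = bu

        gt.grazing_capacity_suit1[y] = {}

        for cid in partition.ids:
            m = partition.mask(cid)
            cl_fao = [r for r in land_rows if r["country"] == int(cid) and r["year"] == y][-1]["cropland_km2"]
            total_harv = harv_frac[int(cid)] * cl_fao
            for crop in cfg.crops:
                h = total_harv * crop_share[int(cid)][crop]
                crop_rows.append({
                    "country": int(cid), "year": y, "crop": crop,
                    "area_harvested_km2": h,
                    "production_t": np.nan,  # filled after yields are interpolated
                })
            # fodder production is not census-reported: emit it explicitly,
            # scaled to the fallow margin it will be grown on (zero
            # harvested area keeps it out of the fallow-minimum identity)
            crop_rows.append({
                "country": int(cid), "year": y, "crop": "CL-FODD",
                "area_harvested_km2": 0.0,
                "production_t": np.nan,
            })

    land_df = pd.DataFrame(land_rows) if land_rows else pd.DataFrame(
        columns=["country", "year", "cropland_km2"])
    crops_df = pd.DataFrame(crop_rows) if crop_rows else pd.DataFrame(
        columns=["country", "year", "crop", "area_harvested_km2", "production_t"])

    # crop production consistent with harvested area × a country-mean yield
    if len(crops_df):
        yld_year = {c: make_epoch_series(spam_yield[c], years) for c in cfg.crops}
        mean_yield = {(c, y): float(np.asarray(yld_year[c][y]).mean())
                      for c in cfg.crops for y in years}
        totals = crops_df.groupby(["country", "year"])["area_harvested_km2"].sum()
        land_idx = land_df.set_index(["country", "year"])["cropland_km2"]
        prod = []
        for _, r in crops_df.iterrows():
            key = (r["country"], r["year"])
            if r["crop"] == "CL-FODD":
                margin = max(float(land_idx.loc[key]) - float(totals.loc[key]), 0.0)
                avg_y = float(np.mean([mean_yield[(c, r["year"])] for c in cfg.crops]))
                prod.append(0.3 * margin * avg_y)
            else:
                prod.append(r["area_harvested_km2"] * mean_yield[(r["crop"], r["year"])])
        crops_df["production_t"] = prod

    # grazing targets need the wilderness masks; assemble the world first,
    # then fill the grazing column and the remaining statistics tables
    accounts = NationalAccounts(
        land=land_df, crops=crops_df,
        wood=pd.DataFrame(columns=["country", "year", "product", "tree_type", "volume_m3"]),
        livestock=pd.DataFrame(columns=["country", "year", "species", "heads", "milk_yield_t", "carcass_kg"]),
        feed=pd.DataFrame(columns=["country", "year", "market_feed_tC", "residues_tC", "oil_production_t"]),
        trade=pd.DataFrame(columns=["year", "importer", "exporter", "reported_by", "oilcake_t"]),
        fertilized={int(cid): False for cid in partition.ids},
    )
    world = SyntheticWorld(
        config=cfg, grid=cfg.grid, area=area, partition=partition, cover=cover,
        spam_physical=spam_physical, spam_multicropping=spam_mc, spam_yield=spam_yield,
        footprint=footprint, ifl=ifl, forest_zone=forest_zone,
        coarse_npp=coarse_npp, ecoregions_fine=ecoregions_fine,
        temperature=temperature, precipitation=precipitation,
        population=population, degradation=degradation,
        accounts=accounts, ground_truth=gt,
    )
    _fill_dependent_accounts(world, rng, graz_frac)
    return world


def _fill_dependent_accounts(world: SyntheticWorld, rng: np.random.Generator,
                             graz_frac: dict[int, float]) -> None:
    """Grazing targets, wood volumes and livestock/feed tables, scaled to the
    capacities the generated fields actually provide."""
    cfg = world.config
    years = cfg.year_list
    table = load_default_table()
    sw = cfg.switches
    ids = [int(c) for c in world.partition.ids]
    if not ids:
        world.accounts.land["grazing_km2"] = pd.Series(dtype=float)
        return
    npp_fine = world.npp_pot_fine()

    graz_rows, wood_rows, lv_rows, feed_rows, trade_rows = [], [], [], [], []
    for y in years:
        stacks = cover_to_suitability(world.cover[y], table, world.area)
        cl_pre = world.ground_truth.cropland_pre[y]
        bu = world.ground_truth.builtup[y]
        npp = npp_fine[y]
        fpy = footprint_for_year(world.footprint, y)
        ifl_y = np.asarray(make_epoch_series(world.ifl, [y])[y]) >= 0.5
        nps = npp < 20.0
        fp0 = fpy == 0
        core = np.where(world.forest_zone, fp0 & ifl_y, fp0) & ~nps
        peri = world.forest_zone & (fp0 ^ ifl_y) & ~nps & ~core
        wild = nps | core | peri
        remaining = np.clip(world.area.area_land - bu - 0.95 * cl_pre, 0.0, None)
        remaining[wild] = 0.0

        for cid in ids:
            m = world.partition.mask(cid)
            net1 = np.clip(np.where(m, stacks["graz1"], 0.0) - cl_pre * m, 0.0, None)
            net1 = np.minimum(net1, np.where(m, remaining, 0.0))
            cap1 = float(net1.sum())
            world.ground_truth.grazing_capacity_suit1[y][cid] = cap1
            if sw.grazing_overshoot:
                cap123 = cap1 + float(np.minimum(
                    np.where(m, stacks["graz2"] + stacks["graz3"], 0.0), remaining).sum())
                target = 2.0 * (cap123 + float(np.where(m, peri * world.area.area_land, 0.0).sum()))
            else:
                target = graz_frac[cid] * cap1
            graz_rows.append({"country": cid, "year": y, "grazing_km2": target})

            # wood volumes: a modest share of the closed-forest 70% cap, so
            # default demands are always placeable
            for t, col in (("con", "forest_con"), ("ncon", "forest_ncon")):
                cap_npp = float((np.minimum(np.where(m, stacks[col], 0.0), world.area.area_land) * npp).sum())
                # volume such that demand ≈ share · 0.7 · NPP cap with the
                # default factor chain (0.5 t/m3 · 0.5 C · expansion 2)
                share = 3.0 if sw.wood_overshoot else rng.uniform(0.1, 0.3)
                vol = share * 0.7 * cap_npp / (0.5 * 0.5 * 2.0)
                for prod, pshare in (("IR", 0.6), ("WF", 0.4)):
                    wood_rows.append({"country": cid, "year": y, "product": prod,
                                      "tree_type": t, "volume_m3": vol * pshare})

            # livestock scaled against grazable capacity so the default
            # grazing gap sits inside the baseline gradient capacity
            graz_area = target
            cap_feed = 0.5 * 0.6 * float(np.where(m, npp, 0.0).mean()) * graz_area  # tC/yr, rough
            demand = (2.5 if sw.grazing_overshoot else rng.uniform(0.3, 0.6)) * max(cap_feed, 1.0)
            heads = demand / (8.0 * 365.0 * 0.45 / 1000.0)  # invert default cattle intake
            lv_rows.append({"country": cid, "year": y, "species": "cattle", "heads": heads,
                            "milk_yield_t": rng.uniform(2.0, 8.0), "carcass_kg": rng.uniform(180, 320)})
            lv_rows.append({"country": cid, "year": y, "species": "sheep",
                            "heads": heads * rng.uniform(0.1, 0.3),
                            "milk_yield_t": 0.0, "carcass_kg": 0.0})
            feed_rows.append({"country": cid, "year": y,
                              "market_feed_tC": 0.2 * demand,
                              "residues_tC": 0.15 * demand,
                              "oil_production_t": rng.uniform(0.0, 0.05) * demand})
        # bilateral oilcake trade among the countries, both reporters present
        for i in ids:
            for j in ids:
                if i == j:
                    continue
                v = rng.uniform(0.0, 1000.0)
                trade_rows.append({"year": y, "importer": i, "exporter": j,
                                   "reported_by": "importer", "oilcake_t": v})
                trade_rows.append({"year": y, "importer": i, "exporter": j,
                                   "reported_by": "exporter", "oilcake_t": v * rng.uniform(0.8, 1.2)})

    # intended per-cell crop harvested areas: the harvesting share of each
    # cropland cell split along the crop-pattern physical-area shares and
    # scaled per country-crop to the census harvested areas (the generated
    # patterns cover every cell, so pattern adaptation is the identity)
    for y in years:
        cl_post = world.ground_truth.cropland_post[y]
        phys_y = {c: np.repeat(np.repeat(
            np.asarray(make_epoch_series(world.spam_physical[c], [y])[y]),
            cfg.spam_factor, axis=0), cfg.spam_factor, axis=1) for c in cfg.crops}
        mc_y = {c: np.repeat(np.repeat(
            np.asarray(make_epoch_series(world.spam_multicropping[c], [y])[y]),
            cfg.spam_factor, axis=0), cfg.spam_factor, axis=1) for c in cfg.crops}
        tot = sum(phys_y.values())
        gt_harv: dict[str, np.ndarray] = {}
        crops_y = world.accounts.crops[world.accounts.crops["year"] == y]
        land_y = world.accounts.land[world.accounts.land["year"] == y].set_index("country")
        for cid in ids:
            m = world.partition.mask(cid)
            cl_fao = float(land_y.loc[cid, "cropland_km2"])
            rows = crops_y[crops_y["country"] == cid]
            tot_harv = float(rows["area_harvested_km2"].sum())
            if cl_fao <= 0:
                continue
            clharv = np.where(m, cl_post, 0.0) * (tot_harv / cl_fao)
            for _, r in rows.iterrows():
                c = r["crop"]
                if c not in phys_y or float(r["area_harvested_km2"]) <= 0:
                    continue
                base = clharv * np.where(tot > 0, phys_y[c] / np.where(tot > 0, tot, 1.0), 0.0)
                bs = base.sum()
                if bs > 0:
                    gt_harv.setdefault(c, np.zeros(cl_post.shape))
                    gt_harv[c] += base * (float(r["area_harvested_km2"]) / bs)
        world.ground_truth.crop_harvested[y] = gt_harv
        world.ground_truth.crop_physical[y] = {
            c: gt_harv[c] / mc_y[c] for c in gt_harv}

    acc = world.accounts
    if graz_rows:
        gdf = pd.DataFrame(graz_rows)
        acc.land = acc.land.merge(gdf, on=["country", "year"], how="left")
    else:
        acc.land["grazing_km2"] = pd.Series(dtype=float)
    acc.wood = pd.DataFrame(wood_rows, columns=["country", "year", "product", "tree_type", "volume_m3"])
    acc.livestock = pd.DataFrame(lv_rows, columns=["country", "year", "species", "heads", "milk_yield_t", "carcass_kg"])
    acc.feed = pd.DataFrame(feed_rows, columns=["country", "year", "market_feed_tC", "residues_tC", "oil_production_t"])
    acc.trade = pd.DataFrame(trade_rows, columns=["year", "importer", "exporter", "reported_by", "oilcake_t"])
    if cfg.switches.fertilized_country and ids:
        acc.fertilized[ids[0]] = True
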