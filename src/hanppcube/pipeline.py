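"""End-to-end cube construction: areas then NPP flows, year by year.

Each year is allocated from scratch (stateless across years) in the
priority order: built-up seed → national cropland → crop split →
unproductive wilderness → core/peripheral wilderness → national grazing
→ closed-forest forestry → open wooded land → residual grazing land.
The per-cell land budget closes exactly after every year, and national
census targets are met exactly wherever suitability capacity suffices.

Flow conventions by class (tC/yr per cell):

* crop classes — harvest from national production distributed along the
  crop-pattern production surface; actual NPP from the pre-harvest-loss
  share; conversion flow vs. potential NPP on the crop's physical area
  (sign-free).
* fallow — no harvest; actual NPP taken at potential (no conversion flow).
* built-up — fixed fractions of potential NPP (1/6 harvest, 2/3
  conversion, 1/6 ecosystem).
* forestry — actual NPP equals potential (zero conversion flow); wood
  harvest capped at 70% of actual NPP.
* grazing classes — actual NPP is potential NPP reduced by the
  degradation/conversion factor map (boosted on the treeless class for
  fertilising countries); grazing harvest via the intensity gradient; the
  open-wooded class additionally carries wood-fuel harvest.
* wilderness — no flows; all potential NPP remains in the ecosystem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import agriculture, grazing as grz, wood as wd
from .allocation import (
    ReconciliationLog,
    allocate_builtup,
    allocate_sequential,
    classify_wilderness,
    split_cropland,
)
from .classes import ALL_CLASSES, CROP_CLASSES
from .grid import closed_budget_check
from .suitability import cover_to_suitability, load_default_table
from .synthetic import SyntheticWorld
from .timeseries import footprint_for_year, make_epoch_series

__all__ = ["CubeResult", "build_year", "build_cube"]


@dataclass
class CubeResult:
    """Areas and flows per year plus the reconciliation log."""

    years: list[int]
    layers: dict[int, dict[str, dict[str, np.ndarray]]] = field(default_factory=dict)
    log: ReconciliationLog = field(default_factory=ReconciliationLog)

    def area_layers(self, year: int) -> dict[str, np.ndarray]:
        return {cls: self.layers[year][cls]["area"] for cls in self.layers[year]}


def _upsample(arr: np.ndarray, factor: int) -> np.ndarray:
    return np.repeat(np.repeat(arr, factor, axis=0), factor, axis=1)


def build_year(
    world: SyntheticWorld,
    year: int,
    npp_fine: np.ndarray,
    log: ReconciliationLog,
    suit_table=None,
    crop_factors: agriculture.CropFactorTable | None = None,
    wood_factors: wd.WoodFactors = wd.WoodFactors(),
    feed_params: grz.FeedParams = grz.FeedParams(),
    gradient: grz.GradientConfig = grz.GradientConfig(),
    palatable_share: float = 0.5,
) -> dict[str, dict[str, np.ndarray]]:
    """Build all 32 class layers (area + flows) for one year."""
    cfg = world.config
    area = world.area
    part = world.partition
    shape = cfg.grid.shape
    suit_table = suit_table or load_default_table()
    crop_factors = crop_factors or agriculture.load_default_crop_factors()

    stacks = cover_to_suitability(world.cover[year], suit_table, area)
    zeros = lambda: np.zeros(shape)  # noqa: E731

    # --- step 1: built-up seed --------------------------------------------
    bu_seed = np.minimum(stacks["builtup"], area.area_land)
    remaining = area.area_land - bu_seed

    # --- step 2: national cropland ----------------------------------------
    land_y = world.accounts.land[world.accounts.land["year"] == year].set_index("country")
    cl_pre = zeros()
    crop_taken = [zeros(), zeros(), zeros()]
    for cid in part.ids:
        m = part.mask(cid)
        budget = np.where(m, remaining, 0.0)
        nets = []
        for k in ("crop1", "crop2", "crop3"):
            net = np.minimum(np.where(m, stacks[k], 0.0), budget)
            nets.append(net)
            budget = budget - net
        target = float(land_y.loc[int(cid), "cropland_km2"]) if int(cid) in land_y.index else 0.0
        allocs, shortfall = allocate_sequential(target, nets)
        for k in range(3):
            crop_taken[k] += allocs[k]
        cl_pre += sum(allocs)
        if shortfall > 1e-9:
            log.add(country=int(cid), year=year, stage="cropland",
                    event="target_shortfall", value=shortfall)
        log.add(country=int(cid), year=year, stage="cropland", event="placed",
                target=target, value=float(sum(a.sum() for a in allocs)))
    remaining = np.clip(remaining - cl_pre, 0.0, None)

    bu, cl = allocate_builtup(bu_seed, cl_pre)

    # --- step 3: crop split ------------------------------------------------
    sf = cfg.spam_factor
    phys_fine = {c: _upsample(np.asarray(make_epoch_series(world.spam_physical[c], [year])[year]), sf)
                 for c in cfg.crops}
    mc_fine = {c: _upsample(np.asarray(make_epoch_series(world.spam_multicropping[c], [year])[year]), sf)
               for c in cfg.crops}
    yld_fine = {c: _upsample(np.asarray(make_epoch_series(world.spam_yield[c], [year])[year]), sf)
                for c in cfg.crops}
    crops_y = world.accounts.crops[world.accounts.crops["year"] == year]
    split = split_cropland(
        cl, part,
        land_y.reset_index()[["country", "cropland_km2"]],
        crops_y[["country", "crop", "area_harvested_km2"]],
        phys_fine, mc_fine, log, year=year,
    )

    # --- steps 4–5: wilderness --------------------------------------------
    fp = footprint_for_year(world.footprint, year)
    ifl_y = np.asarray(make_epoch_series(world.ifl, [year])[year]) >= 0.5
    nps_m, core_m, peri_m = classify_wilderness(npp_fine, fp, ifl_y, world.forest_zone)
    wild_nps = np.where(nps_m, remaining, 0.0)
    remaining = remaining - wild_nps
    wild_core = np.where(core_m, remaining, 0.0)
    remaining = remaining - wild_core
    wild_peri = np.where(peri_m, remaining, 0.0)
    remaining = remaining - wild_peri

    # --- steps 6–9: grazing, forestry, open wooded land, residual ----------
    from .allocation import allocate_grazing_forestry

    graz_targets = {int(c): float(land_y.loc[int(c), "grazing_km2"])
                    for c in part.ids if int(c) in land_y.index}
    res = allocate_grazing_forestry(
        remaining,
        [stacks["graz1"], stacks["graz2"], stacks["graz3"]],
        crop_taken[:2],
        wild_peri,
        graz_targets,
        part,
        stacks["forest_con"], stacks["forest_ncon"],
        stacks["owl_con"], stacks["owl_ncon"],
        log, year=year,
    )

    # --- assemble area layers ---------------------------------------------
    areas: dict[str, np.ndarray] = {c: zeros() for c in ALL_CLASSES}
    for c in CROP_CLASSES:
        if c in split.physical:
            areas[c] = split.physical[c]
    areas["CL-FODD"] = split.fodder
    areas["CL-FALL"] = split.fallow
    areas["BU-builtup"] = bu
    areas["GL-notrees"] = res["GL-notrees"]
    areas["GL-owl"] = res["GL-owl"]
    areas["FO-con"] = res["FO-con"]
    areas["FO-ncon"] = res["FO-ncon"]
    areas["WILD-core"] = wild_core
    areas["WILD-periphery"] = res["WILD-periphery"]
    areas["WILD-nps"] = wild_nps

    # --- flows -------------------------------------------------------------
    flows: dict[str, dict[str, np.ndarray]] = {}

    # cropland
    national = agriculture.national_crop_hanpp_harv(
        crops_y[["country", "crop", "production_t"]], crop_factors)
    harv_layers = agriculture.distribute_crop_harvest(
        national, split, yld_fine, part, log, year=year)
    npp_act_c, luc_c = agriculture.cropland_npp_act(
        harv_layers, crop_factors, npp_fine,
        {**split.physical, "CL-FODD": split.fodder})
    for c in CROP_CLASSES + ["CL-FODD"]:
        harv = harv_layers.get(c, zeros())
        act = npp_act_c.get(c, npp_fine * areas[c])
        luc = luc_c.get(c, zeros())
        flows[c] = {"area": areas[c], "hanpp_harv": harv,
                    "hanpp_luc": luc, "npp_eco": act - harv}
    pot_fall = npp_fine * areas["CL-FALL"]
    flows["CL-FALL"] = {"area": areas["CL-FALL"], "hanpp_harv": zeros(),
                        "hanpp_luc": zeros(), "npp_eco": pot_fall}

    # built-up
    pot_bu = npp_fine * areas["BU-builtup"]
    h, l, e = agriculture.builtup_hanpp(pot_bu)
    flows["BU-builtup"] = {"area": areas["BU-builtup"], "hanpp_harv": h,
                           "hanpp_luc": l, "npp_eco": e}

    # forestry + open wooded land wood harvest
    pools = {
        ("FO", "con"): npp_fine * areas["FO-con"],
        ("FO", "ncon"): npp_fine * areas["FO-ncon"],
        ("OWL", "con"): npp_fine * world.degradation * res["GL-owl-con"],
        ("OWL", "ncon"): npp_fine * world.degradation * res["GL-owl-ncon"],
    }
    wood_y = world.accounts.wood[world.accounts.wood["year"] == year]
    wood_dem = wd.wood_demand_from_stats(wood_y, wood_factors) if len(wood_y) else wood_y
    wood_harv = {p: zeros() for p in pools}
    for cid in part.ids:
        m = part.mask(cid)
        sub = wood_dem[wood_dem["country"] == int(cid)] if len(wood_dem) else wood_dem
        demand = {}
        for _, r in sub.iterrows():
            key = (r["product"], r["tree_type"])
            demand[key] = demand.get(key, 0.0) + float(r["demand_tC"])
        if not demand:
            continue
        walloc = wd.allocate_wood_country(
            demand, {p: np.where(m, pools[p], 0.0) for p in pools},
            log, country=int(cid), year=year)
        for (pool, _key), layer in walloc.layers.items():
            wood_harv[pool] += layer
    for cls, pool in (("FO-con", ("FO", "con")), ("FO-ncon", ("FO", "ncon"))):
        pot = pools[pool]
        flows[cls] = {"area": areas[cls], "hanpp_harv": wood_harv[pool],
                      "hanpp_luc": zeros(), "npp_eco": pot - wood_harv[pool]}

    # grazing
    demand = grz.feed_demand(
        world.accounts.livestock[world.accounts.livestock["year"] == year], feed_params)
    market = grz.market_feed_supply(
        world.accounts.feed[world.accounts.feed["year"] == year],
        world.accounts.trade[world.accounts.trade["year"] == year], feed_params)
    residues = world.accounts.feed[world.accounts.feed["year"] == year] \
        .set_index("country")["residues_tC"]

    act_nt = npp_fine * world.degradation * areas["GL-notrees"]
    act_owl_gr = pools[("OWL", "con")] + pools[("OWL", "ncon")]
    graz_stack = np.stack([act_nt, act_owl_gr])           # (2, nr, nc)
    nt_mask = np.zeros_like(graz_stack, dtype=bool)
    nt_mask[0] = True
    pop2 = np.stack([world.population, world.population])

    harv_nt, harv_owl = zeros(), zeros()
    boost_map = np.ones(shape)
    for cid in part.ids:
        cid = int(cid)
        m = part.mask(cid)
        bal = grz.grazing_gap(float(demand.get(cid, 0.0)), float(market.get(cid, 0.0)),
                              float(residues.get(cid, 0.0)))
        grazable, potential = grz.grazing_potential(
            np.where(np.stack([m, m]), graz_stack, 0.0), palatable_share, pop2)
        r = grz.distribute_grazing(
            bal.grazing_gap, grazable, potential, nt_mask,
            fertilized=world.accounts.fertilized.get(cid, False),
            config=gradient, log=log, country=cid, year=year)
        harv_nt += r.harvest[0]
        harv_owl += r.harvest[1]
        if r.boost > 1.0:
            boost_map[m] = r.boost

    act_nt_final = act_nt * boost_map
    pot_nt = npp_fine * areas["GL-notrees"]
    flows["GL-notrees"] = {"area": areas["GL-notrees"], "hanpp_harv": harv_nt,
                           "hanpp_luc": pot_nt - act_nt_final,
                           "npp_eco": act_nt_final - harv_nt}
    pot_owl = npp_fine * areas["GL-owl"]
    owl_wood = wood_harv[("OWL", "con")] + wood_harv[("OWL", "ncon")]
    flows["GL-owl"] = {"area": areas["GL-owl"],
                       "hanpp_harv": harv_owl + owl_wood,
                       "hanpp_luc": pot_owl - act_owl_gr,
                       "npp_eco": act_owl_gr - harv_owl - owl_wood}

    # wilderness
    for cls in ("WILD-core", "WILD-periphery", "WILD-nps"):
        pot = npp_fine * areas[cls]
        flows[cls] = {"area": areas[cls], "hanpp_harv": zeros(),
                      "hanpp_luc": zeros(), "npp_eco": pot}
    return flows


def build_cube(world: SyntheticWorld, **kwargs) -> CubeResult:
    """Build the full cube for every year of the world's span."""
    years = world.config.year_list
    result = CubeResult(years=years)
    npp = world.npp_pot_fine()
    for y in years:
        result.layers[y] = build_year(world, y, npp[y], result.log, **kwargs)
        violations = closed_budget_check(result.area_layers(y), world.area)
        if violations:
            raise AssertionError(
                f"closed budget violated in year {y}: {len(violations)} cells, "
                f"worst {max(abs(v[2]) for v in violations):.3e} km²")
    return result
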