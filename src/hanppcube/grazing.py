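"""Grazing HANPP: national feed balance and the intensity-gradient mapping.

The national demand for grazed biomass is a residual ("grazing gap"):
livestock feed demand minus market feed and crop residues, with floors
guaranteeing that at least 30% of demand is covered by roughage (residues
plus grazing) and at least 15% by grazing alone.  The gap is distributed
within each country along a grazing-intensity (GI) gradient over the
cells' grazing potentials — grazable NPP times a population-density
response — assigning a baseline GI of 40% to the lowest-potential 10% of
cells and 80% (the seasonal maximum) to the highest 15%, linear in rank
between.  When the baseline capacity falls short the gradient is
flattened stepwise (up to GI_min 75% on 85% of cells); countries that
fertilise grassland may instead boost grazable NPP on the treeless
grazing class by up to a factor 2 (3 in the extreme fallback); any
remaining gap is reduced and logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allocation import ReconciliationLog

__all__ = [
    "FeedParams",
    "GradientConfig",
    "FeedBalance",
    "feed_demand",
    "market_feed_supply",
    "grazing_gap",
    "grazing_potential",
    "distribute_grazing",
    "GrazingResult",
]


@dataclass(frozen=True)
class FeedParams:
    """Feed-intake regressions and conversion factors (configuration).

    Cattle intake (kg dry matter/head/day) is estimated twice — from the
    national milk yield and from the carcass weight — and the minimum is
    used.  Other roughage consumers get fixed intakes.
    """

    milk_intercept: float = 4.0
    milk_slope: float = 1.0        # per t milk yield per head-year
    beef_intercept: float = 5.0
    beef_slope: float = 0.02       # per kg carcass weight
    other_intake: dict[str, float] = field(default_factory=lambda: {"sheep": 1.2, "goats": 1.1})
    carbon_per_dm: float = 0.45    # tC per t dry matter
    oil_to_cake: float = 1.2       # t oilcake per t vegetable oil
    cake_carbon: float = 0.45      # tC per t oilcake


def feed_demand(livestock: pd.DataFrame, params: FeedParams = FeedParams()) -> pd.Series:
    """Roughage feed demand (tC/yr) per country.

    ``livestock`` columns: country, species, heads, milk_yield_t, carcass_kg.
    """
    out: dict[int, float] = {}
    for _, r in livestock.iterrows():
        cid = int(r["country"])
        heads = float(r["heads"])
        if heads < 0:
            raise ValueError("negative livestock heads")
        sp = r["species"]
        if sp == "cattle":
            intake_milk = params.milk_intercept + params.milk_slope * float(r["milk_yield_t"])
            intake_beef = params.beef_intercept + params.beef_slope * float(r["carcass_kg"])
            intake = min(intake_milk, intake_beef)
        else:
            if sp not in params.other_intake:
                raise KeyError(f"no intake regression configured for species {sp!r}")
            intake = params.other_intake[sp]
        out[cid] = out.get(cid, 0.0) + heads * 365.0 * intake / 1000.0 * params.carbon_per_dm
    return pd.Series(out, dtype=float).sort_index()


def market_feed_supply(
    feed: pd.DataFrame, trade: pd.DataFrame, params: FeedParams = FeedParams()
) -> pd.Series:
    """Market feed (tC/yr) per country: reported feed plus the oilcake
    supply estimated as production + imports − exports (floored at zero),
    with importer-reported trade flows preferred over exporter-reported."""
    # deduplicate bilateral flows: importer-reported beats exporter-reported
    flows: dict[tuple[int, int], float] = {}
    reported: dict[tuple[int, int], str] = {}
    for _, r in trade.iterrows():
        key = (int(r["importer"]), int(r["exporter"]))
        role = str(r["reported_by"])
        if key not in flows or (role == "importer" and reported[key] != "importer"):
            flows[key] = float(r["oilcake_t"])
            reported[key] = role
    out: dict[int, float] = {}
    for _, r in feed.iterrows():
        cid = int(r["country"])
        cake_prod = float(r["oil_production_t"]) * params.oil_to_cake
        imports = sum(v for (imp, _), v in flows.items() if imp == cid)
        exports = sum(v for (_, exp), v in flows.items() if exp == cid)
        cake = max(cake_prod + imports - exports, 0.0) * params.cake_carbon
        out[cid] = float(r["market_feed_tC"]) + cake
    return pd.Series(out, dtype=float).sort_index()


@dataclass
class FeedBalance:
    """National feed balance (tC/yr)."""

    demand: float
    market: float
    residues: float
    grazing_gap: float

    def __post_init__(self) -> None:
        assert self.grazing_gap >= 0.15 * self.demand - 1e-9
        assert self.residues + self.grazing_gap >= 0.30 * self.demand - 1e-9


def grazing_gap(demand: float, market: float, residues: float) -> FeedBalance:
    """Grazed-biomass demand after the roughage floors.

    The gap is at least 15% of demand, and residues plus gap at least 30%;
    residue use is capped by what the demand leaves after the gap.
    """
    if min(demand, market, residues) < 0:
        raise ValueError("feed components must be non-negative")
    gap = max(demand - market - residues, 0.15 * demand, 0.30 * demand - residues)
    residues_used = min(residues, max(demand - gap, 0.0))
    return FeedBalance(demand=demand, market=market, residues=residues_used, grazing_gap=gap)


@dataclass(frozen=True)
class GradientConfig:
    """Grazing-intensity gradient parameters (fractions of grazable NPP)."""

    gi_min: float = 0.40
    gi_max: float = 0.80
    p_low: float = 0.10
    p_high: float = 0.15
    gi_min_cap: float = 0.75
    p_high_cap: float = 0.85
    gi_min_step: float = 0.01
    p_high_step: float = 0.02
    boost_cap: float = 2.0
    extreme_boost_cap: float = 3.0


def grazing_potential(
    npp_act_grazing: np.ndarray,
    palatable_share: float,
    population_density: np.ndarray,
    poly2_coeffs: tuple[float, float, float] = (0.2, 0.004, -2e-6),
) -> tuple[np.ndarray, np.ndarray]:
    """Grazable NPP and grazing potential per cell.

    Grazable NPP is the palatable share of actual NPP; the potential
    weights it by a second-order polynomial response to population
    density, floored at zero.  Returns (grazable, potential).
    """
    grazable = np.asarray(npp_act_grazing, float) * palatable_share
    c0, c1, c2 = poly2_coeffs
    d = np.asarray(population_density, float)
    w = np.clip(c0 + c1 * d + c2 * d * d, 0.0, None)
    return grazable, grazable * w


def _gi_from_rank(p: np.ndarray, gi_min: float, gi_max: float, p_low: float, p_high: float) -> np.ndarray:
    hi_start = 1.0 - p_high
    gi = np.empty_like(p)
    low = p <= p_low
    high = p >= hi_start
    mid = ~low & ~high
    gi[low] = gi_min
    gi[high] = gi_max
    span = max(hi_start - p_low, 1e-12)
    gi[mid] = gi_min + (gi_max - gi_min) * (p[mid] - p_low) / span
    return gi


@dataclass
class GrazingResult:
    harvest: np.ndarray          # tC/yr per cell
    gi: np.ndarray               # intensity applied per cell (before scale)
    scale: float
    boost: float                 # factor applied on the treeless class
    unmet: float
    gi_min_used: float
    p_high_used: float


def distribute_grazing(
    gap: float,
    grazable: np.ndarray,
    potential: np.ndarray,
    notrees_mask: np.ndarray,
    fertilized: bool = False,
    config: GradientConfig = GradientConfig(),
    log: ReconciliationLog | None = None,
    country: int | None = None,
    year: int | None = None,
) -> GrazingResult:
    """Distribute a country's grazing gap along the intensity gradient.

    Cells are ranked by grazing potential (ties broken by cell index);
    the rank percentile sets each cell's GI.  If baseline capacity covers
    the gap a single ≤1 scale factor is applied to all cells; otherwise
    the gradient is flattened stepwise, with NPP boosting on the treeless
    class for fertilising countries; whatever remains unmet is reduced.
    """
    cells = grazable > 0
    shape = grazable.shape
    if not np.any(cells) or gap <= 0:
        if gap > 0 and log is not None:
            log.add(country=country, year=year, stage="grazing_harvest",
                    event="demand_reduced", value=gap)
        return GrazingResult(np.zeros(shape), np.zeros(shape), 0.0, 1.0, max(gap, 0.0),
                             config.gi_min, config.p_high)
    flat_idx = np.flatnonzero(cells.ravel())
    order = np.lexsort((flat_idx, potential.ravel()[flat_idx]))
    n = order.size
    p = np.empty(n)
    p[order] = np.arange(n) / max(n - 1, 1)
    pmap = np.zeros(shape)
    pmap[cells] = p

    graz = grazable[cells]
    nt = notrees_mask[cells]

    def capacity(gi_min, p_high, boost):
        gi = _gi_from_rank(p, gi_min, config.gi_max, config.p_low, p_high)
        eff = graz * np.where(nt, boost, 1.0)
        return gi, float((gi * eff).sum()), eff

    gi_min, p_high, boost = config.gi_min, config.p_high, 1.0
    gi, cap, eff = capacity(gi_min, p_high, boost)

    def needed_boost(gi):
        owl_cap = float((gi * graz)[~nt].sum())
        nt_base = float((gi * graz)[nt].sum())
        if nt_base <= 0:
            return np.inf
        return (gap - owl_cap) / nt_base

    while cap < gap and (gi_min < config.gi_min_cap - 1e-12 or p_high < config.p_high_cap - 1e-12):
        if fertilized and needed_boost(gi) <= config.boost_cap:
            break
        gi_min = min(gi_min + config.gi_min_step, config.gi_min_cap)
        p_high = min(p_high + config.p_high_step, config.p_high_cap)
        gi, cap, eff = capacity(gi_min, p_high, boost)

    if cap < gap and fertilized:
        b = needed_boost(gi)
        boost = float(np.clip(b, 1.0, config.boost_cap if b <= config.boost_cap
                              else config.extreme_boost_cap))
        gi, cap, eff = capacity(gi_min, p_high, boost)

    scale = min(gap / cap, 1.0) if cap > 0 else 0.0
    harvest_cells = scale * gi * eff
    unmet = max(gap - cap, 0.0)
    if unmet > 1e-9 and log is not None:
        log.add(country=country, year=year, stage="grazing_harvest",
                event="demand_reduced", value=unmet)

    harvest = np.zeros(shape)
    harvest[cells] = harvest_cells
    gimap = np.zeros(shape)
    gimap[cells] = gi
    return GrazingResult(harvest=harvest, gi=gimap, scale=scale, boost=boost,
                         unmet=unmet, gi_min_used=gi_min, p_high_used=p_high)
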