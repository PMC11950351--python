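"""Wood-harvest HANPP: national roundwood statistics to gridded harvest.

Reported industrial-roundwood (IR) and wood-fuel (WF) volumes, by
coniferous/non-coniferous tree type, are expanded to whole-plant carbon
demand and allocated within each country over four harvestable pools —
closed forest and open wooded land (OWL) of either tree type — always
proportionally to actual NPP and never beyond 70% of a pool's NPP_act.
On woodlands actual NPP is taken equal to potential NPP (no conversion
flow), so 30% of NPP always remains in the ecosystem.

Demand that does not fit its primary pool cascades through a fixed
waterfall: WF assigned to a full closed forest moves to the OWL of the
same type; overflowing IR moves to the closed forest of the other type
(displacing WF there to that type's OWL), then to the OWL of its own
type; WF overflowing an OWL returns to closed forest of the same type,
then of the other type, then to the other type's OWL.  Whatever still
does not fit is reduced and logged — infeasibility is never an exception.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allocation import ReconciliationLog

__all__ = [
    "WoodFactors",
    "wood_demand_from_stats",
    "allocate_wood_country",
    "WoodAllocation",
]

TREE_TYPES = ("con", "ncon")
PRODUCTS = ("IR", "WF")
POOLS = [("FO", "con"), ("FO", "ncon"), ("OWL", "con"), ("OWL", "ncon")]


@dataclass(frozen=True)
class WoodFactors:
    """Volume → carbon expansion chain (configuration with defaults).

    demand = volume · wood density · carbon fraction · expansion, where
    the expansion covers bark, branches/foliage/roots and felling losses.
    """

    density: dict[str, float] = None  # t/m³ per tree type
    carbon_fraction: float = 0.5
    expansion: float = 2.0

    def __post_init__(self):
        if self.density is None:
            object.__setattr__(self, "density", {"con": 0.45, "ncon": 0.55})


def wood_demand_from_stats(fao_wood: pd.DataFrame, factors: WoodFactors = WoodFactors()) -> pd.DataFrame:
    """Expand reported volumes (m³, under bark) to carbon demand (tC/yr)."""
    if np.any(fao_wood["volume_m3"].to_numpy(dtype=float) < 0):
        raise ValueError("wood volumes must be non-negative")
    out = fao_wood.copy()
    dens = out["tree_type"].map(factors.density)
    if dens.isna().any():
        raise KeyError("missing wood density for a tree type")
    out["demand_tC"] = out["volume_m3"].astype(float) * dens * factors.carbon_fraction * factors.expansion
    return out


@dataclass
class WoodAllocation:
    """Per-pool allocation results for one country."""

    placed: dict[tuple[str, str], dict[tuple[str, str], float]]  # (product, type) -> pool -> tC
    reduced: dict[tuple[str, str], float]                        # (product, type) -> unallocated tC
    layers: dict[tuple[tuple[str, str], tuple[str, str]], np.ndarray]  # (pool, (product,type)) -> cell tC

    def pool_total(self, pool: tuple[str, str]) -> float:
        return sum(p.get(pool, 0.0) for p in self.placed.values())


def allocate_wood_country(
    demand: dict[tuple[str, str], float],
    npp_act: dict[tuple[str, str], np.ndarray],
    log: ReconciliationLog,
    cap: float = 0.7,
    country: int | None = None,
    year: int | None = None,
) -> WoodAllocation:
    """Run the waterfall for one country.

    ``demand`` maps (product, tree_type) to tC/yr; ``npp_act`` maps each
    pool (FO/OWL × con/ncon) to its per-cell NPP_act layer (tC/yr).
    """
    totals = {p: float(np.asarray(npp_act[p]).sum()) for p in POOLS}
    capacity = {p: cap * totals[p] for p in POOLS}
    free = dict(capacity)
    placed: dict[tuple[str, str], dict[tuple[str, str], float]] = {
        (prod, t): {} for prod in PRODUCTS for t in TREE_TYPES
    }

    def put(key, pool, amount) -> float:
        """Place up to `amount` of demand `key` into `pool`; return placed."""
        take = min(amount, free[pool])
        if take > 0:
            placed[key][pool] = placed[key].get(pool, 0.0) + take
            free[pool] -= take
        return take

    def evict_wf(pool) -> float:
        """Remove all WF currently in `pool`; return the evicted amount."""
        t = pool[1]
        amt = placed[("WF", t)].pop(pool, 0.0)
        free[pool] += amt
        return amt

    other = {"con": "ncon", "ncon": "con"}
    ir_left = {t: demand.get(("IR", t), 0.0) for t in TREE_TYPES}
    wf_left = {t: demand.get(("WF", t), 0.0) for t in TREE_TYPES}
    owl_assigned = {t: 0.0 for t in TREE_TYPES}  # WF waiting at OWL(t)

    # 1) IR into its own closed forest
    for t in TREE_TYPES:
        ir_left[t] -= put(("IR", t), ("FO", t), ir_left[t])

    # 2) WF split between closed forest and OWL proportionally to NPP_act;
    #    the closed-forest share that does not fit joins the OWL assignment
    for t in TREE_TYPES:
        tot = totals[("FO", t)] + totals[("OWL", t)]
        fo_share = wf_left[t] * (totals[("FO", t)] / tot) if tot > 0 else 0.0
        placed_fo = put(("WF", t), ("FO", t), fo_share)
        owl_assigned[t] += wf_left[t] - placed_fo
        wf_left[t] = 0.0

    # 3) IR overflow: other type's closed forest (evicting WF there to its
    #    OWL), then own-type OWL; residual reduced later
    for t in TREE_TYPES:
        if ir_left[t] <= 0:
            continue
        t2 = other[t]
        if ir_left[t] > free[("FO", t2)]:
            owl_assigned[t2] += evict_wf(("FO", t2))
        ir_left[t] -= put(("IR", t), ("FO", t2), ir_left[t])
        if ir_left[t] > 0:
            ir_left[t] -= put(("IR", t), ("OWL", t), ir_left[t])

    # 4) OWL assignments, overflow returning to closed forests then the
    #    other type's OWL
    for t in TREE_TYPES:
        amt = owl_assigned[t]
        amt -= put(("WF", t), ("OWL", t), amt)
        if amt > 0:
            amt -= put(("WF", t), ("FO", t), amt)
        if amt > 0:
            amt -= put(("WF", t), ("FO", other[t]), amt)
        if amt > 0:
            amt -= put(("WF", t), ("OWL", other[t]), amt)
        wf_left[t] = amt

    reduced = {}
    for t in TREE_TYPES:
        reduced[("IR", t)] = max(ir_left[t], 0.0)
        reduced[("WF", t)] = max(wf_left[t], 0.0)
        for prod in PRODUCTS:
            if reduced[(prod, t)] > 1e-9:
                log.add(country=country, year=year, stage="wood",
                        event="demand_reduced", product=prod, tree_type=t,
                        value=reduced[(prod, t)])

    # spread each pool's placed amounts over cells proportionally to NPP_act
    layers = {}
    for key, pools in placed.items():
        for pool, amt in pools.items():
            tot = totals[pool]
            if tot > 0 and amt > 0:
                layers[(pool, key)] = np.asarray(npp_act[pool]) * (amt / tot)
    return WoodAllocation(placed=placed, reduced=reduced, layers=layers)
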