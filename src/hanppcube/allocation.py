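"""Sequential closed-budget land-use allocation.

One year of the cube is built by filling each cell's land area in a fixed
priority order: built-up seed → national cropland → crop split →
unproductive wilderness → core/peripheral wilderness → national grazing →
closed-forest forestry → open wooded land → residual grazing.  Earlier
classes are never displaced by later ones; national census targets are met
exactly wherever suitability capacity suffices, and every shortfall or
reduction is logged, never silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import CountryPartition

__all__ = [
    "ReconciliationLog",
    "allocate_sequential",
    "allocate_builtup",
    "CropSplit",
    "split_cropland",
    "classify_wilderness",
    "allocate_grazing_forestry",
]


class ReconciliationLog:
    """Audit trail of every reconciliation, shortfall and reduction event."""

    def __init__(self) -> None:
        self.rows: list[dict] = []

    def add(self, **row) -> None:
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def events(self, event: str) -> list[dict]:
        return [r for r in self.rows if r.get("event") == event]


def _fill_by_proximity(
    stack: np.ndarray, remainder: float, seed_mask: np.ndarray
) -> np.ndarray:
    """Fill ``remainder`` area into ``stack`` cells by nondecreasing
    Euclidean distance (in cell units) to the nearest seed cell.

    Cells at equal distance form a shell and are filled proportionally to
    their stack area, which avoids scan-order artifacts; with no seed
    cells every cell is one shell (plain proportional fill).
    """
    alloc = np.zeros_like(stack)
    if remainder <= 0 or stack.sum() <= 0:
        return alloc
    if seed_mask.any():
        dist = ndimage.distance_transform_edt(~seed_mask)
    else:
        dist = np.zeros_like(stack)
    cells = stack > 0
    # iterate shells in distance order
    shell_dists = np.unique(dist[cells])
    left = remainder
    for d in shell_dists:
        shell = cells & (dist == d)
        cap = stack[shell].sum()
        if cap <= 0:
            continue
        if left >= cap:
            alloc[shell] = stack[shell]
            left -= cap
        else:
            alloc[shell] = stack[shell] * (left / cap)
            left = 0.0
            break
    return alloc


def allocate_sequential(
    target_area: float,
    stacks: list[np.ndarray],
    already_taken: list[np.ndarray] | None = None,
    proximity_seed_mask: np.ndarray | None = None,
) -> tuple[list[np.ndarray], float]:
    """Distribute a national target over ranked suitability stacks.

    If the target fits into suitability class 1, class-1 cells are used
    proportionally to their available area.  Otherwise class 1 is filled
    completely and the remainder is placed into class 2 (then class 3)
    cells in order of distance to the nearest class-1-bearing cell.

    Returns per-class allocation layers and the unplaced shortfall
    (zero when total capacity covers the target).
    """
    if target_area < 0:
        raise ValueError("target area must be non-negative")
    nets = []
    for k, s in enumerate(stacks):
        taken = already_taken[k] if already_taken is not None else 0.0
        net = np.asarray(s, dtype=float) - taken
        if np.any(net < -1e-9):
            raise ValueError("already_taken exceeds a stack")
        nets.append(np.clip(net, 0.0, None))

    allocs = [np.zeros_like(nets[0]) for _ in nets]
    s1 = nets[0]
    sum1 = s1.sum()
    if target_area <= sum1 or len(nets) == 1:
        if sum1 > 0:
            take = min(target_area, sum1)
            allocs[0] = s1 * (take / sum1)
            shortfall = target_area - take
        else:
            shortfall = target_area
        if len(nets) == 1 or target_area <= sum1:
            return allocs, float(max(shortfall, 0.0))
    # class 1 exhausted: fill it and spill outwards
    allocs[0] = s1.copy()
    left = target_area - sum1
    seed = proximity_seed_mask if proximity_seed_mask is not None else (s1 > 0)
    for k in range(1, len(nets)):
        if left <= 0:
            break
        allocs[k] = _fill_by_proximity(nets[k], left, seed)
        left -= allocs[k].sum()
    return allocs, float(max(left, 0.0))


def allocate_builtup(
    urban_area: np.ndarray, cropland: np.ndarray, transfer_share: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Built-up layer: urban cover plus a share of cropland transferred to
    account for dispersed settlement; the transfer leaves the cropland layer."""
    transfer = transfer_share * cropland
    return urban_area + transfer, cropland - transfer


# ---------------------------------------------------------------------------
# cropland split into crop classes


@dataclass
class CropSplit:
    """Per-crop harvested/physical areas plus fallow and fodder layers (km²)."""

    harvested: dict[str, np.ndarray]
    physical: dict[str, np.ndarray]
    multicropping: dict[str, np.ndarray]
    fodder: np.ndarray
    fallow: np.ndarray
    f_fao: dict[tuple[int, str], float] = field(default_factory=dict)
    fallow_min_fao: dict[int, float] = field(default_factory=dict)


def gap_fill_radius(values: np.ndarray, valid: np.ndarray, targets: np.ndarray,
                    radius: int = 30) -> np.ndarray:
    """Fill ``targets`` cells with the mean of nonzero donor cells within a
    circular neighbourhood of ``radius`` cells; zero where no donor exists."""
    out = values.copy()
    need = targets & ~valid
    if not need.any() or not valid.any():
        out[need] = 0.0
        return out
    rr, cc = np.nonzero(need)
    vr, vc = np.nonzero(valid)
    vvals = values[valid]
    for r, c in zip(rr, cc):
        d2 = (vr - r) ** 2 + (vc - c) ** 2
        close = d2 <= radius * radius
        out[r, c] = vvals[close].mean() if close.any() else 0.0
    return out


def split_cropland(
    cropland: np.ndarray,
    partition: CountryPartition,
    fao_land: pd.DataFrame,
    fao_crops: pd.DataFrame,
    spam_physical: dict[str, np.ndarray],
    spam_multicropping: dict[str, np.ndarray],
    log: ReconciliationLog,
    year: int | None = None,
    gap_radius: int = 30,
) -> CropSplit:
    """Split the cropland layer into crop-class harvested/physical areas.

    ``fao_land`` needs columns (country, cropland_km2); ``fao_crops``
    columns (country, crop, area_harvested_km2).  ``spam_physical`` and
    ``spam_multicropping`` are per-crop layers already interpolated to the
    year and resampled to the working grid; cells outside the cropland
    layer are ignored, cropland cells without crop-pattern information are
    gap-filled from donors within ``gap_radius`` cells.

    National harvested areas per crop match the census table exactly via a
    per-country-crop scaling factor wherever the pattern admits it; the
    residual cell area is split half/half into fodder production and true
    fallow.  The per-cell identity Σ physical + fallow + fodder = cropland
    holds exactly (inconsistent inputs are rescaled per cell and logged).
    """
    crops = sorted(spam_physical)
    shape = cropland.shape
    crop_mask = cropland > 0

    # adapt the pattern layers to this year's cropland mask
    phys_adj: dict[str, np.ndarray] = {}
    mc_adj: dict[str, np.ndarray] = {}
    any_valid = np.zeros(shape, dtype=bool)
    for c in crops:
        any_valid |= spam_physical[c] > 0
    for c in crops:
        v = np.where(crop_mask, spam_physical[c], 0.0)
        v = gap_fill_radius(v, any_valid & crop_mask, crop_mask, gap_radius)
        phys_adj[c] = np.where(crop_mask, v, 0.0)
        mc_adj[c] = np.where(spam_multicropping[c] >= 1, spam_multicropping[c], 0.0)

    total_phys = sum(phys_adj.values())
    with np.errstate(invalid="ignore", divide="ignore"):
        s_area = {c: np.where(total_phys > 0, phys_adj[c] / np.where(total_phys > 0, total_phys, 1.0), 0.0)
                  for c in crops}

    harvested = {c: np.zeros(shape) for c in crops}
    mc_filled = {c: np.ones(shape) for c in crops}
    f_fao: dict[tuple[int, str], float] = {}
    fallow_min: dict[int, float] = {}

    land = fao_land.set_index("country")
    global_mc_median = {
        c: float(np.median(mc_adj[c][mc_adj[c] >= 1])) if np.any(mc_adj[c] >= 1) else 1.0
        for c in crops
    }

    for cid in partition.ids:
        cmask = partition.mask(cid) & crop_mask
        cl_cell = np.where(cmask, cropland, 0.0)
        cl_sum = cl_cell.sum()
        if cid not in land.index:
            continue
        cl_fao = float(land.loc[cid, "cropland_km2"])
        rows = fao_crops[fao_crops["country"] == cid]
        harv_fao = {r["crop"]: float(r["area_harvested_km2"]) for _, r in rows.iterrows()}
        tot_harv = sum(harv_fao.values())
        fallow_min[cid] = max(cl_fao - tot_harv, 0.0)
        if cl_fao <= 0:
            if tot_harv > 0:
                log.add(country=int(cid), year=year, stage="crop_split",
                        event="reconciliation_error",
                        detail="harvested area reported with zero cropland",
                        value=tot_harv)
            continue
        ratio = tot_harv / cl_fao
        cl_harv = cl_cell * ratio  # area available for harvesting per cell

        for c, target in harv_fao.items():
            if target <= 0 or c not in s_area:
                continue
            base = cl_harv * s_area[c]
            base_sum = base.sum()
            if base_sum > 0:
                f = target / base_sum
                harvested[c] += base * f
                f_fao[(int(cid), c)] = f
            elif cl_sum > 0:
                # census-only crop: spread proportionally over all cropland cells
                harvested[c] += cl_cell * (target / cl_sum)
                f_fao[(int(cid), c)] = np.nan
                log.add(country=int(cid), year=year, stage="crop_split",
                        event="census_only_crop", crop=c, value=target)

        # multicropping: per-cell where present, country median fill, global fallback
        for c in crops:
            mc = mc_adj[c]
            have = cmask & (mc >= 1)
            fill = float(np.median(mc[have])) if have.any() else global_mc_median[c]
            mc_filled[c][cmask] = np.where(have[cmask], mc[cmask], fill)

    physical = {c: harvested[c] / mc_filled[c] for c in crops}
    total_physical = sum(physical.values())

    # enforce the per-cell budget: physical areas can never exceed cropland
    over = total_physical > cropland + 1e-12
    if np.any(over):
        scale = np.ones(shape)
        scale[over] = cropland[over] / total_physical[over]
        for c in crops:
            physical[c] *= scale
            harvested[c] *= scale
        log.add(country=None, year=year, stage="crop_split", event="cell_overflow_rescaled",
                value=float((total_physical - cropland)[over].sum()), cells=int(over.sum()))
        total_physical = sum(physical.values())

    fallow_area = np.clip(cropland - total_physical, 0.0, None)
    return CropSplit(
        harvested=harvested,
        physical=physical,
        multicropping=mc_filled,
        fodder=0.5 * fallow_area,
        fallow=0.5 * fallow_area,
        f_fao=f_fao,
        fallow_min_fao=fallow_min,
    )


# ---------------------------------------------------------------------------
# wilderness


def classify_wilderness(
    npp_pot: np.ndarray,
    footprint: np.ndarray,
    ifl_present: np.ndarray,
    forest_zone: np.ndarray,
    nps_threshold: float = 20.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cell masks (nps, core, periphery) for the three wilderness classes.

    Unproductive wilderness wherever potential productivity falls below
    the threshold (gC/m²/yr), regardless of footprint.  Elsewhere, inside
    the forest zone a cell is core if the human footprint is zero *and* an
    intact forest landscape is present, and periphery if exactly one of
    the two criteria holds; outside the forest zone footprint zero alone
    makes core.  Inputs are already interpolated to the target year.
    """
    if np.any(footprint < 0) or np.any(footprint > 50):
        raise ValueError("footprint values outside [0, 50]")
    nps = npp_pot < nps_threshold
    fz = forest_zone.astype(bool)
    fp0 = footprint == 0
    ifl = ifl_present.astype(bool)
    core = np.where(fz, fp0 & ifl, fp0) & ~nps
    peri = fz & (fp0 ^ ifl) & ~nps & ~core
    return nps, core, peri


# ---------------------------------------------------------------------------
# grazing land, open wooded land and forestry


def allocate_grazing_forestry(
    remaining: np.ndarray,
    graz_stacks: list[np.ndarray],
    crop_taken: list[np.ndarray],
    wild_periphery: np.ndarray,
    grazing_targets: dict[int, float],
    partition: CountryPartition,
    forest_con_stack: np.ndarray,
    forest_ncon_stack: np.ndarray,
    owl_con_stack: np.ndarray,
    owl_ncon_stack: np.ndarray,
    log: ReconciliationLog,
    year: int | None = None,
) -> dict[str, np.ndarray]:
    """Steps 6–9: grazing census targets, forestry, open wooded land, residual.

    ``remaining`` is the per-cell land area still unassigned after built-up,
    cropland and wilderness; ``crop_taken`` holds the cropland areas drawn
    from each grazing-overlapping suitability class (grazing suitability 1
    and 2 share source classes with cropland 1 and 2).  Returns the final
    GL/FO layers, the updated periphery, and the internal con/ncon split of
    GL-owl needed by the wood-harvest stage.
    """
    shape = remaining.shape
    gl_suit1 = np.zeros(shape)
    gl_rest = np.zeros(shape)  # grazing target met from suit 2/3 (drawn from `remaining`)
    gl_from_peri = np.zeros(shape)  # grazing target met by reclassified periphery
    peri = wild_periphery.copy()
    remaining = remaining.copy()

    for cid in partition.ids:
        m = partition.mask(cid)
        target = float(grazing_targets.get(int(cid), 0.0))
        # net stacks: subtract cropland drawn from the shared source classes,
        # and never exceed the still-unassigned land
        nets = []
        budget = np.where(m, remaining, 0.0)
        for k, s in enumerate(graz_stacks):
            taken = crop_taken[k] if k < len(crop_taken) else 0.0
            net = np.clip(np.where(m, s, 0.0) - taken, 0.0, None)
            net = np.minimum(net, budget)
            nets.append(net)
            budget = budget - net
        allocs, shortfall = allocate_sequential(target, nets)
        gl_suit1 += allocs[0]
        for a in allocs[1:]:
            gl_rest += a
        placed = float(sum(a.sum() for a in allocs))
        if shortfall > 1e-9:
            # reclassify peripheral wilderness, proportionally across cells
            peri_c = np.where(m, peri, 0.0)
            cap = peri_c.sum()
            take = min(shortfall, cap)
            if cap > 0:
                frac = take / cap
                gl_from_peri += peri_c * frac
                peri -= peri_c * frac
            if take < shortfall - 1e-9:
                log.add(country=int(cid), year=year, stage="grazing",
                        event="target_shortfall", value=float(shortfall - take))
            log.add(country=int(cid), year=year, stage="grazing",
                    event="periphery_reclassified", value=float(take))
        log.add(country=int(cid), year=year, stage="grazing", event="placed",
                target=target, value=float(placed))

    # only suit-stack grazing consumes `remaining`; periphery reclassification
    # moved area between already-assigned layers
    remaining = np.clip(remaining - gl_suit1 - gl_rest, 0.0, None)

    fo_con = np.minimum(forest_con_stack, remaining)
    remaining -= fo_con
    fo_ncon = np.minimum(forest_ncon_stack, remaining)
    remaining -= fo_ncon

    owl_con = np.minimum(owl_con_stack, remaining)
    remaining -= owl_con
    owl_ncon = np.minimum(owl_ncon_stack, remaining)
    remaining -= owl_ncon

    # residual unassigned land becomes other grazing land (open wooded class)
    residual = remaining.copy()

    gl_owl_con = owl_con
    gl_owl_ncon = owl_ncon + gl_rest + gl_from_peri + residual
    return {
        "GL-notrees": gl_suit1,
        "GL-owl": gl_owl_con + gl_owl_ncon,
        "GL-owl-con": gl_owl_con,
        "GL-owl-ncon": gl_owl_ncon,
        "FO-con": fo_con,
        "FO-ncon": fo_ncon,
        "WILD-periphery": peri,
    }
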