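"""HANPP flows on cropland and built-up land.

National crop production is converted to carbon harvest flows with
per-crop factor chains (moisture/carbon content times a by-product and
harvest-loss expansion), distributed within countries along the
crop-pattern production surface, and completed to actual NPP by a
pre-harvest-loss share.  Built-up land uses fixed fractions of the
potential NPP: one sixth harvested, two thirds lost to conversion, one
sixth remaining in the (green) urban ecosystem.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage

from .allocation import CropSplit, ReconciliationLog
from .grid import CountryPartition

__all__ = [
    "CropFactorTable",
    "load_default_crop_factors",
    "national_crop_hanpp_harv",
    "distribute_crop_harvest",
    "cropland_npp_act",
    "builtup_hanpp",
]


@dataclass
class CropFactorTable:
    """Per-crop conversion factors.

    ``carbon_per_t``: tC per tonne fresh production; ``expansion`` ≥ 1 for
    by-products and harvest losses; ``preharvest_share`` ∈ [0, 1): share of
    actual NPP lost before harvest.
    """

    frame: pd.DataFrame  # index: crop class

    def __post_init__(self) -> None:
        if np.any(self.frame["expansion"].to_numpy() < 1):
            raise ValueError("expansion factors must be >= 1")
        sh = self.frame["preharvest_share"].to_numpy()
        if np.any(sh < 0) or np.any(sh >= 1):
            raise ValueError("preharvest_share must lie in [0, 1)")

    def row(self, crop: str) -> pd.Series:
        if crop not in self.frame.index:
            raise KeyError(f"no factors configured for crop {crop!r}")
        return self.frame.loc[crop]


def load_default_crop_factors() -> CropFactorTable:
    with resources.as_file(resources.files("hanppcube.data") / "crop_factors.csv") as p:
        return CropFactorTable(pd.read_csv(p, comment="#", index_col="crop"))


def national_crop_hanpp_harv(
    fao_production: pd.DataFrame, factors: CropFactorTable
) -> pd.DataFrame:
    """National carbon harvest per crop: production × carbon × expansion.

    ``fao_production`` needs columns (country, crop, production_t); returns
    the same keys plus ``hanpp_harv_tC``.
    """
    if np.any(fao_production["production_t"].to_numpy(dtype=float) < 0):
        raise ValueError("production must be non-negative")
    out = fao_production.copy()
    vals = []
    for _, r in out.iterrows():
        f = factors.row(r["crop"])
        vals.append(float(r["production_t"]) * float(f["carbon_per_t"]) * float(f["expansion"]))
    out["hanpp_harv_tC"] = vals
    return out


def distribute_crop_harvest(
    national: pd.DataFrame,
    split: CropSplit,
    spam_yield: dict[str, np.ndarray],
    partition: CountryPartition,
    log: ReconciliationLog,
    smooth_radius: int = 0,
    year: int | None = None,
) -> dict[str, np.ndarray]:
    """Distribute national carbon harvest per crop to the grid (tC/yr).

    The within-country pattern is the production surface: harvested area ×
    yield.  Cropland cells the yield pattern does not cover get 80% of the
    country's 5th-percentile yield for that crop (a reduced yield even
    when a single yield level covers the country); countries absent from
    the pattern entirely use the global median yield.  A moving-average
    pass blurs the coarse pattern edges, and a final per-country rescaling
    restores the national totals exactly.  The fodder class is distributed
    proportionally to the fodder area layer.
    """
    out: dict[str, np.ndarray] = {}
    shape = split.fodder.shape
    global_median = {
        c: float(np.median(y[y > 0])) if np.any(y > 0) else 0.0
        for c, y in spam_yield.items()
    }
    for _, r in national.iterrows():
        crop, cid, tot = r["crop"], int(r["country"]), float(r["hanpp_harv_tC"])
        if tot <= 0:
            continue
        layer = out.setdefault(crop, np.zeros(shape))
        m = partition.mask(cid)
        if crop == "CL-FODD":
            pattern = np.where(m, split.fodder, 0.0)
        else:
            harv_area = np.where(m, split.harvested.get(crop, np.zeros(shape)), 0.0)
            yld = np.where(m, spam_yield.get(crop, np.zeros(shape)), 0.0)
            covered = yld > 0
            cells = harv_area > 0
            if not np.any(covered & cells):
                fill_yld = global_median.get(crop, 0.0)
                yld = np.where(cells, fill_yld, 0.0)
            else:
                p5 = float(np.percentile(yld[covered & cells], 5))
                yld = np.where(cells & ~covered, 0.8 * p5, yld)
            pattern = harv_area * yld
        psum = pattern.sum()
        if psum <= 0:
            # no pattern at all: uniform fallback over the country's cropland
            cl = np.where(m, split.fallow + split.fodder + sum(split.physical.values()), 0.0)
            psum = cl.sum()
            if psum <= 0:
                log.add(country=cid, year=year, stage="crop_harvest",
                        event="undistributable_harvest", crop=crop, value=tot)
                continue
            pattern = cl
            log.add(country=cid, year=year, stage="crop_harvest",
                    event="uniform_fallback", crop=crop, value=tot)
        alloc = pattern * (tot / psum)
        if smooth_radius > 0:
            sm = ndimage.uniform_filter(alloc, size=2 * smooth_radius + 1, mode="constant")
            sm = np.where(m & (pattern >= 0), sm, 0.0)
            sm = np.where(m, sm, 0.0)
            if sm.sum() > 0:
                alloc = sm * (tot / sm.sum())
        layer += alloc
    return out


def cropland_npp_act(
    hanpp_harv: dict[str, np.ndarray],
    factors: CropFactorTable,
    npp_pot_density: np.ndarray,
    class_areas: dict[str, np.ndarray],
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Actual NPP and land-conversion flow per crop class (tC/yr).

    NPP_act = HANPP_harv / (1 − pre-harvest share); HANPP_luc is the
    difference to the potential NPP on the class's area and may be
    negative where inputs push cropland NPP above potential.
    """
    npp_act: dict[str, np.ndarray] = {}
    hanpp_luc: dict[str, np.ndarray] = {}
    for crop, harv in hanpp_harv.items():
        share = float(factors.row(crop)["preharvest_share"])
        act = harv / (1.0 - share)
        pot = npp_pot_density * class_areas.get(crop, np.zeros_like(harv))
        npp_act[crop] = act
        hanpp_luc[crop] = pot - act
    return npp_act, hanpp_luc


def builtup_hanpp(npp_pot_on_builtup: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Built-up flows: (HANPP_harv, HANPP_luc, NPP_eco) = (1/6, 2/3, 1/6) · NPP_pot."""
    pot = np.asarray(npp_pot_on_builtup, dtype=float)
    harv = pot / 6.0
    luc = pot * (2.0 / 3.0)
    eco = pot - luc - harv
    return harv, luc, eco
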