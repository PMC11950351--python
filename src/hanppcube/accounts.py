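"""HANPP identity assembly, aggregation, trend classification and output.

The accounting identities tie the four flows together on every unit:

    NPP_act = NPP_eco + HANPP_harv
    NPP_pot = NPP_act + HANPP_luc
    HANPP   = HANPP_harv + HANPP_luc = NPP_pot − NPP_eco

Aggregation always sums flow components and recomputes ratios — a HANPP
percentage is never averaged.  Woodland conversion flows and all
wilderness flows are zero by definition; wilderness keeps its entire
potential NPP in the ecosystem.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .classes import ALL_CLASSES, LU_TYPE, LU_TYPES, NO_HARVEST_CLASSES, ZERO_LUC_CLASSES
from .grid import CountryPartition
from .raster import read_layer, write_layer

__all__ = [
    "HanppAccount",
    "assemble_accounts",
    "aggregate_accounts",
    "hanpp_pct",
    "classify_trend",
    "TrendClass",
    "write_cube",
    "read_cube_year",
    "regional_table",
    "load_published_accounts",
]

FLOW_LAYERS = ("area_km2", "NPPeco_tC", "HANPPluc_tC", "HANPPharv_tC")


@dataclass
class HanppAccount:
    """Flow table per (unit, class): columns NPP_pot, NPP_act, NPP_eco,
    HANPP_harv, HANPP_luc, HANPP, area."""

    frame: pd.DataFrame


def assemble_accounts(
    class_layers: dict[str, dict[str, np.ndarray]],
    partition: CountryPartition | None = None,
    rtol: float = 1e-6,
) -> HanppAccount:
    """Build per-class (and per-country) accounts from cell-level layers.

    ``class_layers`` maps class name → {area, npp_eco, hanpp_harv,
    hanpp_luc} cell layers (km² and tC/yr).  The three identities are
    enforced by construction and re-checked; a violation beyond ``rtol``
    relative is a hard failure naming the class.
    """
    rows = []
    for cls, layers in class_layers.items():
        eco = np.asarray(layers["npp_eco"], float)
        harv = np.asarray(layers["hanpp_harv"], float)
        luc = np.asarray(layers["hanpp_luc"], float)
        area = np.asarray(layers["area"], float)
        if cls in NO_HARVEST_CLASSES and np.any(np.abs(harv) > 0):
            raise ValueError(f"harvest flow on no-harvest class {cls}")
        if cls in ZERO_LUC_CLASSES and np.any(np.abs(luc) > 0):
            raise ValueError(f"conversion flow on zero-luc class {cls}")
        act = eco + harv
        pot = act + luc
        scale = max(np.abs(pot).sum(), 1.0)
        resid = np.abs(pot - (eco + harv + luc)).sum()
        if resid > rtol * scale:
            raise ValueError(f"identity violation on class {cls}: residual {resid}")
        units = {"": None}
        if partition is not None:
            units = {int(c): partition.mask(int(c)) for c in partition.ids}
        for unit, mask in units.items():
            sel = (slice(None) if mask is None else mask)
            rows.append({
                "unit": unit if unit != "" else "grid",
                "class": cls,
                "lu_type": LU_TYPE[cls] if cls in LU_TYPE else "other",
                "area": float(area[sel].sum()),
                "NPP_pot": float(pot[sel].sum()),
                "NPP_act": float(act[sel].sum()),
                "NPP_eco": float(eco[sel].sum()),
                "HANPP_harv": float(harv[sel].sum()),
                "HANPP_luc": float(luc[sel].sum()),
            })
    frame = pd.DataFrame(rows)
    frame["HANPP"] = frame["HANPP_harv"] + frame["HANPP_luc"]
    return HanppAccount(frame=frame)


def aggregate_accounts(account: HanppAccount, by: str = "lu_type") -> pd.DataFrame:
    """Sum flows over classes (per unit) and recompute HANPP ratios."""
    cols = ["area", "NPP_pot", "NPP_act", "NPP_eco", "HANPP_harv", "HANPP_luc", "HANPP"]
    g = account.frame.groupby(["unit", by])[cols].sum().reset_index()
    g["HANPP_pct"] = hanpp_pct(g["HANPP"].to_numpy(), g["NPP_pot"].to_numpy())
    return g


def hanpp_pct(hanpp, npp_pot):
    """HANPP as percent of NPP_pot; NaN flags an undefined ratio (pot = 0)."""
    h = np.asarray(hanpp, dtype=float)
    p = np.asarray(npp_pot, dtype=float)
    if np.any(p < 0):
        raise ValueError("NPP_pot must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(p > 0, 100.0 * h / np.where(p > 0, p, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


@dataclass
class TrendClass:
    slope: np.ndarray      # robust %/yr per cell
    trend: np.ndarray      # -1 decreasing / 0 no trend / +1 increasing
    level: np.ndarray      # tertile (1..3) of the first-year distribution; 0 = undefined


def theil_sen_slope(series: np.ndarray, years: np.ndarray) -> float:
    """Median of all pairwise slopes (robust trend)."""
    slope, _, _, _ = stats.theilslopes(series, years)
    return float(slope)


def classify_trend(
    pct_series: np.ndarray,
    years: np.ndarray,
    threshold: float = 0.1,
) -> TrendClass:
    """Classify HANPP% level and trend per cell.

    ``pct_series`` has shape (n_years, ...); the trend is the Theil–Sen
    slope with ±``threshold`` %/yr class boundaries, the level the
    tertile of the first year's distribution over valid cells.
    """
    arr = np.asarray(pct_series, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least two yearly values")
    years = np.asarray(years, dtype=float)
    flat = arr.reshape(arr.shape[0], -1)
    valid = ~np.isnan(flat).any(axis=0)
    slopes = np.full(flat.shape[1], np.nan)
    for j in np.nonzero(valid)[0]:
        slopes[j] = theil_sen_slope(flat[:, j], years)
    trend = np.zeros(flat.shape[1], dtype=int)
    trend[slopes < -threshold] = -1
    trend[slopes > threshold] = 1

    first = flat[0]
    level = np.zeros(flat.shape[1], dtype=int)
    ok = ~np.isnan(first)
    if ok.any():
        t1, t2 = np.nanquantile(first[ok], [1 / 3, 2 / 3])
        level[ok] = 1 + (first[ok] > t1).astype(int) + (first[ok] > t2).astype(int)
    shape = arr.shape[1:]
    return TrendClass(slope=slopes.reshape(shape), trend=trend.reshape(shape),
                      level=level.reshape(shape))


def write_cube(
    cube_layers: dict[int, dict[str, dict[str, np.ndarray]]],
    out_dir,
    overwrite: bool = False,
) -> list[Path]:
    """Write one TIFF per year × data layer × class.

    ``cube_layers``: year → class → {area, npp_eco, hanpp_harv, hanpp_luc}.
    Files are grouped in per-class folders and named
    ``{year}{layer}_{class}.tif``; no-harvest classes omit the harvest
    layer and zero-conversion classes write their (zero) conversion layer.
    """
    out_dir = Path(out_dir)
    written = []
    mapping = {"area_km2": "area", "NPPeco_tC": "npp_eco",
               "HANPPluc_tC": "hanpp_luc", "HANPPharv_tC": "hanpp_harv"}
    for year, classes in cube_layers.items():
        for cls, layers in classes.items():
            for fname, key in mapping.items():
                if fname == "HANPPharv_tC" and cls in NO_HARVEST_CLASSES:
                    continue
                path = out_dir / cls / f"{year}{fname}_{cls}.tif"
                written.append(write_layer(path, layers[key], overwrite=overwrite))
    return written


def read_cube_year(out_dir, year: int, classes=ALL_CLASSES) -> dict[str, dict[str, np.ndarray]]:
    out_dir = Path(out_dir)
    mapping = {"area_km2": "area", "NPPeco_tC": "npp_eco",
               "HANPPluc_tC": "hanpp_luc", "HANPPharv_tC": "hanpp_harv"}
    out: dict[str, dict[str, np.ndarray]] = {}
    for cls in classes:
        layers = {}
        for fname, key in mapping.items():
            path = out_dir / cls / f"{year}{fname}_{cls}.tif"
            if path.exists():
                layers[key], _ = read_layer(path)
            elif fname == "HANPPharv_tC":
                layers[key] = np.zeros_like(layers["area"])
        if layers:
            out[cls] = layers
    return out


def regional_table(account: HanppAccount, region_of_unit: dict[int, str]) -> pd.DataFrame:
    """Region × land-use-type accounts in the published layout.

    Rows: area (Mkm²), NPP_pot, HANPP_harv, HANPP_luc, HANPP (MtC/yr) and
    HANPP% (integer-rounded, computed from the summed components);
    columns: the four used land-use types plus the wilderness-inclusive
    total.
    """
    f = account.frame.copy()
    f = f[f["unit"] != "grid"]
    f["region"] = f["unit"].map(region_of_unit)
    rows = []
    for region, sub in f.groupby("region"):
        for lu in LU_TYPES + ["Total"]:
            s = sub if lu == "Total" else sub[sub["lu_type"] == lu]
            if lu == "Wilderness":
                continue
            rec = {
                "region": region, "lu_type": lu,
                "area_Mkm2": s["area"].sum() / 1e6,
                "npp_pot": s["NPP_pot"].sum() / 1e6,
                "hanpp_harv": s["HANPP_harv"].sum() / 1e6,
                "hanpp_luc": s["HANPP_luc"].sum() / 1e6,
                "hanpp": s["HANPP"].sum() / 1e6,
            }
            pct = hanpp_pct(rec["hanpp"], max(rec["npp_pot"], 0.0)) if rec["npp_pot"] > 0 else np.nan
            rec["hanpp_pct"] = int(round(pct)) if np.isfinite(pct) else np.nan
            rows.append(rec)
    return pd.DataFrame(rows)


def load_published_accounts() -> pd.DataFrame:
    """The packaged published 2020 global/regional accounts table."""
    with resources.as_file(resources.files("hanppcube.data") / "regional_accounts_2020.csv") as p:
        return pd.read_csv(p, comment="#")
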