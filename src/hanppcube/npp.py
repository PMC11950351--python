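"""Potential-NPP reference surface: empirical climate model, dasymetric
downscaling of coarse model output, and time-series smoothing.

The potential NPP (NPP_pot, gC/m²/yr) is the reference point of the HANPP
framework: the productivity that would prevail without land use under the
current climate.  Coarse model output is brought to the working grid by
scaling a fine-resolution climate-driven pattern (the MIAMI model, the
minimum of a temperature- and a precipitation-limited response) so that
the NPP total of every ecoregion matches the coarse input exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MiamiParams", "miami_npp", "downscale", "smooth_series"]


@dataclass(frozen=True)
class MiamiParams:
    """Coefficients of the empirical climate-NPP curves.

    NPP_T = asymptote / (1 + exp(t_a − t_b·T)),  NPP_P = asymptote·(1 − exp(−p_k·P)),
    both in g dry matter/m²/yr; the minimum of the two is converted to
    carbon with ``carbon_per_dm`` (gC per g dry matter).
    """

    asymptote: float = 3000.0
    t_a: float = 1.315
    t_b: float = 0.119
    p_k: float = 0.000664
    carbon_per_dm: float = 0.5


def miami_npp(
    temperature: np.ndarray | float,
    precipitation: np.ndarray | float,
    params: MiamiParams = MiamiParams(),
) -> np.ndarray | float:
    """Climate-limited NPP (gC/m²/yr) from temperature (°C) and precipitation (mm/yr)."""
    t = np.asarray(temperature, dtype=float)
    p = np.asarray(precipitation, dtype=float)
    npp_t = params.asymptote / (1.0 + np.exp(params.t_a - params.t_b * t))
    npp_p = params.asymptote * (1.0 - np.exp(-params.p_k * p))
    out = np.minimum(npp_t, npp_p) * params.carbon_per_dm
    return float(out) if out.ndim == 0 else out


def downscale(
    coarse_npp: np.ndarray,
    miami_fine_pattern: np.ndarray,
    ecoregion_map: np.ndarray,
    coarse_cell_area: np.ndarray,
    fine_cell_area: np.ndarray,
    factor: int,
) -> np.ndarray:
    """Downscale a coarse NPP density field to the fine grid.

    Fine values are proportional to the climate pattern within each
    ecoregion and rescaled so the ecoregion NPP total (density × area)
    matches the coarse field; where a whole ecoregion's pattern is zero
    the coarse total is spread uniformly over its area.

    Parameters are densities (gC/m²/yr) and areas (km²); ``ecoregion_map``
    is an integer label per fine cell; the coarse grid must nest the fine
    grid with block size ``factor``.
    """
    coarse_npp = np.asarray(coarse_npp, dtype=float)
    pattern = np.asarray(miami_fine_pattern, dtype=float)
    nr, nc = pattern.shape
    if coarse_npp.shape != (nr // factor, nc // factor) or nr % factor or nc % factor:
        raise ValueError("coarse grid does not nest the fine grid")
    # per-fine-cell total from the coarse field (each fine cell inherits
    # its block's density; totals use the fine cell areas)
    coarse_density_on_fine = np.repeat(np.repeat(coarse_npp, factor, axis=0), factor, axis=1)
    target_total = coarse_density_on_fine * fine_cell_area  # tC/yr per fine cell
    pattern_total = pattern * fine_cell_area

    out = np.zeros_like(pattern)
    for eco in np.unique(ecoregion_map):
        m = ecoregion_map == eco
        if not np.any(m):
            continue
        t_sum = target_total[m].sum()
        p_sum = pattern_total[m].sum()
        if p_sum > 0:
            out[m] = pattern[m] * (t_sum / p_sum)
        else:
            a_sum = fine_cell_area[m].sum()
            out[m] = t_sum / a_sum if a_sum > 0 else 0.0
    return out


def smooth_series(npp_years: np.ndarray, window: int = 5) -> np.ndarray:
    """Clamp negatives to zero, then centred moving average over years.

    ``npp_years`` has the year axis first; windows shrink symmetrically at
    the series edges (a centred window truncated to the available years).
    """
    arr = np.clip(np.asarray(npp_years, dtype=float), 0.0, None)
    n = arr.shape[0]
    half = window // 2
    out = np.empty_like(arr)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = arr[lo:hi].mean(axis=0)
    return out
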