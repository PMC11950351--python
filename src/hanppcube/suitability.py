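"""Land-cover to land-use suitability: fractional cover → per-cell available areas.

The correspondence between land-cover classes and land-use types is a CSV
asset (``data/suitability_esa.csv``) giving, per cover class, the share of
its area available to each of eleven land-use columns: built-up seed,
cropland suitability 1–3, grazing suitability 1–3, closed forest
(coniferous / non-coniferous) and open wooded land (con / ncon).  Cropland
and grazing suitability 1–2 deliberately overlap the same source classes;
overlapping claims are resolved downstream by the sequential allocation
order, never by renormalising this table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .grid import CellAreaField

__all__ = [
    "STACK_COLUMNS",
    "SuitabilityTable",
    "SuitabilityStacks",
    "load_default_table",
    "resample_cover",
    "cover_to_suitability",
]

STACK_COLUMNS = [
    "builtup",
    "crop1", "crop2", "crop3",
    "graz1", "graz2", "graz3",
    "forest_con", "forest_ncon",
    "owl_con", "owl_ncon",
]


@dataclass
class SuitabilityTable:
    """Share (%) of each cover class available to each land-use column."""

    frame: pd.DataFrame  # index: cover class code; columns: STACK_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in STACK_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"suitability table missing columns {missing}")
        vals = self.frame[STACK_COLUMNS].to_numpy(dtype=float)
        if np.any(vals < 0) or np.any(vals > 100):
            raise ValueError("suitability shares must lie in [0, 100]")
        closed = self.frame["forest_con"] + self.frame["forest_ncon"]
        if np.any(closed.to_numpy() > 100 + 1e-9):
            raise ValueError("closed-forest shares exceed 100% within a class")

    def share(self, code: int, column: str) -> float:
        return float(self.frame.loc[code, column])

    @classmethod
    def from_csv(cls, path) -> "SuitabilityTable":
        frame = pd.read_csv(path, comment="#", index_col="code")
        return cls(frame=frame)


def load_default_table() -> SuitabilityTable:
    """The packaged cover/land-use correspondence table."""
    with resources.as_file(resources.files("hanppcube.data") / "suitability_esa.csv") as p:
        return SuitabilityTable.from_csv(p)


@dataclass
class SuitabilityStacks:
    """Per-cell area (km²) available to each land-use column."""

    stacks: dict[str, np.ndarray]

    def __getitem__(self, column: str) -> np.ndarray:
        return self.stacks[column]


def resample_cover(fine_cover: dict[int, np.ndarray], factor: int) -> dict[int, np.ndarray]:
    """Aggregate fractional cover to a ``factor``× coarser grid.

    The coarse fraction is the plain mean of the ``factor²`` nested fine
    cells (cells within a block are treated as equal-area, adequate at the
    block sizes used here); per-cell fractions still sum to one.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    out: dict[int, np.ndarray] = {}
    for code, frac in fine_cover.items():
        frac = np.asarray(frac, dtype=float)
        nr, nc = frac.shape
        if nr % factor or nc % factor:
            raise ValueError("fine grid does not nest the target grid")
        out[code] = frac.reshape(nr // factor, factor, nc // factor, factor).mean(axis=(1, 3))
    return out


def cover_to_suitability(
    cover_fractions: dict[int, np.ndarray],
    table: SuitabilityTable,
    area: CellAreaField,
) -> SuitabilityStacks:
    """Turn fractional cover into per-cell available areas per land-use column.

    stack(col) = Σ_class fraction(class) · share(class, col)/100 · area_total.

    Fractions are shares of the *total* cell area (the water class carries
    zero shares), so this equals the land-normalised fraction times the
    land area: stacks can never exceed ``area_land`` while per-column
    shares stay ≤ 100 and fractions sum to one.
    """
    shape = area.area_land.shape
    stacks = {col: np.zeros(shape) for col in STACK_COLUMNS}
    for code, frac in cover_fractions.items():
        if code not in table.frame.index:
            raise KeyError(f"cover class {code} missing from suitability table")
        frac = np.asarray(frac, dtype=float)
        if np.any(frac < -1e-12) or np.any(frac > 1 + 1e-9):
            raise ValueError(f"cover fraction for class {code} outside [0, 1]")
        for col in STACK_COLUMNS:
            share = table.share(code, col)
            if share:
                stacks[col] += frac * (share / 100.0) * area.area_total
    return SuitabilityStacks(stacks=stacks)
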