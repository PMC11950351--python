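"""Grid geometry, cell areas, country partition and closed-budget arithmetic.

All layers in the package share a single regular latitude/longitude grid
(row 0 northernmost, 0-based row-major indexing, half-open cell intervals
in degrees).  Cell areas are computed on a sphere of configurable radius:
the area of a cell is the spherical band between its bounding parallels
divided by the number of cells a full circle of longitude would hold, so
the full-planet grid sums exactly to ``4 * pi * R**2``.

The unit convention used throughout the package is km² for areas and
gC/m²/yr for NPP densities; their product is tC/yr
(1 gC/m²/yr over 1 km² = 10⁶ gC/yr = 1 tC/yr).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AUTHALIC_RADIUS_KM",
    "GridSpec",
    "CellAreaField",
    "CountryPartition",
    "cell_area",
    "cell_area_column",
    "land_area",
    "closed_budget_check",
]

#: Authalic (equal-area) Earth radius in km.
AUTHALIC_RADIUS_KM = 6371.0072


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular geographic grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; row 0 is the northernmost row.
    cell_size
        Cell edge length in degrees (cells are square in degrees).
    origin_lat, origin_lon
        Latitude/longitude of the top-left corner of cell (0, 0).
    planet_radius
        Sphere radius in km used for all area computations.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_lat: float = 90.0
    origin_lon: float = -180.0
    planet_radius: float = AUTHALIC_RADIUS_KM

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid shape must be positive")
        if self.n_rows * self.cell_size > 180.0 + 1e-9:
            raise ValueError("grid extends beyond 180 degrees of latitude")
        if self.origin_lat > 90.0 + 1e-9 or self.origin_lat - self.n_rows * self.cell_size < -90.0 - 1e-9:
            raise ValueError("grid extends beyond the poles")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def row_lat_bounds(self, row: int) -> tuple[float, float]:
        """(north, south) latitude bounds of a row."""
        north = self.origin_lat - row * self.cell_size
        return north, north - self.cell_size

    def coarsen(self, factor: int) -> "GridSpec":
        """Spec of a grid `factor`× coarser covering the same extent."""
        if self.n_rows % factor or self.n_cols % factor:
            raise ValueError("factor does not divide the grid shape")
        return GridSpec(
            self.n_rows // factor,
            self.n_cols // factor,
            self.cell_size * factor,
            self.origin_lat,
            self.origin_lon,
            self.planet_radius,
        )


def cell_area(row_index: int, grid_spec: GridSpec) -> float:
    """Total area (km²) of a cell in the given row.

    The spherical band between the row's bounding parallels is divided by
    the number of cells in a full 360° circle of longitude, so areas depend
    only on latitude and the full grid closes to the sphere's area.
    """
    if not 0 <= row_index < grid_spec.n_rows:
        raise IndexError(f"row {row_index} outside grid with {grid_spec.n_rows} rows")
    north, south = grid_spec.row_lat_bounds(row_index)
    r = grid_spec.planet_radius
    band = 2.0 * np.pi * r * r * (np.sin(np.deg2rad(north)) - np.sin(np.deg2rad(south)))
    return float(band * grid_spec.cell_size / 360.0)


def cell_area_column(grid_spec: GridSpec) -> np.ndarray:
    """Vector of per-row cell areas (km²), length ``n_rows``."""
    rows = np.arange(grid_spec.n_rows)
    north = grid_spec.origin_lat - rows * grid_spec.cell_size
    south = north - grid_spec.cell_size
    r = grid_spec.planet_radius
    band = 2.0 * np.pi * r * r * (np.sin(np.deg2rad(north)) - np.sin(np.deg2rad(south)))
    return band * grid_spec.cell_size / 360.0


@dataclass
class CellAreaField:
    """Per-cell total and land areas in km²."""

    area_total: np.ndarray
    area_land: np.ndarray

    def __post_init__(self) -> None:
        if self.area_total.shape != self.area_land.shape:
            raise ValueError("area_total and area_land shapes differ")
        if np.any(self.area_land < -1e-12) or np.any(self.area_land > self.area_total + 1e-9):
            raise ValueError("area_land must lie in [0, area_total]")


@dataclass
class CountryPartition:
    """Integer country id per cell (0 = ocean / no country) plus region labels."""

    country_id: np.ndarray
    region_map: dict[int, str] = field(default_factory=dict)

    @property
    def ids(self) -> np.ndarray:
        out = np.unique(self.country_id)
        return out[out > 0]

    def mask(self, cid: int) -> np.ndarray:
        return self.country_id == cid

    def validate(self, area: CellAreaField) -> None:
        bad = (area.area_land > 0) & (self.country_id <= 0)
        if np.any(bad):
            raise ValueError(f"{int(bad.sum())} land cells without a country id")


def land_area(water_fraction: np.ndarray, grid_spec: GridSpec) -> CellAreaField:
    """Land area per cell: total cell area minus the water-body share."""
    wf = np.asarray(water_fraction, dtype=float)
    if wf.shape != grid_spec.shape:
        raise ValueError("water fraction shape does not match grid")
    if np.any(wf < -1e-12) or np.any(wf > 1 + 1e-12):
        raise ValueError("water fraction outside [0, 1]")
    wf = np.clip(wf, 0.0, 1.0)
    total = np.broadcast_to(cell_area_column(grid_spec)[:, None], grid_spec.shape).copy()
    return CellAreaField(area_total=total, area_land=total * (1.0 - wf))


def closed_budget_check(
    layers: dict[str, np.ndarray],
    area: CellAreaField,
    tolerance: float = 1e-6,
) -> list[tuple[int, int, float]]:
    """Verify that land-use class areas close the per-cell land budget.

    Returns the (row, col, residual_km²) triples where
    ``|sum(layers) - area_land|`` exceeds ``tolerance``; an empty list
    means the budget closes everywhere.
    """
    if not layers:
        raise ValueError("no class layers supplied")
    total = np.zeros_like(area.area_land)
    for name, layer in layers.items():
        if layer is None or np.asarray(layer).shape != area.area_land.shape:
            raise ValueError(f"class layer {name!r} missing or mis-shaped")
        total = total + layer
    resid = total - area.area_land
    bad = np.abs(resid) > tolerance
    rows, cols = np.nonzero(bad)
    return [(int(r), int(c), float(resid[r, c])) for r, c in zip(rows, cols)]
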