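"""Sea-ice concentration around a point: radius queries and presence overlay.

Gridded ice-concentration fields (percent per cell, cells of a few km) are
queried for the mean concentration within a great-circle radius of the
observatory; the complement is the open-water percentage.  Daily queries are
then joined onto the acoustic presence series so that call activity can be
read against local ice conditions (e.g. calls on days with >90% ice cover).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_KM",
    "IceGrid",
    "RadiusQuery",
    "IceCoverResult",
    "haversine_km",
    "cover_within_radius",
    "ice_presence_overlay",
    "write_grid_csv",
    "read_grid_csv",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class IceGrid:
    """One dated concentration field.

    ``concentration`` holds percent ice cover per cell in [0, 100], NaN for
    missing cells; ``cell_lat``/``cell_lon`` give each cell's centre in
    degrees; ``cell_size_km`` is the nominal cell edge length.
    """

    concentration: np.ndarray
    cell_lat: np.ndarray
    cell_lon: np.ndarray
    cell_size_km: float
    date: date

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=np.float64)
        self.cell_lat = np.asarray(self.cell_lat, dtype=np.float64)
        self.cell_lon = np.asarray(self.cell_lon, dtype=np.float64)
        if not (self.concentration.shape == self.cell_lat.shape == self.cell_lon.shape):
            raise ValueError("concentration, cell_lat, cell_lon shapes must match")
        c = self.concentration
        valid = c[~np.isnan(c)]
        if valid.size and (valid.min() < 0 or valid.max() > 100):
            raise ValueError("concentrations must lie in [0, 100] or be NaN")


@dataclass(frozen=True)
class RadiusQuery:
    """Great-circle disc around a point (degrees, km)."""

    center_lat: float
    center_lon: float
    radius_km: float

    def __post_init__(self) -> None:
        if not self.radius_km > 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class IceCoverResult:
    ice_percent: float
    open_water_percent: float
    n_cells: int


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km on a spherical Earth (radius 6371 km)."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = la2 - la1
    dlon = lo2 - lo1
    h = np.sin(dlat / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def cover_within_radius(
    grid: IceGrid, query: RadiusQuery, cos_lat_weights: bool = False
) -> IceCoverResult:
    """Mean ice concentration over cells whose centres fall inside the disc.

    Cell membership is decided by the cell-centre distance; with ~6 km cells
    and a 100 km radius the boundary discretization moves the result by well
    under a percent.  Missing cells are excluded from numerator and
    denominator.  ``cos_lat_weights`` applies cos(latitude) area weights for
    plain lat/lon grids whose cells shrink toward the pole; the default is
    equal weights, appropriate for near-equal-area products.
    """
    d = haversine_km(grid.cell_lat, grid.cell_lon, query.center_lat, query.center_lon)
    inside = d <= query.radius_km
    if not inside.any():
        raise ValueError(f"no grid cells within {query.radius_km} km of the query point")
    conc = grid.concentration[inside]
    w = np.cos(np.radians(grid.cell_lat[inside])) if cos_lat_weights else np.ones(conc.size)
    ok = ~np.isnan(conc)
    if not ok.any():
        raise ValueError("all cells within the radius are missing")
    ice = float(np.average(conc[ok], weights=w[ok]))
    return IceCoverResult(ice, 100.0 - ice, int(ok.sum()))


def ice_presence_overlay(
    series: pd.DataFrame,
    grids,
    query: RadiusQuery,
    max_gap_days: int = 2,
    cos_lat_weights: bool = False,
) -> pd.DataFrame:
    """Join daily ice cover onto the acoustic presence series.

    For each presence day the nearest dated grid within ``max_gap_days`` is
    queried (ties toward the earlier grid); days with no grid near enough get
    NaN ice columns.  Output columns: ``ice_percent, open_water_percent,
    detection_count, detected, effort``.
    """
    grids = sorted(grids, key=lambda g: g.date)
    grid_days = np.array([g.date.toordinal() for g in grids])
    cache: dict[int, tuple[float, float]] = {}

    def ice_for(day: date) -> tuple[float, float]:
        if grid_days.size == 0:
            return (np.nan, np.nan)
        o = day.toordinal()
        j = int(np.searchsorted(grid_days, o))
        best, best_gap = None, None
        for k in (j - 1, j):
            if 0 <= k < grid_days.size:
                gap = abs(grid_days[k] - o)
                if best is None or gap < best_gap:
                    best, best_gap = k, gap
        if best is None or best_gap > max_gap_days:
            return (np.nan, np.nan)
        if best not in cache:
            res = cover_within_radius(grids[best], query, cos_lat_weights)
            cache[best] = (res.ice_percent, res.open_water_percent)
        return cache[best]

    rows = []
    for d, row in series.iterrows():
        ice, ow = ice_for(d)
        rows.append({
            "date": d,
            "ice_percent": ice,
            "open_water_percent": ow,
            "detection_count": int(row["detection_count"]),
            "detected": bool(row["detection_count"] > 0),
            "effort": bool(row["recorded_seconds"] > 0),
        })
    return pd.DataFrame(rows).set_index("date")


def write_grid_csv(path, grid: IceGrid) -> None:
    """Flat CSV: one row per cell with row/col indices, centre coordinates,
    and concentration (empty for missing)."""
    r, c = np.indices(grid.concentration.shape)
    pd.DataFrame({
        "date": grid.date.isoformat(),
        "row": r.ravel(),
        "col": c.ravel(),
        "lat": grid.cell_lat.ravel(),
        "lon": grid.cell_lon.ravel(),
        "concentration": grid.concentration.ravel(),
        "cell_size_km": grid.cell_size_km,
    }).to_csv(path, index=False)


def read_grid_csv(path) -> IceGrid:
    df = pd.read_csv(path)
    nr = int(df["row"].max()) + 1
    nc = int(df["col"].max()) + 1

    def reshape(col):
        a = np.full((nr, nc), np.nan)
        a[df["row"], df["col"]] = df[col]
        return a

    return IceGrid(
        reshape("concentration"), reshape("lat"), reshape("lon"),
        float(df["cell_size_km"].iloc[0]),
        date.fromisoformat(str(df["date"].iloc[0])),
    )
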