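"""Equal-area gridding of geographic point data.

Occurrence records are projected with a Behrmann cylindrical equal-area
projection (standard parallel 30°) and binned into square cells, by default
48.24 km on a side (roughly half a degree at the standard parallel).  Because
the projection is equal-area, every cell covers the same ground area, so
per-cell counts are directly comparable across latitudes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "GridSpec",
    "CellIndex",
    "project",
    "unproject",
    "cell_of",
    "centroid_of",
    "cells_to_geojson",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the equal-area analysis grid.

    Parameters
    ----------
    cell_size_km : float
        Side length of the square grid cells, km.
    standard_parallel_deg : float
        Latitude of true scale of the cylindrical equal-area projection.
        30° gives the Behrmann projection.
    sphere_radius_km : float
        Radius of the sphere; the authalic radius preserves total area.
    origin_x_km, origin_y_km : float
        Projected coordinate of the corner of cell (0, 0).
    """

    cell_size_km: float = 48.24
    standard_parallel_deg: float = 30.0
    sphere_radius_km: float = 6371.007
    origin_x_km: float = 0.0
    origin_y_km: float = 0.0

    def __post_init__(self) -> None:
        if not self.cell_size_km > 0:
            raise ValueError(f"cell_size_km must be positive, got {self.cell_size_km}")
        if not abs(self.standard_parallel_deg) < 90:
            raise ValueError("standard parallel must lie strictly between the poles")
        if not self.sphere_radius_km > 0:
            raise ValueError("sphere_radius_km must be positive")

    @property
    def cos_parallel(self) -> float:
        return math.cos(math.radians(self.standard_parallel_deg))

    @property
    def cell_area_km2(self) -> float:
        """Planar cell area; identical for every cell by construction."""
        return self.cell_size_km**2


@dataclass(frozen=True, order=True)
class CellIndex:
    """Integer (column, row) identity of one grid cell."""

    ix: int
    iy: int


class CoordinateRangeError(ValueError):
    """A longitude/latitude fell outside [-180, 180] x [-90, 90]."""


def project(lon, lat, spec: GridSpec = GridSpec()):
    """Forward Behrmann projection: degrees -> km.

    x = R * lambda * cos(phi_s),  y = R * sin(phi) / cos(phi_s).

    Accepts scalars or arrays; raises :class:`CoordinateRangeError` for
    coordinates outside the valid geographic ranges.
    """
    lon_a = np.asarray(lon, dtype=float)
    lat_a = np.asarray(lat, dtype=float)
    if np.any(~np.isfinite(lon_a)) or np.any(~np.isfinite(lat_a)):
        raise CoordinateRangeError("non-finite coordinates")
    if np.any(np.abs(lon_a) > 180.0) or np.any(np.abs(lat_a) > 90.0):
        raise CoordinateRangeError(
            "coordinates outside lon [-180, 180] / lat [-90, 90]"
        )
    c = spec.cos_parallel
    r = spec.sphere_radius_km
    x = r * np.radians(lon_a) * c
    y = r * np.sin(np.radians(lat_a)) / c
    if np.isscalar(lon) and np.isscalar(lat):
        return float(x), float(y)
    return x, y


def unproject(x, y, spec: GridSpec = GridSpec()):
    """Inverse Behrmann projection: km -> degrees.

    Raises ValueError when ``y`` lies beyond the projected poles (the point
    is off the globe).
    """
    x_a = np.asarray(x, dtype=float)
    y_a = np.asarray(y, dtype=float)
    c = spec.cos_parallel
    r = spec.sphere_radius_km
    sin_lat = y_a * c / r
    if np.any(np.abs(sin_lat) > 1.0 + 1e-12):
        raise ValueError("y coordinate beyond the projected poles")
    sin_lat = np.clip(sin_lat, -1.0, 1.0)
    lon = np.degrees(x_a / (r * c))
    lat = np.degrees(np.arcsin(sin_lat))
    if np.isscalar(x) and np.isscalar(y):
        return float(lon), float(lat)
    return lon, lat


def cell_of(x, y, spec: GridSpec = GridSpec()):
    """Map projected km coordinates to their grid cell.

    Binning is half-open: a point exactly on an edge belongs to the cell on
    the higher-index side, so every point maps to exactly one cell.
    """
    x_a = np.asarray(x, dtype=float)
    y_a = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(x_a)) or np.any(~np.isfinite(y_a)):
        raise ValueError("non-finite projected coordinates")
    s = spec.cell_size_km
    ix = np.floor((x_a - spec.origin_x_km) / s).astype(np.int64)
    iy = np.floor((y_a - spec.origin_y_km) / s).astype(np.int64)
    if np.isscalar(x) and np.isscalar(y):
        return CellIndex(int(ix), int(iy))
    return ix, iy


def centroid_of(cell: CellIndex, spec: GridSpec = GridSpec(), geographic: bool = False):
    """Planar centroid of a cell, optionally inverse-projected to (lon, lat).

    A cell whose centroid lies beyond the projected poles is off the globe;
    requesting its geographic centroid raises ValueError.
    """
    s = spec.cell_size_km
    x = spec.origin_x_km + (cell.ix + 0.5) * s
    y = spec.origin_y_km + (cell.iy + 0.5) * s
    if geographic:
        return unproject(x, y, spec)
    return x, y


def centroids_of(ix, iy, spec: GridSpec = GridSpec()):
    """Vectorised planar centroids for arrays of cell indices."""
    ix_a = np.asarray(ix, dtype=float)
    iy_a = np.asarray(iy, dtype=float)
    s = spec.cell_size_km
    return spec.origin_x_km + (ix_a + 0.5) * s, spec.origin_y_km + (iy_a + 0.5) * s


def _cell_corners_lonlat(cell: CellIndex, spec: GridSpec):
    s = spec.cell_size_km
    x0 = spec.origin_x_km + cell.ix * s
    y0 = spec.origin_y_km + cell.iy * s
    corners = [(x0, y0), (x0 + s, y0), (x0 + s, y0 + s), (x0, y0 + s), (x0, y0)]
    return [list(unproject(cx, cy, spec)) for cx, cy in corners]


def cells_to_geojson(cells: Iterable[CellIndex], spec: GridSpec = GridSpec()) -> dict:
    """GeoJSON FeatureCollection of cell polygons (corners inverse-projected)."""
    features = []
    for cell in cells:
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [_cell_corners_lonlat(cell, spec)],
                },
                "properties": {"ix": cell.ix, "iy": cell.iy},
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_geojson(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh)
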