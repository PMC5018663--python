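"""Registration of a regular geographic grid and boundary clipping.

Cells are half-open squares ``[edge, edge + resolution)`` in both latitude
and longitude, so cell assignment is a partition: a point on a shared edge
belongs to the cell with the larger index along that axis.  The default
resolution, 0.05 degrees, is roughly 5-6 km at Mexican latitudes.

The grid origin is configurable because published cell centers need not sit
on multiples of the resolution; analyses that must match an external grid
registration can set ``origin_lat``/``origin_lon``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box, mapping, shape
from shapely.geometry.base import BaseGeometry

EARTH_RADIUS_KM = 6371.0072  # authalic sphere


class CellId(NamedTuple):
    """Grid-cell address: row indexes latitude, col indexes longitude."""

    row: int
    col: int


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the analysis grid.

    ``assign(center(k)) == k`` holds for every cell; this registration
    invariant pins down the half-open convention.
    """

    resolution: float = 0.05
    origin_lat: float = 0.0
    origin_lon: float = 0.0

    def __post_init__(self) -> None:
        if not self.resolution > 0:
            raise ValueError("grid resolution must be positive")

    def cell_center(self, cell: CellId) -> tuple[float, float]:
        """(lat, lon) of the cell center: edge + resolution/2."""
        lat = self.origin_lat + (cell.row + 0.5) * self.resolution
        lon = self.origin_lon + (cell.col + 0.5) * self.resolution
        return lat, lon

    def cell_bounds(self, cell: CellId) -> tuple[float, float, float, float]:
        """(min_lon, min_lat, max_lon, max_lat) of the cell square."""
        lat0 = self.origin_lat + cell.row * self.resolution
        lon0 = self.origin_lon + cell.col * self.resolution
        return lon0, lat0, lon0 + self.resolution, lat0 + self.resolution

    def cell_polygon(self, cell: CellId) -> BaseGeometry:
        return box(*self.cell_bounds(cell))


def assign_cell(lat: float, lon: float, spec: GridSpec) -> CellId:
    """Assign a point to its grid cell (half-open convention).

    Raises ``ValueError`` on non-finite coordinates.
    """
    if not (math.isfinite(lat) and math.isfinite(lon)):
        raise ValueError(f"non-finite coordinates ({lat}, {lon})")
    row = math.floor((lat - spec.origin_lat) / spec.resolution)
    col = math.floor((lon - spec.origin_lon) / spec.resolution)
    return CellId(int(row), int(col))


def cell_place_resolver(spec: GridSpec):
    """Record -> place-key function for the georeferenced path.

    Returns ``None`` for records without coordinates so they are excluded
    from the georeferenced event set.
    """

    def resolve(record: pd.Series):
        lat, lon = record["lat"], record["lon"]
        if pd.isna(lat) or pd.isna(lon):
            return None
        return assign_cell(float(lat), float(lon), spec)

    return resolve


# --- boundary handling ------------------------------------------------------

def load_boundary(path: str | Path) -> BaseGeometry:
    """Load a boundary polygon from GeoJSON (geometry, Feature or collection)."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in doc["features"]]
        geom = shapely.union_all(geoms)
    elif doc.get("type") == "Feature":
        geom = shape(doc["geometry"])
    else:
        geom = shape(doc)
    _check_boundary(geom)
    return geom


def _check_boundary(boundary: BaseGeometry) -> None:
    if boundary is None or boundary.is_empty:
        raise ValueError("boundary polygon is empty")
    if not boundary.is_valid:
        raise ValueError("boundary polygon is invalid")


def clip_to_boundary(
    records: pd.DataFrame, boundary: BaseGeometry, buffer: float = 0.05
) -> pd.DataFrame:
    """Keep georeferenced records inside the boundary or within ``buffer`` degrees.

    Distances are planar in degrees.  Records without coordinates pass
    through untouched (they are clipped, if ever, after locality rescue).
    """
    _check_boundary(boundary)
    has_coords = records["lat"].notna() & records["lon"].notna()
    points = shapely.points(
        records.loc[has_coords, "lon"].to_numpy(float),
        records.loc[has_coords, "lat"].to_numpy(float),
    )
    shapely.prepare(boundary)
    near = shapely.dwithin(boundary, points, buffer)
    keep = records.index[~has_coords].tolist() + list(
        records.index[has_coords][near]
    )
    kept = records.loc[sorted(keep)].copy()
    n_dropped = len(records) - len(kept)
    frac = n_dropped / len(records) if len(records) else 0.0
    logging.getLogger(__name__).info(
        "clip_to_boundary: dropped %d/%d records (%.1f%%)",
        n_dropped,
        len(records),
        100 * frac,
    )
    return kept


def clip_cells(
    spec: GridSpec, boundary: BaseGeometry, buffer: float = 0.05
) -> set[CellId]:
    """Cells whose square lies within ``buffer`` degrees of the boundary.

    Candidate cells are enumerated over the boundary's bounding box expanded
    by the buffer; a cell is retained iff the planar distance from its square
    to the boundary polygon is at most ``buffer`` (zero for any overlap).
    """
    _check_boundary(boundary)
    minx, miny, maxx, maxy = boundary.bounds
    lo = assign_cell(miny - buffer, minx - buffer, spec)
    hi = assign_cell(maxy + buffer, maxx + buffer, spec)
    shapely.prepare(boundary)
    retained: set[CellId] = set()
    # one extra ring: a cell just outside the expanded bounding box can still
    # sit exactly at the buffer distance
    for row in range(lo.row - 1, hi.row + 2):
        for col in range(lo.col - 1, hi.col + 2):
            cell = CellId(row, col)
            # tiny tolerance: cells exactly at the buffer distance must not
            # flip on float rounding of grid-aligned coordinates
            if boundary.distance(spec.cell_polygon(cell)) <= buffer + 1e-9:
                retained.add(cell)
    return retained


# --- per-cell counting and geometry export ----------------------------------

def count_events_per_cell(
    events: pd.DataFrame, retained_cells: Iterable[CellId] | None = None
) -> dict[CellId, int]:
    """Count events per cell; retained cells with no events count zero.

    The zeros matter: the Gi* statistic is computed over the full study
    area, not only over sampled cells.
    """
    counts: dict[CellId, int] = {}
    if retained_cells is not None:
        counts.update({cell: 0 for cell in retained_cells})
    if len(events):
        for cell, n in events.groupby("place_key", sort=False).size().items():
            if isinstance(cell, tuple):
                counts[CellId(*cell)] = counts.get(CellId(*cell), 0) + int(n)
    return counts


def cell_area_km2(cell: CellId, spec: GridSpec) -> float:
    """Spherical-Earth area of one cell in km^2."""
    lon0, lat0, lon1, lat1 = spec.cell_bounds(cell)
    dlon = math.radians(lon1 - lon0)
    band = math.sin(math.radians(lat1)) - math.sin(math.radians(lat0))
    return EARTH_RADIUS_KM**2 * dlon * band


def cells_to_geojson(
    cells: Iterable[CellId],
    spec: GridSpec,
    properties: Mapping[CellId, Mapping] | None = None,
) -> dict:
    """Export cells as a GeoJSON FeatureCollection of squares."""
    features = []
    for cell in sorted(cells):
        props = {"row": cell.row, "col": cell.col}
        lat, lon = spec.cell_center(cell)
        props.update({"center_lat": lat, "center_lon": lon})
        if properties and cell in properties:
            props.update(properties[cell])
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(spec.cell_polygon(cell)),
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}
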