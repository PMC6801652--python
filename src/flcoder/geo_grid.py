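"""Study-area gridding and point-to-cell location.

The validation design compares coder output and street audit per square
cell ("grid", the buffer zone of the fieldwork), by default 100 m x 100 m.
Cells are axis-aligned squares in a projected CRS, anchored at the
bounding-box minimum corner, half-open on the top/right edge so that every
point belongs to at most one cell.  Partial edge cells are kept: the audit
walks physical blocks, and clipping slivers would silently shrink the
sampling frame.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from shapely.geometry import box, shape
from shapely.geometry.base import BaseGeometry

from .projection import UtmZone, from_utm, to_utm, utm_zone_for

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 longitude/latitude pair in degrees."""

    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")


def haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance between two WGS84 points in kilometres."""
    la1, la2 = math.radians(a.lat), math.radians(b.lat)
    dla = la2 - la1
    dlo = math.radians(b.lon - a.lon)
    h = math.sin(dla / 2.0) ** 2 + math.cos(la1) * math.cos(la2) * math.sin(dlo / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def haversine_m(a: GeoPoint, b: GeoPoint) -> float:
    return haversine_km(a, b) * 1000.0


@dataclass
class GridSet:
    """Axis-aligned square tiling of a projected study area.

    ``cells`` lists the (col, row) indices whose square intersects the
    study-area polygon; indices count from the bounding-box min corner.
    Each cell covers the half-open square
    ``[x0 + col*s, x0 + (col+1)*s) x [y0 + row*s, y0 + (row+1)*s)``.
    """

    origin_xy: tuple[float, float]
    cell_size_m: float
    n_cols: int
    n_rows: int
    crs_id: str = "projected"
    cells: list[tuple[int, int]] = field(default_factory=list)
    _cellset: frozenset = field(init=False, repr=False, default=frozenset())

    def __post_init__(self) -> None:
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        if self.n_cols * self.n_rows < len(self.cells):
            raise ValueError("more cells than the grid extent allows")
        self._cellset = frozenset(self.cells)

    def __len__(self) -> int:
        return len(self.cells)

    def cell_id(self, col: int, row: int) -> str:
        return f"c{col}_r{row}"

    def cell_ids(self) -> list[str]:
        return [self.cell_id(c, r) for c, r in self.cells]

    def cell_polygon(self, col: int, row: int):
        x0, y0 = self.origin_xy
        s = self.cell_size_m
        return box(x0 + col * s, y0 + row * s, x0 + (col + 1) * s, y0 + (row + 1) * s)

    def parse_cell_id(self, cell_id: str) -> tuple[int, int]:
        try:
            c, r = cell_id.lstrip("c").split("_r")
            return int(c), int(r)
        except ValueError as exc:
            raise ValueError(f"malformed cell id {cell_id!r}") from exc


def _as_polygon(study_area) -> BaseGeometry:
    if isinstance(study_area, BaseGeometry):
        geom = study_area
    elif isinstance(study_area, dict):
        geom = shape(study_area.get("geometry", study_area))
    else:
        raise TypeError("study_area must be a shapely geometry or GeoJSON mapping")
    if geom.is_empty:
        raise ValueError("study area polygon is empty")
    return geom


def _looks_geographic(geom: BaseGeometry) -> bool:
    minx, miny, maxx, maxy = geom.bounds
    return (
        -180.0 <= minx <= 180.0
        and -180.0 <= maxx <= 180.0
        and -90.0 <= miny <= 90.0
        and -90.0 <= maxy <= 90.0
    )


def make_grid(study_area, cell_size_m: float = 100.0, crs_id: str = "projected") -> GridSet:
    """Tile a projected study-area polygon with square cells.

    Returns every cell whose square intersects the polygon, anchored at
    the bounding-box min corner.  Geographic (degree) input is rejected:
    metric cells require projected coordinates (see
    :func:`project_study_area`).
    """
    geom = _as_polygon(study_area)
    if cell_size_m <= 0:
        raise ValueError("cell_size_m must be positive")
    if _looks_geographic(geom):
        raise ValueError(
            "study area appears to be in geographic degrees; project it to a "
            "metric CRS first (e.g. project_study_area() for WGS84 -> UTM)"
        )

    minx, miny, maxx, maxy = geom.bounds
    n_cols = max(1, math.ceil((maxx - minx) / cell_size_m - 1e-9))
    n_rows = max(1, math.ceil((maxy - miny) / cell_size_m - 1e-9))

    cells: list[tuple[int, int]] = []
    for row in range(n_rows):
        for col in range(n_cols):
            sq = box(
                minx + col * cell_size_m,
                miny + row * cell_size_m,
                minx + (col + 1) * cell_size_m,
                miny + (row + 1) * cell_size_m,
            )
            if sq.intersects(geom) and not sq.touches(geom):
                cells.append((col, row))
    return GridSet(
        origin_xy=(minx, miny),
        cell_size_m=cell_size_m,
        n_cols=n_cols,
        n_rows=n_rows,
        crs_id=crs_id,
        cells=cells,
    )


def locate_point(xy: Sequence[float], grid: GridSet) -> Optional[tuple[int, int]]:
    """Cell (col, row) containing a projected point, or None if outside.

    Uses the half-open convention: a point exactly on an interior cell
    boundary belongs to the higher-index cell.
    """
    x0, y0 = grid.origin_xy
    s = grid.cell_size_m
    col = math.floor((xy[0] - x0) / s)
    row = math.floor((xy[1] - y0) / s)
    if (col, row) in grid._cellset:
        return (col, row)
    return None


def project_study_area(geojson_geom: dict | BaseGeometry, zone: UtmZone | None = None):
    """Project a WGS84 GeoJSON polygon to UTM metres.

    The zone defaults to the UTM zone of the polygon centroid.  Returns
    ``(projected shapely geometry, zone)``.
    """
    geom = _as_polygon(geojson_geom)
    if zone is None:
        c = geom.centroid
        zone = utm_zone_for(c.x, c.y)
    from shapely.ops import transform as shp_transform

    def _fwd(x, y, z=None):
        xs = np.atleast_1d(x).astype(float)
        ys = np.atleast_1d(y).astype(float)
        pts = [to_utm(float(xi), float(yi), zone) for xi, yi in zip(xs, ys)]
        ex = np.array([p[0] for p in pts])
        ny = np.array([p[1] for p in pts])
        if np.isscalar(x):
            return ex[0], ny[0]
        return ex, ny

    return shp_transform(_fwd, geom), zone


def grid_to_geojson(grid: GridSet, zone: UtmZone | None = None) -> dict:
    """Export grid cells as a GeoJSON FeatureCollection.

    With a UTM ``zone``, cell corners are inverse-projected to WGS84
    degrees; otherwise the projected metre coordinates are emitted as-is.
    """
    features = []
    for col, row in grid.cells:
        poly = grid.cell_polygon(col, row)
        coords = list(poly.exterior.coords)
        if zone is not None:
            coords = [from_utm(x, y, zone) for x, y in coords]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [list(map(list, coords))]},
                "properties": {"col": col, "row": row, "cell_id": grid.cell_id(col, row)},
            }
        )
    return {"type": "FeatureCollection", "features": features}


def load_study_area(path: str) -> dict:
    """Read a GeoJSON file and return its first Polygon/MultiPolygon geometry."""
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") == "FeatureCollection":
        for feat in data.get("features", []):
            g = feat.get("geometry") or {}
            if g.get("type") in ("Polygon", "MultiPolygon"):
                return g
        raise ValueError(f"no polygon feature found in {path}")
    if data.get("type") == "Feature":
        return data["geometry"]
    return data
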