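"""Point-of-interest ingestion: file loaders, zone queries, deduplication.

Place records come from heterogeneous sources (typically a commercial
places API and OpenStreetMap) that frequently list the same storefront
twice with slightly different coordinates and name spellings.  Records
are merged by single-linkage grouping over pairs that are both spatially
close and textually similar; each group becomes one facility whose
representative record is taken from the most trusted source.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Point, shape
from shapely.geometry.base import BaseGeometry

from .classify import CategoryLabel
from .geo_grid import GeoPoint, haversine_m
from .text import normalize_text, token_set_similarity

logger = logging.getLogger(__name__)

# higher trusted first: curated files beat the places API beats OSM
SOURCE_PRIORITY = {"file": 0, "synthetic": 0, "google": 1, "osm": 2}

# with an empty name, location alone decides duplicates within this radius
EMPTY_NAME_DIST_M = 10.0


@dataclass
class RawPlace:
    """One point of interest as reported by a single source."""

    source: str
    source_id: str
    name: str
    location: GeoPoint
    tags: dict = field(default_factory=dict)

    @property
    def canonical_name(self) -> str:
        return normalize_text(self.name or "")


@dataclass
class FacilityRecord:
    """A deduplicated facility, possibly merged from several sources."""

    source: str
    source_id: str
    name: str
    location: GeoPoint
    tags: dict = field(default_factory=dict)
    canonical_name: str = ""
    category: Optional[CategoryLabel] = None
    merged_from: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.canonical_name:
            self.canonical_name = normalize_text(self.name or "")
        if not self.merged_from:
            self.merged_from = [(self.source, self.source_id)]


def load_geojson(path: str, source: str = "file") -> list[RawPlace]:
    """Read places from a GeoJSON FeatureCollection.

    Point features are used directly; polygon features are reduced to
    their centroid.  Feature ``properties`` become the record tags;
    features without geometry are skipped with a warning, and a missing
    name becomes "" (logged).
    """
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    places: list[RawPlace] = []
    for i, feat in enumerate(data.get("features", [])):
        geom = feat.get("geometry")
        if geom is None:
            logger.warning("%s: feature %d has no geometry, skipped", path, i)
            continue
        g = shape(geom)
        if g.geom_type != "Point":
            g = g.centroid
        props = dict(feat.get("properties") or {})
        name = props.pop("name", None)
        if name is None:
            logger.warning("%s: feature %d has no name", path, i)
            name = ""
        places.append(
            RawPlace(
                source=str(props.pop("source", source)),
                source_id=str(props.pop("source_id", f"{source}-{i}")),
                name=str(name),
                location=GeoPoint(lon=g.x, lat=g.y),
                tags=props,
            )
        )
    return places


def load_csv(path: str) -> list[RawPlace]:
    """Read places from CSV with columns ``name,lon,lat,source,source_id``.

    Optional ``tag:<key>`` columns populate the record tags.
    """
    places: list[RawPlace] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"name", "lon", "lat", "source", "source_id"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
        for row in reader:
            tags = {
                k[4:]: v for k, v in row.items() if k.startswith("tag:") and v not in (None, "")
            }
            places.append(
                RawPlace(
                    source=row["source"],
                    source_id=row["source_id"],
                    name=row["name"] or "",
                    location=GeoPoint(lon=float(row["lon"]), lat=float(row["lat"])),
                    tags=tags,
                )
            )
    return places


class FilePlacesAdapter:
    """Offline source adapter backed by already-loaded records."""

    def __init__(self, places: Sequence[RawPlace]):
        self._places = list(places)

    def search(self, zone: BaseGeometry) -> list[RawPlace]:
        return [p for p in self._places if zone.intersects(Point(p.location.lon, p.location.lat))]


class LiveAdapterUnavailable(RuntimeError):
    pass


class GooglePlacesAdapter:
    """Stub for the commercial places API; requires network and an API key."""

    def __init__(self, api_key: str | None = None):
        self.api_key = api_key

    def search(self, zone) -> list[RawPlace]:
        raise LiveAdapterUnavailable(
            "live places-API queries are not configured in this build; "
            "export the data and use load_geojson/load_csv with FilePlacesAdapter"
        )


class OverpassAdapter:
    """Stub for OpenStreetMap Overpass queries; requires network."""

    def search(self, zone) -> list[RawPlace]:
        raise LiveAdapterUnavailable(
            "live Overpass queries are not configured in this build; "
            "use an OSM extract with load_geojson/load_csv instead"
        )


def query_zone(adapter, zone) -> list[RawPlace]:
    """All places the adapter reports inside a WGS84 zone polygon."""
    zone = shape(zone) if isinstance(zone, dict) else zone
    if zone.is_empty:
        return []
    return adapter.search(zone)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _duplicate_pair(
    a: RawPlace, b: RawPlace, dist_threshold_m: float, name_sim_threshold: float
) -> bool:
    d = haversine_m(a.location, b.location)
    ca, cb = a.canonical_name, b.canonical_name
    if not ca or not cb:
        return d <= EMPTY_NAME_DIST_M
    return d <= dist_threshold_m and token_set_similarity(ca, cb) >= name_sim_threshold


def merge_and_dedupe(
    places: Sequence[RawPlace],
    dist_threshold_m: float = 25.0,
    name_sim_threshold: float = 0.85,
) -> list[FacilityRecord]:
    """Merge duplicate place records into facilities.

    Pairs are duplicates when within ``dist_threshold_m`` metres AND
    their canonical names reach ``name_sim_threshold`` token-set
    similarity (location alone within 10 m when either name is empty).
    Single-linkage groups over these pairs each yield one facility; the
    representative is the member from the highest-priority source
    (file > google > osm), ties broken by most non-empty tags, then by
    (source, source_id) for determinism.  ``merged_from`` lists every
    member, so no input record is lost.
    """
    if dist_threshold_m <= 0 or name_sim_threshold <= 0:
        raise ValueError("thresholds must be positive")
    places = list(places)
    n = len(places)
    if n == 0:
        return []

    # candidate pairs via a KD-tree on a local equirectangular projection
    lat0 = float(np.mean([p.location.lat for p in places]))
    mlat = 111_194.9  # metres per degree latitude (mean-radius sphere)
    mlon = mlat * np.cos(np.radians(lat0))
    xy = np.array([[p.location.lon * mlon, p.location.lat * mlat] for p in places])
    radius = max(dist_threshold_m, EMPTY_NAME_DIST_M) * 1.05
    pairs = cKDTree(xy).query_pairs(r=radius)

    uf = _UnionFind(n)
    for i, j in pairs:
        if _duplicate_pair(places[i], places[j], dist_threshold_m, name_sim_threshold):
            uf.union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    def _rank(i: int) -> tuple:
        p = places[i]
        n_tags = sum(1 for v in p.tags.values() if v not in (None, ""))
        return (SOURCE_PRIORITY.get(p.source, 99), -n_tags, p.source, p.source_id)

    facilities: list[FacilityRecord] = []
    for members in groups.values():
        rep = places[min(members, key=_rank)]
        merged = sorted((places[i].source, places[i].source_id) for i in members)
        tags = dict(rep.tags)
        for i in sorted(members, key=_rank):
            for k, v in places[i].tags.items():
                tags.setdefault(k, v)
        facilities.append(
            FacilityRecord(
                source=rep.source,
                source_id=rep.source_id,
                name=rep.name,
                location=rep.location,
                tags=tags,
                merged_from=merged,
            )
        )
    facilities.sort(key=lambda f: (f.source, f.source_id))
    return facilities


def facilities_to_geojson(facilities: Iterable[FacilityRecord]) -> dict:
    features = []
    for f in facilities:
        props = {
            "name": f.name,
            "source": f.source,
            "source_id": f.source_id,
            "category": str(f.category) if f.category is not None else "unassigned",
            "merged_from": ";".join(f"{s}:{i}" for s, i in f.merged_from),
        }
        props.update({f"tag:{k}": v for k, v in f.tags.items()})
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [f.location.lon, f.location.lat]},
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}
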