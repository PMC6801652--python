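"""Synthetic city and street-audit generator.

The original validation data (a Catalan coastal city's facilities and
the audited sample of cells) were never published, so this module
generates stand-in cities with known ground truth: facility point
patterns over a metric study rectangle, a realistic category mix,
multi-language storefront names built from the classification lexicon
(so the classifier is exercised non-trivially), injected duplicate pairs
for the deduplication stage, and noisy audits with controlled
false-positive / false-negative structure for the validation statistics.

Defaults emulate the study conditions: a 5500 m x 2500 m frame (exactly
1375 cells of 100 m), 935 facilities, bars/restaurants the most common
food category (26%) ahead of fast food (19%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml
from shapely.geometry import box

from .classify import CategoryLabel, FOOD_CATEGORIES, KeywordLexicon
from .geo_grid import GeoPoint, GridSet, locate_point, make_grid
from .ingest import RawPlace, facilities_to_geojson
from .projection import UtmZone, from_utm, to_utm, utm_zone_for
from .validation import AuditRecord

DEFAULT_ORIGIN = (2.41, 41.52)  # WGS84 lon/lat of the study rectangle's SW corner

DEFAULT_MIX = {
    CategoryLabel.FAST_FOOD: 0.19,
    CategoryLabel.BAR_RESTAURANT: 0.26,
    CategoryLabel.SUPERMARKET: 0.10,
    CategoryLabel.CONVENIENCE_OTHER: 0.25,
    CategoryLabel.NON_FOOD: 0.20,
}

# filler vocabulary for synthetic storefront names; none of these words
# occur in the default lexicon, so they never flip a classification
_FILLERS = (
    "can", "cal", "nou", "vell", "central", "petit", "gran", "maria", "joan",
    "pepe", "montse", "carme", "jordi", "nuria", "sol", "mar", "lluna",
    "estrella", "rambla", "passeig", "avinguda",
)

_NON_FOOD_BASES = (
    "farmacia", "ferreteria", "llibreria", "perruqueria", "floristeria",
    "optica", "joieria", "merceria", "copisteria", "gimnas",
)


@dataclass
class CitySpec:
    """Parameters of a synthetic city."""

    seed: int = 0
    width_m: float = 5500.0
    height_m: float = 2500.0
    origin_lonlat: tuple[float, float] = DEFAULT_ORIGIN
    n_facilities: int = 935
    category_mix: dict = field(default_factory=lambda: dict(DEFAULT_MIX))
    clustering: str = "uniform"  # or "clustered"
    name_noise: float = 0.0      # probability of a typo / extra token per name
    duplicate_rate: float = 0.05  # probability a facility is listed by a second source
    tag_rate: float = 0.3        # probability a place carries a category source tag
    n_clusters: int = 8
    cluster_sd_m: float = 150.0

    def __post_init__(self) -> None:
        self.category_mix = {CategoryLabel(k): float(v) for k, v in self.category_mix.items()}
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category mix sums to {total}, expected 1")
        if self.n_facilities < 0:
            raise ValueError("n_facilities must be >= 0")
        if self.clustering not in ("uniform", "clustered"):
            raise ValueError("clustering must be 'uniform' or 'clustered'")

    @classmethod
    def from_yaml(cls, path: str) -> "CitySpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "origin_lonlat" in data:
            data["origin_lonlat"] = tuple(data["origin_lonlat"])
        return cls(**data)


@dataclass
class AuditNoiseSpec:
    """Error structure injected into a simulated street audit.

    ``fp_rate``: probability a coder facility is a phantom -- listed by
    the sources but not physically present, hence absent from the audit
    (a false positive for the coder).  ``fn_rate``: expected share of
    on-the-ground facilities the coder misses, realized as audit-only
    records (false negatives).  ``gps_sd_m``: auditor GPS jitter.
    """

    seed: int = 0
    fn_rate: float = 0.08
    fp_rate: float = 0.14
    gps_sd_m: float = 5.0

    def __post_init__(self) -> None:
        for name in ("fn_rate", "fp_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.gps_sd_m < 0:
            raise ValueError("gps_sd_m must be >= 0")


@dataclass
class TruthFacility:
    """Ground-truth facility: what is physically on the street."""

    uid: str
    name: str
    location: GeoPoint
    xy: tuple[float, float]  # projected metres
    category: CategoryLabel


@dataclass
class SyntheticCity:
    spec: CitySpec
    zone: UtmZone
    origin_xy: tuple[float, float]
    truth: list
    places: list

    @property
    def study_area_utm(self):
        x0, y0 = self.origin_xy
        return box(x0, y0, x0 + self.spec.width_m, y0 + self.spec.height_m)

    def grid(self, cell_size_m: float = 100.0) -> GridSet:
        return make_grid(self.study_area_utm, cell_size_m, crs_id=f"utm{self.zone}")

    def places_geojson(self) -> dict:
        feats = []
        for p in self.places:
            props = {"name": p.name, "source": p.source, "source_id": p.source_id}
            props.update({f"tag:{k}": v for k, v in p.tags.items()})
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [p.location.lon, p.location.lat]},
                    "properties": props,
                }
            )
        return {"type": "FeatureCollection", "features": feats}

    def truth_categories(self) -> dict:
        return {t.uid: t.category for t in self.truth}


def _mutate_name(name: str, rng: np.random.Generator) -> str:
    tokens = name.split()
    if rng.random() < 0.5 and tokens:
        i = int(rng.integers(len(tokens)))
        tok = tokens[i]
        if len(tok) > 2:
            j = int(rng.integers(len(tok) - 1))
            tok = tok[:j] + tok[j + 1] + tok[j] + tok[j + 2 :]  # swap two letters
        tokens[i] = tok
    else:
        tokens.append(str(_FILLERS[int(rng.integers(len(_FILLERS)))]))
    return " ".join(tokens)


def _facility_name(cat: CategoryLabel, lexicon: KeywordLexicon, rng: np.random.Generator) -> str:
    if cat == CategoryLabel.NON_FOOD:
        base = _NON_FOOD_BASES[int(rng.integers(len(_NON_FOOD_BASES)))]
    else:
        kws = lexicon.all_keywords(cat)
        base = kws[int(rng.integers(len(kws)))]
    filler = _FILLERS[int(rng.integers(len(_FILLERS)))]
    return f"{base} {filler}" if rng.random() < 0.8 else base


def generate_city(spec: CitySpec, lexicon: Optional[KeywordLexicon] = None) -> SyntheticCity:
    """Generate a deterministic synthetic city from a seed.

    Every ground-truth facility gets a name containing a keyword of its
    true category (unless ``name_noise`` corrupts it), optional source
    tags at ``tag_rate``, and a second listing from another source at
    ``duplicate_rate`` within a few metres -- exercising classification
    and deduplication end to end.
    """
    lexicon = lexicon or KeywordLexicon.default()
    rng = np.random.default_rng(spec.seed)
    zone = utm_zone_for(*spec.origin_lonlat)
    origin_xy = to_utm(*spec.origin_lonlat, zone)
    x0, y0 = origin_xy

    cats = list(spec.category_mix.keys())
    probs = np.array([spec.category_mix[c] for c in cats])

    if spec.clustering == "clustered":
        centres = np.column_stack(
            [
                rng.uniform(0, spec.width_m, spec.n_clusters),
                rng.uniform(0, spec.height_m, spec.n_clusters),
            ]
        )

    truth: list[TruthFacility] = []
    places: list[RawPlace] = []
    for i in range(spec.n_facilities):
        if spec.clustering == "clustered":
            c = centres[int(rng.integers(spec.n_clusters))]
            for _ in range(100):
                dx, dy = rng.normal(0.0, spec.cluster_sd_m, 2)
                px, py = c[0] + dx, c[1] + dy
                if 0 <= px < spec.width_m and 0 <= py < spec.height_m:
                    break
            else:
                px, py = rng.uniform(0, spec.width_m), rng.uniform(0, spec.height_m)
        else:
            px, py = rng.uniform(0, spec.width_m), rng.uniform(0, spec.height_m)

        cat = cats[int(rng.choice(len(cats), p=probs))]
        name = _facility_name(cat, lexicon, rng)
        if rng.random() < spec.name_noise:
            name = _mutate_name(name, rng)

        xy = (x0 + px, y0 + py)
        lon, lat = from_utm(*xy, zone)
        uid = f"fac{i:05d}"
        truth.append(TruthFacility(uid, name, GeoPoint(lon, lat), xy, cat))

        tags: dict = {}
        if cat != CategoryLabel.NON_FOOD and rng.random() < spec.tag_rate:
            tag_list = lexicon.tags.get(cat, [])
            if tag_list:
                k, v = tag_list[int(rng.integers(len(tag_list)))].split("=", 1)
                tags[k] = v
        places.append(RawPlace("google", uid, name, GeoPoint(lon, lat), tags))

        if rng.random() < spec.duplicate_rate:
            jitter = rng.normal(0.0, 3.0, 2)  # metres; well inside the dedup radius
            dlon, dlat = from_utm(xy[0] + jitter[0], xy[1] + jitter[1], zone)
            places.append(RawPlace("osm", f"osm-{uid}", name, GeoPoint(dlon, dlat), dict(tags)))

    return SyntheticCity(spec=spec, zone=zone, origin_xy=origin_xy, truth=truth, places=places)


def simulate_audit(
    city: SyntheticCity,
    noise: AuditNoiseSpec,
    grid: Optional[GridSet] = None,
) -> list[AuditRecord]:
    """Simulate the street audit of a synthetic city.

    The audit covers food facilities only (the fieldwork protocol ignores
    non-food storefronts).  Coder phantoms are realized by omitting each
    true facility from the audit with probability ``fp_rate``; coder
    misses by adding spurious audit-only records so their expected share
    of the audit is ``fn_rate``, placed uniformly within occupied cells.
    Audit coordinates get Gaussian GPS jitter; grid ids always come from
    the true location.
    """
    grid = grid if grid is not None else city.grid()
    rng = np.random.default_rng(noise.seed)
    food_truth = [t for t in city.truth if t.category != CategoryLabel.NON_FOOD]

    records: list[AuditRecord] = []
    occupied_cells: list[tuple[int, int]] = []
    for t in food_truth:
        cell = locate_point(t.xy, grid)
        if cell is None:
            continue
        occupied_cells.append(cell)
        if rng.random() < noise.fp_rate:
            continue  # phantom: sources list it, the street does not
        jx, jy = rng.normal(0.0, noise.gps_sd_m, 2) if noise.gps_sd_m > 0 else (0.0, 0.0)
        lon, lat = from_utm(t.xy[0] + jx, t.xy[1] + jy, city.zone)
        records.append(
            AuditRecord(
                name=t.name,
                address=f"carrer sintetica {t.uid}",
                location=GeoPoint(lon, lat),
                category=t.category,
                grid_id=grid.cell_id(*cell),
            )
        )

    if noise.fn_rate > 0 and records:
        n_spurious = int(rng.poisson(len(records) * noise.fn_rate / (1.0 - noise.fn_rate)))
        lexicon = KeywordLexicon.default()
        x0g, y0g = grid.origin_xy
        for s in range(n_spurious):
            cell = occupied_cells[int(rng.integers(len(occupied_cells)))]
            cx = x0g + (cell[0] + rng.random()) * grid.cell_size_m
            cy = y0g + (cell[1] + rng.random()) * grid.cell_size_m
            lon, lat = from_utm(cx, cy, city.zone)
            cat = FOOD_CATEGORIES[int(rng.integers(len(FOOD_CATEGORIES)))]
            records.append(
                AuditRecord(
                    name=_facility_name(cat, lexicon, rng) + f" {s}",
                    address=f"carrer sintetica extra {s}",
                    location=GeoPoint(lon, lat),
                    category=cat,
                    grid_id=grid.cell_id(*cell),
                )
            )
    return records


def audit_to_csv(records: Sequence[AuditRecord], path: str) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "address", "lon", "lat", "category", "grid_id", "photo_ref"])
        for r in records:
            w.writerow(
                [r.name, r.address, f"{r.location.lon:.8f}", f"{r.location.lat:.8f}",
                 str(r.category), r.grid_id, r.photo_ref or ""]
            )


def city_to_files(city: SyntheticCity, geojson_path: str, truth_path: Optional[str] = None) -> None:
    with open(geojson_path, "w") as fh:
        json.dump(city.places_geojson(), fh, sort_keys=True)
    if truth_path:
        with open(truth_path, "w") as fh:
            json.dump({uid: str(cat) for uid, cat in city.truth_categories().items()}, fh, sort_keys=True)
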