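"""Coder-vs-audit comparison: per-grid counts, matching, FP/FN rates.

The street audit is the gold standard: auditors walk each sampled cell
and record every facility by name, address and coordinates.  This module
pairs the coder's facilities with the audit records cell by cell, counts
matches, false positives (coder-only: found by the coder but not
physically present) and false negatives (audit-only: on the ground but
missed by the coder), and applies the market correction -- the fieldwork
counts a covered food market as a single facility, while the coder lists
every stall inside it individually.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from shapely.geometry import Point, shape

from .classify import DEFAULT_PRECEDENCE, CategoryLabel
from .geo_grid import GeoPoint, GridSet, haversine_m, locate_point
from .ingest import FacilityRecord
from .projection import UtmZone, to_utm
from .text import normalize_text, token_set_similarity

logger = logging.getLogger(__name__)

MATCH_DIST_M = 50.0        # audit GPS + source coordinates are block-level noisy
MATCH_NAME_SIM = 0.75      # storefront names are noisier than source metadata


@dataclass
class AuditRecord:
    """One facility recorded during the street audit."""

    name: str
    address: str
    location: GeoPoint
    category: CategoryLabel
    grid_id: str
    photo_ref: Optional[str] = None


@dataclass
class ConfusionCounts:
    """Matched / coder-only / audit-only tallies."""

    matched: int = 0
    false_positive: int = 0
    false_negative: int = 0

    def __post_init__(self) -> None:
        if min(self.matched, self.false_positive, self.false_negative) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def flc_total(self) -> int:
        return self.matched + self.false_positive

    @property
    def audit_total(self) -> int:
        return self.matched + self.false_negative

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.matched + other.matched,
            self.false_positive + other.false_positive,
            self.false_negative + other.false_negative,
        )


@dataclass(frozen=True)
class GridCountPair:
    """Facility counts in one cell: coder vs audit."""

    grid_id: str
    n_flc: int
    n_audit: int

    @property
    def diff(self) -> int:
        return self.n_flc - self.n_audit


def load_audit_csv(path: str) -> list[AuditRecord]:
    """Read audit records from ``name,address,lon,lat,category,grid_id[,photo_ref]``."""
    records: list[AuditRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"name", "lon", "lat", "category", "grid_id"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
        for row in reader:
            records.append(
                AuditRecord(
                    name=row["name"] or "",
                    address=row.get("address", "") or "",
                    location=GeoPoint(lon=float(row["lon"]), lat=float(row["lat"])),
                    category=CategoryLabel(row["category"]),
                    grid_id=row["grid_id"],
                    photo_ref=row.get("photo_ref") or None,
                )
            )
    return records


def facility_cell(fac, grid: GridSet, zone: Optional[UtmZone]) -> Optional[str]:
    """Grid cell id of a facility, projecting WGS84 coords when a zone is given."""
    if zone is not None:
        xy = to_utm(fac.location.lon, fac.location.lat, zone)
    else:
        xy = getattr(fac, "xy", None)
        if xy is None:
            raise ValueError("facility has no projected coordinates and no UTM zone given")
    cell = locate_point(xy, grid)
    return None if cell is None else grid.cell_id(*cell)


def assign_audit_grid_ids(
    audits: Sequence[AuditRecord], grid: GridSet, zone: Optional[UtmZone]
) -> list[AuditRecord]:
    """Fill missing audit grid ids from the record coordinates."""
    out = []
    for rec in audits:
        if rec.grid_id:
            out.append(rec)
            continue
        xy = to_utm(rec.location.lon, rec.location.lat, zone) if zone else None
        cell = locate_point(xy, grid) if xy is not None else None
        if cell is None:
            raise ValueError(f"audit record {rec.name!r} falls outside the grid")
        out.append(
            AuditRecord(rec.name, rec.address, rec.location, rec.category,
                        grid.cell_id(*cell), rec.photo_ref)
        )
    return out


def count_by_grid(
    facilities: Sequence,
    audits: Sequence[AuditRecord],
    grid: GridSet,
    sampled_cells: Sequence[str],
    zone: Optional[UtmZone] = None,
    category: Optional[CategoryLabel] = None,
) -> list[GridCountPair]:
    """Per-sampled-cell facility counts, coder vs audit, zero-filled.

    Facilities outside every sampled cell are excluded (count logged);
    an audit record whose grid id is not in the sample is an error --
    the fieldwork only ever visits sampled cells.
    """
    sampled = list(sampled_cells)
    sampled_set = set(sampled)
    if category is not None:
        facilities = [f for f in facilities if f.category == category]
        audits = [a for a in audits if a.category == category]

    flc_counts: Counter = Counter()
    outside = 0
    for fac in facilities:
        cid = facility_cell(fac, grid, zone)
        if cid in sampled_set:
            flc_counts[cid] += 1
        else:
            outside += 1
    if outside:
        logger.info("%d coder facilities fall outside the sampled cells", outside)

    audit_counts: Counter = Counter()
    for rec in audits:
        if rec.grid_id not in sampled_set:
            raise ValueError(f"audit grid id {rec.grid_id!r} is not in the sampled cells")
        audit_counts[rec.grid_id] += 1

    return [GridCountPair(cid, flc_counts[cid], audit_counts[cid]) for cid in sampled]


def match_confusion(
    flc: Sequence,
    audit: Sequence[AuditRecord],
    dist_threshold_m: float = MATCH_DIST_M,
    name_sim_threshold: float = MATCH_NAME_SIM,
) -> ConfusionCounts:
    """Greedy one-to-one matching of coder facilities to audit records.

    Candidate pairs must pass both the distance and the name-similarity
    gate; pairs are consumed best-similarity-first (distance breaks
    ties).  Unmatched coder records are false positives, unmatched audit
    records false negatives.
    """
    if dist_threshold_m <= 0 or name_sim_threshold <= 0:
        raise ValueError("thresholds must be positive")
    candidates = []
    for i, f in enumerate(flc):
        fname = getattr(f, "canonical_name", "") or ""
        for j, a in enumerate(audit):
            d = haversine_m(f.location, a.location)
            if d > dist_threshold_m:
                continue
            sim = token_set_similarity(fname, normalize_text(a.name or ""))
            if sim >= name_sim_threshold:
                candidates.append((-sim, d, i, j))
    candidates.sort()
    used_f: set[int] = set()
    used_a: set[int] = set()
    matched = 0
    for _, _, i, j in candidates:
        if i in used_f or j in used_a:
            continue
        used_f.add(i)
        used_a.add(j)
        matched += 1
    return ConfusionCounts(
        matched=matched,
        false_positive=len(flc) - matched,
        false_negative=len(audit) - matched,
    )


def fp_fn_rates(c: ConfusionCounts) -> tuple[Optional[float], Optional[float]]:
    """False-positive and false-negative rates.

    fp_rate = FP / (matched + FP): the share of coder facilities not
    physically present.  fn_rate = FN / (matched + FN): the share of
    on-the-ground facilities the coder missed.  A zero denominator gives
    None (undefined) rather than an exception.
    """
    fp_rate = c.false_positive / c.flc_total if c.flc_total > 0 else None
    fn_rate = c.false_negative / c.audit_total if c.audit_total > 0 else None
    return fp_rate, fn_rate


def collapse_markets(facilities: Sequence[FacilityRecord], market_polygons) -> list:
    """Merge every facility inside a market polygon into one facility.

    Mirrors the fieldwork convention of counting a covered market as a
    single facility.  The collapsed facility sits at the polygon
    centroid; its category is the modal member category, precedence order
    breaking ties; ``merged_from`` is the union.  Overlapping market
    polygons are rejected.
    """
    if isinstance(market_polygons, dict):
        feats = market_polygons.get("features", [market_polygons])
        polys = [shape(f.get("geometry", f)) for f in feats]
    else:
        polys = [shape(p) if isinstance(p, dict) else p for p in market_polygons]
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            inter = polys[i].intersection(polys[j])
            if not inter.is_empty and inter.area > 0:
                raise ValueError(f"market polygons {i} and {j} overlap")

    out: list = []
    groups: dict[int, list] = {i: [] for i in range(len(polys))}
    for fac in facilities:
        pt = Point(fac.location.lon, fac.location.lat)
        for i, poly in enumerate(polys):
            if poly.covers(pt):
                groups[i].append(fac)
                break
        else:
            out.append(fac)

    for i, members in groups.items():
        if not members:
            continue
        centroid = polys[i].centroid
        counts = Counter(m.category for m in members if m.category is not None)
        if counts:
            best = max(counts.values())
            order = {c: k for k, c in enumerate(DEFAULT_PRECEDENCE)}
            modal = min(
                (c for c, n in counts.items() if n == best),
                key=lambda c: order.get(c, len(order)),
            )
        else:
            modal = None
        merged = sorted({mf for m in members for mf in m.merged_from})
        rep = min(members, key=lambda m: (m.source, m.source_id))
        out.append(
            FacilityRecord(
                source=rep.source,
                source_id=f"market-{i}",
                name=f"market {i}",
                location=GeoPoint(lon=centroid.x, lat=centroid.y),
                tags={"market": "collapsed", "n_members": str(len(members))},
                category=modal,
                merged_from=merged,
            )
        )
    return out


def agreement_rate(pairs: Sequence[GridCountPair], tolerance: int = 0) -> float:
    """Share of cells where coder and audit counts differ by at most
    ``tolerance`` facilities."""
    if not pairs:
        raise ValueError("no grid count pairs supplied")
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    ok = sum(1 for p in pairs if abs(p.diff) <= tolerance)
    return ok / len(pairs)
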