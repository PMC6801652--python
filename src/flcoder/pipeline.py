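"""High-level composition of the coding and validation stages.

`code_facilities` runs the coder proper: zone query -> merge/dedupe ->
classification.  `validate_against_audit` runs the full comparison of
coder output with street-audit records over a set of sampled grid cells
and assembles the validation report (per-grid pairs, matching, FP/FN
rates, market correction, agreement statistics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

from .classify import CategoryLabel, FOOD_CATEGORIES, KeywordLexicon, classify_all
from .geo_grid import GridSet
from .ingest import FacilityRecord, RawPlace, merge_and_dedupe
from .projection import UtmZone
from .stats import ValidationReport, run_validation
from .validation import (
    ConfusionCounts,
    GridCountPair,
    collapse_markets,
    count_by_grid,
    facility_cell,
    match_confusion,
)

logger = logging.getLogger(__name__)


@dataclass
class CodingResult:
    facilities: list
    tally: dict
    shares: dict
    n_places_in: int

    @property
    def food_facilities(self) -> list:
        return [f for f in self.facilities if f.category in FOOD_CATEGORIES]


def code_facilities(
    places: Sequence[RawPlace],
    lexicon: Optional[KeywordLexicon] = None,
    dist_threshold_m: float = 25.0,
    name_sim_threshold: float = 0.85,
) -> CodingResult:
    """The coder pipeline: deduplicate place records, classify facilities."""
    lexicon = lexicon or KeywordLexicon.default()
    facilities = merge_and_dedupe(places, dist_threshold_m, name_sim_threshold)
    facilities, tally, shares = classify_all(facilities, lexicon)
    logger.info(
        "coded %d places -> %d facilities (%d food)",
        len(places),
        len(facilities),
        sum(tally[c] for c in FOOD_CATEGORIES),
    )
    return CodingResult(facilities, tally, shares, n_places_in=len(places))


def aggregate_confusion(
    facilities: Sequence,
    audits: Sequence,
    grid: GridSet,
    sampled_cells: Sequence[str],
    zone: Optional[UtmZone] = None,
    category: Optional[CategoryLabel] = None,
    dist_threshold_m: float = 50.0,
    name_sim_threshold: float = 0.75,
) -> ConfusionCounts:
    """Cell-by-cell greedy matching summed over the sampled cells."""
    sampled = set(sampled_cells)
    by_cell_f: Dict[str, list] = {c: [] for c in sampled}
    for fac in facilities:
        if category is not None and fac.category != category:
            continue
        cid = facility_cell(fac, grid, zone)
        if cid in sampled:
            by_cell_f[cid].append(fac)
    by_cell_a: Dict[str, list] = {c: [] for c in sampled}
    for rec in audits:
        if category is not None and rec.category != category:
            continue
        if rec.grid_id in sampled:
            by_cell_a[rec.grid_id].append(rec)

    total = ConfusionCounts()
    for cid in sampled:
        total = total + match_confusion(
            by_cell_f[cid], by_cell_a[cid], dist_threshold_m, name_sim_threshold
        )
    return total


@dataclass
class ValidationOutput:
    report: ValidationReport
    pairs_overall: list
    pairs_market_corrected: Optional[list]
    pairs_by_category: dict
    confusion_overall: ConfusionCounts
    confusion_market_corrected: Optional[ConfusionCounts]
    confusion_by_category: dict


def validate_against_audit(
    facilities: Sequence,
    audits: Sequence,
    grid: GridSet,
    sampled_cells: Sequence[str],
    zone: Optional[UtmZone] = None,
    market_polygons=None,
    alpha_metric: str = "interval",
    match_dist_m: float = 50.0,
    match_name_sim: float = 0.75,
) -> ValidationOutput:
    """Compare coder facilities with audit records over sampled cells.

    Only food facilities enter the comparison (the audit protocol records
    food facilities only).  When market polygons are given, a
    market-corrected stratum is added and the per-category strata use the
    corrected facilities, mirroring the original table layout.
    """
    food = [f for f in facilities if f.category in FOOD_CATEGORIES]

    pairs_overall = count_by_grid(food, audits, grid, sampled_cells, zone)
    confusion_overall = aggregate_confusion(
        food, audits, grid, sampled_cells, zone,
        dist_threshold_m=match_dist_m, name_sim_threshold=match_name_sim,
    )

    corrected = None
    pairs_mc = None
    confusion_mc = None
    if market_polygons is not None:
        corrected = collapse_markets(food, market_polygons)
        pairs_mc = count_by_grid(corrected, audits, grid, sampled_cells, zone)
        confusion_mc = aggregate_confusion(
            corrected, audits, grid, sampled_cells, zone,
            dist_threshold_m=match_dist_m, name_sim_threshold=match_name_sim,
        )

    cat_source = corrected if corrected is not None else food
    pairs_by_cat = {}
    confusion_by_cat = {}
    for cat in FOOD_CATEGORIES:
        pairs_by_cat[cat.value] = count_by_grid(
            cat_source, audits, grid, sampled_cells, zone, category=cat
        )
        confusion_by_cat[cat.value] = aggregate_confusion(
            cat_source, audits, grid, sampled_cells, zone, category=cat,
            dist_threshold_m=match_dist_m, name_sim_threshold=match_name_sim,
        )

    report = run_validation(
        pairs_overall,
        confusion_overall=confusion_overall,
        pairs_market_corrected=pairs_mc,
        confusion_market_corrected=confusion_mc,
        pairs_by_category=pairs_by_cat,
        confusion_by_category=confusion_by_cat,
        alpha_metric=alpha_metric,
    )
    return ValidationOutput(
        report=report,
        pairs_overall=pairs_overall,
        pairs_market_corrected=pairs_mc,
        pairs_by_category=pairs_by_cat,
        confusion_overall=confusion_overall,
        confusion_market_corrected=confusion_mc,
        confusion_by_category=confusion_by_cat,
    )
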