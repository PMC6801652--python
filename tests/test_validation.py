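"""Coder-vs-audit comparison: counts, matching, rates, market correction."""

import pytest
from shapely.geometry import box, mapping

import flcoder as flc
from flcoder.classify import CategoryLabel
from flcoder.geo_grid import GeoPoint, make_grid
from flcoder.validation import (
    AuditRecord,
    ConfusionCounts,
    GridCountPair,
    agreement_rate,
    collapse_markets,
    count_by_grid,
    fp_fn_rates,
    match_confusion,
)

X0, Y0 = 500_000.0, 4_600_000.0
ZONE = flc.utm_zone_for(2.44, 41.54)


def _fac(name, x, y, cat=CategoryLabel.BAR_RESTAURANT):
    lon, lat = flc.from_utm(x, y, ZONE)
    f = flc.FacilityRecord("file", name, name, GeoPoint(lon, lat))
    f.category = cat
    return f


def _audit(name, x, y, grid_id, cat=CategoryLabel.BAR_RESTAURANT):
    lon, lat = flc.from_utm(x, y, ZONE)
    return AuditRecord(name, "", GeoPoint(lon, lat), cat, grid_id)


@pytest.fixture()
def grid3():
    return make_grid(box(X0, Y0, X0 + 300, Y0 + 100), 100.0)  # cells c0_r0..c2_r0


def test_count_by_grid_zero_filled(grid3):
    pairs = count_by_grid([], [], grid3, grid3.cell_ids(), ZONE)
    assert [(p.n_flc, p.n_audit) for p in pairs] == [(0, 0)] * 3


def test_count_by_grid_counts_and_conservation(grid3):
    facs = [_fac("a", X0 + 10, Y0 + 10), _fac("b", X0 + 20, Y0 + 20),
            _fac("out", X0 + 250, Y0 + 50)]
    audits = [_audit("a", X0 + 10, Y0 + 10, "c0_r0"), _audit("b", X0 + 20, Y0 + 20, "c0_r0")]
    sampled = ["c0_r0", "c1_r0"]
    pairs = count_by_grid(facs, audits, grid3, sampled, ZONE)
    assert pairs[0] == GridCountPair("c0_r0", 2, 2)
    assert pairs[0].diff == 0
    assert pairs[1] == GridCountPair("c1_r0", 0, 0)
    # facilities outside the sampled cells are excluded
    assert sum(p.n_flc for p in pairs) == 2


def test_count_by_grid_rejects_unsampled_audit_id(grid3):
    audits = [_audit("a", X0 + 250, Y0 + 50, "c2_r0")]
    with pytest.raises(ValueError, match="not in the sampled"):
        count_by_grid([], audits, grid3, ["c0_r0"], ZONE)


def test_match_confusion_identical_lists():
    facs = [_fac(f"bar {i}", X0 + 10 * i, Y0 + 10) for i in range(4)]
    audits = [_audit(f"bar {i}", X0 + 10 * i, Y0 + 12, "c0_r0") for i in range(4)]
    c = match_confusion(facs, audits)
    assert (c.matched, c.false_positive, c.false_negative) == (4, 0, 0)


def test_match_confusion_extras_and_identities():
    facs = [_fac("bar pepe", X0 + 10, Y0 + 10), _fac("forn nou", X0 + 40, Y0 + 10)]
    audits = [_audit("bar pepe", X0 + 12, Y0 + 10, "c0_r0")]
    c = match_confusion(facs, audits)
    assert c.false_positive == 1 and c.false_negative == 0 and c.matched == 1
    assert c.matched + c.false_positive == len(facs)
    assert c.matched + c.false_negative == len(audits)

    c2 = match_confusion(audits and facs[:1], audits + [_audit("nou extra", X0 + 80, Y0 + 10, "c0_r0")])
    assert c2.false_negative == 1


def test_match_confusion_gates():
    # same name but 200 m away: no match (distance gate)
    far = match_confusion([_fac("bar pepe", X0, Y0)], [_audit("bar pepe", X0 + 200, Y0, "c")])
    assert far.matched == 0
    # close but dissimilar names: no match (name gate)
    diff = match_confusion([_fac("bar pepe", X0, Y0)], [_audit("farmacia creu", X0 + 5, Y0, "c")])
    assert diff.matched == 0


def test_match_confusion_greedy_prefers_best_similarity():
    facs = [_fac("bar pepe", X0 + 10, Y0)]
    audits = [
        _audit("bar pepe granja", X0 + 12, Y0, "c"),  # partial
        _audit("bar pepe", X0 + 30, Y0, "c"),         # exact, further away
    ]
    c = match_confusion(facs, audits)
    assert c.matched == 1 and c.false_negative == 1


def test_match_confusion_random_identities(rng):
    for trial in range(20):
        n_f, n_a = rng.integers(0, 8, 2)
        facs = [_fac(f"bar {i}", X0 + rng.uniform(0, 90), Y0 + rng.uniform(0, 90)) for i in range(n_f)]
        audits = [_audit(f"bar {i}", X0 + rng.uniform(0, 90), Y0 + rng.uniform(0, 90), "c") for i in range(n_a)]
        c = match_confusion(facs, audits)
        assert c.matched + c.false_positive == n_f
        assert c.matched + c.false_negative == n_a
        assert min(c.matched, c.false_positive, c.false_negative) >= 0


def test_fp_fn_rates_definitions():
    assert fp_fn_rates(ConfusionCounts(86, 14, 0))[0] == pytest.approx(0.14)
    assert fp_fn_rates(ConfusionCounts(92, 0, 8))[1] == pytest.approx(0.08)
    fp, fn = fp_fn_rates(ConfusionCounts(0, 0, 0))
    assert fp is None and fn is None


def _market_poly(cx, cy, half=30.0):
    lonlat = [flc.from_utm(x, y, ZONE) for x, y in
              [(cx - half, cy - half), (cx + half, cy - half), (cx + half, cy + half),
               (cx - half, cy + half), (cx - half, cy - half)]]
    return {"type": "Polygon", "coordinates": [[list(p) for p in lonlat]]}


def test_collapse_markets_single_market():
    market = _market_poly(X0 + 50, Y0 + 50)
    inside = [_fac(f"parada {i}", X0 + 40 + i * 4, Y0 + 50, CategoryLabel.CONVENIENCE_OTHER)
              for i in range(5)]
    outside = [_fac("bar fora", X0 + 500, Y0 + 50)]
    out = collapse_markets(inside + outside, [market])
    assert len(out) == 2
    collapsed = [f for f in out if f.tags.get("market") == "collapsed"][0]
    assert collapsed.category == CategoryLabel.CONVENIENCE_OTHER
    assert len(collapsed.merged_from) == 5


def test_collapse_markets_no_members_identity():
    facs = [_fac("bar", X0 + 500, Y0 + 50)]
    out = collapse_markets(facs, [_market_poly(X0 + 50, Y0 + 50)])
    assert out == facs


def test_collapse_markets_two_markets_and_idempotence():
    m1, m2 = _market_poly(X0 + 50, Y0 + 50), _market_poly(X0 + 250, Y0 + 50)
    facs = ([_fac(f"p{i}", X0 + 45 + i, Y0 + 50) for i in range(3)]
            + [_fac(f"q{i}", X0 + 245 + i, Y0 + 50) for i in range(2)])
    out = collapse_markets(facs, [m1, m2])
    assert len(out) == 2
    again = collapse_markets(out, [m1, m2])
    assert len(again) == 2  # idempotent: one facility per market stays one
    assert len(out) <= len(facs)


def test_collapse_markets_modal_category_tie_precedence():
    m = _market_poly(X0 + 50, Y0 + 50)
    facs = [_fac("a", X0 + 45, Y0 + 50, CategoryLabel.BAR_RESTAURANT),
            _fac("b", X0 + 55, Y0 + 50, CategoryLabel.FAST_FOOD)]
    out = collapse_markets(facs, [m])
    assert out[0].category == CategoryLabel.FAST_FOOD  # tie broken by precedence


def test_collapse_markets_overlapping_polygons_rejected():
    m1 = _market_poly(X0 + 50, Y0 + 50)
    m2 = _market_poly(X0 + 70, Y0 + 50)
    with pytest.raises(ValueError, match="overlap"):
        collapse_markets([], [m1, m2])


def test_agreement_rate():
    pairs = [GridCountPair("a", 1, 1), GridCountPair("b", 2, 1), GridCountPair("c", 3, 1)]
    assert agreement_rate(pairs, 0) == pytest.approx(1 / 3)
    assert agreement_rate(pairs, 1) == pytest.approx(2 / 3)
    assert agreement_rate(pairs, 10) == 1.0
    all_equal = [GridCountPair(str(i), 2, 2) for i in range(4)]
    assert agreement_rate(all_equal, 0) == 1.0
    with pytest.raises(ValueError):
        agreement_rate([], 0)


def test_agreement_rate_monotone_in_tolerance(rng):
    pairs = [GridCountPair(str(i), int(rng.integers(0, 6)), int(rng.integers(0, 6)))
             for i in range(100)]
    rates = [agreement_rate(pairs, t) for t in range(6)]
    assert rates == sorted(rates)
    assert rates[-1] == 1.0
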