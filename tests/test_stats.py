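"""Agreement statistics: paired t, Bland-Altman, ICC(A,k), alpha, report."""

import math

import numpy as np
import pytest
from scipy import stats as sps

import flcoder as flc
from flcoder.stats import (
    bland_altman,
    icc_a_k,
    icc_band,
    kripp_alpha,
    paired_t,
    run_validation,
)
from flcoder.validation import ConfusionCounts, GridCountPair


# ---------------------------------------------------------------- paired t

def test_paired_t_hand_computed():
    # diffs (1, 2, 0): mean 1, sd 1 -> t = sqrt(3), df = 2
    r = paired_t([2, 4, 3], [1, 2, 3])
    assert r.t == pytest.approx(math.sqrt(3))
    assert r.df == 2
    assert r.mean_diff == pytest.approx(1.0)
    assert r.sd_diff == pytest.approx(1.0)


def test_paired_t_zero_mean_difference():
    r = paired_t([1, 0, 1, 0], [0, 1, 0, 1])  # diffs (1,-1,1,-1)
    assert r.t == pytest.approx(0.0)
    assert r.df == 3


def test_paired_t_degenerate_cases():
    same = paired_t([2, 3, 4], [2, 3, 4])
    assert same.t == 0.0 and same.flag == "zero-variance"
    shifted = paired_t([3, 4, 5], [2, 3, 4])
    assert math.isinf(shifted.t) and shifted.flag == "degenerate"


def test_paired_t_matches_scipy(rng):
    x = rng.poisson(3, 40).astype(float)
    y = x + rng.normal(0, 1, 40)
    mine = paired_t(x, y)
    ref = sps.ttest_rel(x, y)
    assert mine.t == pytest.approx(ref.statistic, rel=1e-12)
    assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-9)


# ------------------------------------------------------------ Bland-Altman

def test_bland_altman_hand_computed():
    r = bland_altman([2, 4, 3], [1, 2, 3])  # diffs (1,2,0), sd 1
    assert r.bias == pytest.approx(1.0)
    assert r.loa_low == pytest.approx(-0.96)
    assert r.loa_high == pytest.approx(2.96)
    assert r.points[0] == (1.5, 1.0)


def test_bland_altman_identical_methods():
    r = bland_altman([1, 2, 3], [1, 2, 3])
    assert r.bias == r.loa_low == r.loa_high == 0.0


def test_bland_altman_limits_cover_95pct_of_normal_diffs():
    rng = np.random.default_rng(7)
    x = rng.normal(10, 2, 10_000)
    y = x + rng.normal(0.5, 1.0, 10_000)
    r = bland_altman(x, y)
    inside = np.mean([(r.loa_low <= d <= r.loa_high) for _, d in r.points])
    assert inside == pytest.approx(0.95, abs=0.01)


# --------------------------------------------------------------- ICC(A,k)

def test_icc_perfect_agreement():
    r = icc_a_k([[0, 0], [1, 1], [5, 5], [2, 2]])
    assert r.icc == 1.0
    assert r.band == "excellent"
    assert r.ci_high == 1.0


def test_icc_constant_offset_hand_anova():
    # rows (0,1),(1,2),(2,3): MS_R=2, MS_C=1.5, MS_E=0 -> 2/(2+0.5) = 0.8
    r = icc_a_k([[0, 1], [1, 2], [2, 3]])
    assert r.anova.ms_rows == pytest.approx(2.0)
    assert r.anova.ms_cols == pytest.approx(1.5)
    assert r.anova.ms_error == pytest.approx(0.0, abs=1e-12)
    assert r.icc == pytest.approx(0.8)
    # absolute agreement is sensitive to the offset: a consistency ICC would be 1
    assert r.icc < 1.0


def test_icc_invariant_to_shared_shift_not_single_shift(rng):
    t = rng.poisson(3, (30, 2)).astype(float) + rng.normal(0, 0.3, (30, 2))
    base = icc_a_k(t).icc
    both = icc_a_k(t + 5.0).icc
    one = icc_a_k(np.column_stack([t[:, 0] + 5.0, t[:, 1]])).icc
    assert both == pytest.approx(base, abs=1e-10)
    assert one < base


def test_icc_permutation_invariant(rng):
    t = rng.poisson(2, (40, 2)).astype(float)
    t[0, 0] += 1  # ensure non-constant
    perm = rng.permutation(40)
    assert icc_a_k(t[perm]).icc == pytest.approx(icc_a_k(t).icc, rel=1e-12)


def test_icc_errors_and_degenerate():
    with pytest.raises(ValueError, match="3 subjects"):
        icc_a_k([[1, 2], [3, 4]])
    r = icc_a_k([[2, 2], [2, 2], [2, 2]])
    assert r.flag == "zero-variance"
    assert math.isnan(r.icc)


def test_icc_ci_brackets_estimate(rng):
    for _ in range(10):
        t = rng.poisson(3, (25, 2)).astype(float) + rng.normal(0, 0.5, (25, 2))
        r = icc_a_k(t)
        assert r.ci_low <= r.icc <= r.ci_high <= 1.0
        assert r.df1 == 24
        assert r.df2 > 0


def test_icc_satterthwaite_df_generally_non_integer(rng):
    t = rng.poisson(3, (50, 2)).astype(float) + rng.normal(0, 0.5, (50, 2))
    r = icc_a_k(t)
    assert abs(r.df2 - round(r.df2)) > 1e-9


@pytest.mark.parametrize(
    "value,band",
    [(0.933, "excellent"), (0.9, "excellent"), (0.76, "good"), (0.75, "good"),
     (0.5, "moderate"), (0.49, "poor"), (-0.2, "poor")],
)
def test_icc_band_thresholds(value, band):
    assert icc_band(value) == band


def test_icc_matches_independent_reference(rng):
    """Estimate and F cross-checked against an independent ANOVA-based
    implementation; CI and Satterthwaite df against the published
    absolute-agreement interval formulas, on 100 random 50x2 tables."""
    import pandas as pd
    import pingouin as pg

    def reference_ci(t, conf=0.95):
        t = np.asarray(t, float)
        n, k = t.shape
        grand = t.mean()
        msr = k * np.sum((t.mean(1) - grand) ** 2) / (n - 1)
        msc = n * np.sum((t.mean(0) - grand) ** 2) / (k - 1)
        mse = (np.sum((t - grand) ** 2) - (n - 1) * msr - (k - 1) * msc) / ((n - 1) * (k - 1))
        icc1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        fj = msc / mse
        vn = (k - 1) * (n - 1) * (k * icc1 * fj + n * (1 + (k - 1) * icc1) - k * icc1) ** 2
        vd = (n - 1) * k**2 * icc1**2 * fj**2 + (n * (1 + (k - 1) * icc1) - k * icc1) ** 2
        v = vn / vd
        a = 1 - conf
        fu = sps.f.ppf(1 - a / 2, n - 1, v)
        fl = sps.f.ppf(1 - a / 2, v, n - 1)
        lo1 = n * (msr - fu * mse) / (fu * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi1 = n * (fl * msr - mse) / (k * msc + (k * n - k - n) * mse + n * fl * msr)
        return lo1 * k / (1 + (k - 1) * lo1), hi1 * k / (1 + (k - 1) * hi1), v

    rng_local = np.random.default_rng(1234)
    for _ in range(100):
        t = rng_local.poisson(3, (50, 2)) + rng_local.normal(0, 0.5, (50, 2))
        mine = icc_a_k(t)
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(50), 2),
                "raters": np.tile(["flc", "audit"], 50),
                "ratings": t.ravel(),
            }
        )
        row = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="ratings")
        row = row[row.Type == "ICC(A,k)"].iloc[0]
        assert mine.icc == pytest.approx(row.ICC, abs=1e-8)
        assert mine.f_value == pytest.approx(row.F, abs=1e-8)
        lo, hi, v = reference_ci(t)
        assert mine.ci_low == pytest.approx(lo, abs=1e-8)
        assert mine.ci_high == pytest.approx(hi, abs=1e-8)
        assert mine.df2 == pytest.approx(v, abs=1e-8)


# ---------------------------------------------------- Krippendorff's alpha

def test_alpha_identical_columns():
    r = kripp_alpha([[0, 0], [3, 3], [1, 1]])
    assert r.alpha == pytest.approx(1.0)


def test_alpha_hand_coincidence_matrix():
    # units (0,0), (1,1), (0,1): D_o = 1/3, D_e = 3/5 -> alpha = 4/9
    r = kripp_alpha([[0, 0], [1, 1], [0, 1]])
    assert r.alpha == pytest.approx(4 / 9)
    assert r.d_observed == pytest.approx(1 / 3)
    assert r.d_expected == pytest.approx(3 / 5)


def test_alpha_all_values_equal_is_degenerate():
    r = kripp_alpha([[2, 2], [2, 2], [2, 2]])
    assert r.flag == "degenerate"
    assert math.isnan(r.alpha)


def test_alpha_missing_codings_excluded():
    nan = float("nan")
    with_missing = kripp_alpha([[0, 0], [1, 1], [0, 1], [5, nan]])
    complete = kripp_alpha([[0, 0], [1, 1], [0, 1]])
    # the single-coding unit contributes nothing to observed disagreement
    assert with_missing.d_observed == pytest.approx(complete.d_observed)


def test_alpha_nominal_metric():
    # same units, nominal: D_o = 2/6, D_e = (2*3*3)/30 = 3/5 (binary case
    # coincides with interval on 0/1 values)
    r = kripp_alpha([[0, 0], [1, 1], [0, 1]], metric="nominal")
    assert r.alpha == pytest.approx(4 / 9)
    rr = kripp_alpha([[0, 0], [2, 2], [0, 2]], metric="nominal")
    assert rr.alpha == pytest.approx(4 / 9)  # nominal ignores distances
    # with three distinct values a near-miss (0 vs 1) is mild for the
    # interval metric but a full disagreement for the nominal one
    table = [[0, 0], [10, 10], [0, 1]]
    assert kripp_alpha(table, "interval").alpha > kripp_alpha(table, "nominal").alpha


def test_alpha_permutation_invariant(rng):
    t = rng.poisson(2, (40, 2)).astype(float)
    t[0, 0] += 3
    perm = rng.permutation(40)
    assert kripp_alpha(t[perm]).alpha == pytest.approx(kripp_alpha(t).alpha, rel=1e-12)


def test_alpha_unknown_metric_rejected():
    with pytest.raises(ValueError, match="metric"):
        kripp_alpha([[0, 1], [1, 0]], metric="ordinal")


# ------------------------------------------------------- report assembly

def _pairs(xs, ys):
    return [GridCountPair(f"g{i}", x, y) for i, (x, y) in enumerate(zip(xs, ys))]


def test_run_validation_perfect_agreement():
    pairs = _pairs([0, 1, 2, 3, 0], [0, 1, 2, 3, 0])
    rep = run_validation(pairs, confusion_overall=ConfusionCounts(6, 0, 0))
    s = rep.strata[0]
    assert s.icc.icc == 1.0
    assert s.alpha.alpha == pytest.approx(1.0)
    assert s.fp_rate == 0.0
    assert rep.paired.t == 0.0
    assert rep.agreement_tol0 == 1.0


def test_run_validation_equals_component_operations(rng):
    x = rng.poisson(1, 30)
    y = rng.poisson(1, 30)
    pairs = _pairs(x, y)
    rep = run_validation(pairs)
    table = np.column_stack([x, y]).astype(float)
    assert rep.strata[0].icc.icc == pytest.approx(icc_a_k(table).icc)
    assert rep.strata[0].alpha.alpha == pytest.approx(kripp_alpha(table).alpha)
    assert rep.paired.t == pytest.approx(paired_t(x, y).t)
    assert rep.bland_altman.bias == pytest.approx(bland_altman(x, y).bias)


def test_run_validation_report_schema():
    pairs = _pairs([0, 1, 2, 1], [0, 1, 2, 2])
    by_cat = {"fast_food": pairs, "bar_restaurant": pairs}
    rep = run_validation(pairs, pairs_market_corrected=pairs, pairs_by_category=by_cat,
                         confusion_overall=ConfusionCounts(3, 1, 1))
    d = rep.to_dict()
    assert [s["stratum"] for s in d["strata"]] == [
        "overall", "overall_market_corrected", "fast_food", "bar_restaurant"]
    expected_keys = {"stratum", "n_grids", "icc", "ci_low", "ci_high", "f_value",
                     "df1", "df2", "p_value", "band", "icc_flag",
                     "krippendorff_alpha", "alpha_metric", "alpha_flag",
                     "fp_rate", "fn_rate"}
    assert set(d["strata"][0]) == expected_keys
    rows = rep.to_csv_rows()
    assert rows[0] == list(rep.CSV_COLUMNS)
    assert len(rows) == 5


def test_run_validation_small_stratum_skipped(caplog):
    import logging

    pairs = _pairs([0, 1, 2, 1], [0, 1, 2, 2])
    tiny = {"supermarket": _pairs([1], [1])}
    with caplog.at_level(logging.WARNING):
        rep = run_validation(pairs, pairs_by_category=tiny)
    assert [s.stratum for s in rep.strata] == ["overall"]
    assert any("skipped" in r.message for r in caplog.records)


def test_significance_formatting():
    pairs = _pairs(list(range(10)), list(range(10)))
    rep = run_validation(pairs)
    rows = rep.to_csv_rows()
    sig = rows[1][rows[0].index("significance")]
    assert sig == "0.000"  # printed to 3 decimals; means < 0.0005


def test_icc_decreases_with_noise_variance():
    """More audit-independent count noise means lower reliability,
    monotone over averaged seeds."""
    sds = [0.2, 0.6, 1.2, 2.4]
    means = []
    for sd in sds:
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(10_000 + seed)
            y = rng.poisson(1.0, 200).astype(float)
            x = y + rng.normal(0, sd, 200)
            vals.append(icc_a_k(np.column_stack([x, y])).icc)
        means.append(np.mean(vals))
    assert means == sorted(means, reverse=True)
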