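"""Agreement statistics for the coder-vs-audit comparison.

Two "raters" -- the automatic coder and the street audit -- each count
facilities in the same n grid cells.  Validity is probed with a paired
t-test (systematic difference) and a Bland-Altman analysis (bias and
1.96-SD limits of agreement); reliability with the intraclass
correlation ICC(A,k): mean-rating (k = 2), absolute-agreement, two-way
mixed-effects model, plus Krippendorff's alpha, which corrects for
chance agreement and is robust to the many all-zero cells of a sparse
urban grid.

ICC notation follows the McGraw-Wong two-way ANOVA decomposition with
rows = grid cells and columns = methods: MS_R (between rows), MS_C
(between columns), MS_E (residual),

    ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E)/n)
    ICC(A,k) = (MS_R - MS_E) / (MS_R + (MS_C - MS_E)/n)

The F test against a true value of 0 uses F = MS_R/MS_E with df1 = n-1;
the confidence interval (and the reported denominator df) uses the
Satterthwaite approximation, which is why df2 is generally non-integer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "PairedTestResult",
    "BlandAltmanResult",
    "AnovaDecomposition",
    "IccResult",
    "AlphaResult",
    "StratumResult",
    "ValidationReport",
    "paired_t",
    "bland_altman",
    "icc_a_k",
    "icc_band",
    "kripp_alpha",
    "run_validation",
]


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p_value: float
    mean_diff: float
    sd_diff: float
    n: int
    flag: Optional[str] = None  # "zero-variance" / "degenerate"


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    points: tuple  # ((mean, diff), ...) per pair


@dataclass(frozen=True)
class AnovaDecomposition:
    n: int
    k: int
    ms_rows: float
    ms_cols: float
    ms_error: float


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    f_value: float
    df1: float
    df2: float
    p_value: float
    band: Optional[str]
    anova: AnovaDecomposition
    flag: Optional[str] = None  # "zero-variance" when the table is constant


@dataclass(frozen=True)
class AlphaResult:
    alpha: float
    d_observed: float
    d_expected: float
    metric: str
    flag: Optional[str] = None  # "degenerate" when D_e = 0


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedTestResult:
    """Two-sided paired t-test on per-cell counts from the two methods.

    The standard deviation of the differences uses the n-1 denominator.
    A zero-variance difference vector is flagged instead of raising:
    t = 0 when the mean difference is also 0, infinite t otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = x.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    df = n - 1
    if sd_d == 0.0:
        if mean_d == 0.0:
            return PairedTestResult(0.0, df, 1.0, 0.0, 0.0, n, flag="zero-variance")
        t = math.inf if mean_d > 0 else -math.inf
        return PairedTestResult(t, df, 0.0, mean_d, 0.0, n, flag="degenerate")
    t = mean_d / (sd_d / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return PairedTestResult(float(t), df, p, mean_d, sd_d, n)


def bland_altman(x: Sequence[float], y: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman agreement: bias and 1.96-SD limits of agreement.

    Points are ((x+y)/2, x-y) per pair, the usual mean-vs-difference
    plot coordinates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D sequences with n >= 2")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    pts = tuple(zip(((x + y) / 2.0).tolist(), d.tolist()))
    return BlandAltmanResult(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd, pts)


def bland_altman_plot(result: BlandAltmanResult, path: str) -> None:
    """Write the mean-vs-difference diagram to ``path`` (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means, diffs = zip(*result.points)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=12, alpha=0.6)
    for yv, style in ((result.bias, "-"), (result.loa_low, "--"), (result.loa_high, "--")):
        ax.axhline(yv, linestyle=style, color="grey")
    ax.set_xlabel("mean of methods per cell")
    ax.set_ylabel("difference (coder - audit)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _two_way_anova(table: np.ndarray) -> AnovaDecomposition:
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((table - grand) ** 2).sum())
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    return AnovaDecomposition(
        n=n,
        k=k,
        ms_rows=ss_rows / (n - 1),
        ms_cols=ss_cols / (k - 1) if k > 1 else 0.0,
        ms_error=ss_err / ((n - 1) * (k - 1)) if k > 1 else 0.0,
    )


def icc_a_k(table, conf: float = 0.95) -> IccResult:
    """Absolute-agreement, average-measures intraclass correlation.

    ``table`` is the complete n x k matrix of counts (rows = grid cells,
    columns = methods; k = 2 in the validation design).  Returns the
    ICC(A,k) estimate, its confidence interval (single-measure interval
    with Satterthwaite denominator df, Spearman-Brown stepped up to k),
    the F statistic for the test against a true value of 0, and the
    qualitative reliability band.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValueError("table must be n x k with k >= 2")
    n, k = table.shape
    if n < 3:
        raise ValueError("need at least 3 subjects (grid cells)")
    if np.isnan(table).any():
        raise ValueError("table must be complete (no missing entries)")

    an = _two_way_anova(table)
    msr, msc, mse = an.ms_rows, an.ms_cols, an.ms_error

    if msr == 0.0 and msc == 0.0 and mse == 0.0:
        nan = float("nan")
        return IccResult(nan, nan, nan, nan, n - 1, nan, nan, None, an, flag="zero-variance")

    den_k = msr + (msc - mse) / n
    icc_k = (msr - mse) / den_k if den_k != 0 else float("nan")
    den_1 = msr + (k - 1) * mse + k * (msc - mse) / n
    icc_1 = (msr - mse) / den_1 if den_1 != 0 else float("nan")

    # F test with true value 0
    f_value = msr / mse if mse > 0 else math.inf
    df1 = n - 1

    # Satterthwaite denominator df, evaluated at the single-measure estimate
    if math.isfinite(icc_1) and icc_1 < 1.0:
        a = k * icc_1 / (n * (1.0 - icc_1))
        b = 1.0 + k * icc_1 * (n - 1) / (n * (1.0 - icc_1))
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        df2 = num / den if den > 0 else float((n - 1) * (k - 1))
    else:
        df2 = float((n - 1) * (k - 1))
    p_value = float(sps.f.sf(f_value, df1, df2)) if math.isfinite(f_value) else 0.0

    alpha = 1.0 - conf
    fl = float(sps.f.ppf(1.0 - alpha / 2.0, df1, df2))
    fu = float(sps.f.ppf(1.0 - alpha / 2.0, df2, df1))
    lo1 = n * (msr - fl * mse) / (fl * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi1 = n * (fu * msr - mse) / (k * msc + (k * n - k - n) * mse + n * fu * msr)
    lo_k = lo1 * k / (1.0 + (k - 1) * lo1)
    hi_k = hi1 * k / (1.0 + (k - 1) * hi1)

    icc_k = min(icc_k, 1.0)
    return IccResult(
        icc=float(icc_k),
        ci_low=float(min(lo_k, icc_k)),
        ci_high=float(min(max(hi_k, icc_k), 1.0)),
        f_value=float(f_value),
        df1=float(df1),
        df2=float(df2),
        p_value=p_value,
        band=icc_band(icc_k),
        anova=an,
    )


def icc_band(icc: float) -> Optional[str]:
    """Qualitative reliability band for an ICC estimate.

    < 0.5 poor; [0.5, 0.75) moderate; [0.75, 0.9) good; >= 0.9
    excellent.  Boundary values are assigned to the higher band.
    """
    if not math.isfinite(icc):
        return None
    if icc >= 0.9:
        return "excellent"
    if icc >= 0.75:
        return "good"
    if icc >= 0.5:
        return "moderate"
    return "poor"


_METRICS = {
    "interval": lambda v, w: (v - w) ** 2,
    "ratio": lambda v, w: ((v - w) / (v + w)) ** 2 if (v + w) != 0 else 0.0,
    "nominal": lambda v, w: 0.0 if v == w else 1.0,
}


def kripp_alpha(table, metric: str = "interval") -> AlphaResult:
    """Krippendorff's alpha from the coincidence-matrix definition.

    ``table`` is n units x k coders with NaN marking missing codings;
    units with fewer than two codings contribute nothing to the observed
    disagreement.  alpha = 1 - D_o / D_e, where D_o is the observed and
    D_e the expected disagreement under the chosen difference metric
    (interval by default, since facility counts are numeric; ratio and
    nominal are available).
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {sorted(_METRICS)}")
    delta = _METRICS[metric]
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be 2-D (units x coders)")

    units = [row[~np.isnan(row)] for row in table]
    pairable = [u for u in units if u.size >= 2]
    if len(pairable) < 2:
        raise ValueError("need at least two units with two or more codings")

    values = np.concatenate(pairable)
    n_total = values.size
    vals, counts = np.unique(values, return_counts=True)
    index = {v: i for i, v in enumerate(vals)}

    coincidence = np.zeros((vals.size, vals.size))
    for u in pairable:
        m = u.size
        for i in range(m):
            for j in range(m):
                if i != j:
                    coincidence[index[u[i]], index[u[j]]] += 1.0 / (m - 1)

    dmat = np.array([[delta(v, w) for w in vals] for v in vals])
    d_obs = float((coincidence * dmat).sum()) / n_total
    d_exp = float((np.outer(counts, counts) * dmat).sum()) / (n_total * (n_total - 1))

    if d_exp == 0.0:
        return AlphaResult(float("nan"), d_obs, 0.0, metric, flag="degenerate")
    return AlphaResult(1.0 - d_obs / d_exp, d_obs, d_exp, metric)


@dataclass(frozen=True)
class StratumResult:
    stratum: str
    n_grids: int
    icc: IccResult
    alpha: AlphaResult
    fp_rate: Optional[float]
    fn_rate: Optional[float] = None


@dataclass
class ValidationReport:
    """Everything the validation tables report, per stratum.

    Strata are "overall", "overall_market_corrected" and one per food
    category (market-corrected); each carries ICC(A,2) with CI/F/dfs,
    Krippendorff's alpha and the false-positive rate.  The overall
    descriptives (paired t, Bland-Altman, exact and +/-1-tolerance
    agreement rates) are attached once.
    """

    strata: list
    paired: Optional[PairedTestResult] = None
    bland_altman: Optional[BlandAltmanResult] = None
    agreement_tol0: Optional[float] = None
    agreement_tol1: Optional[float] = None

    CSV_COLUMNS = (
        "stratum",
        "n_grids",
        "icc",
        "ci_low",
        "ci_high",
        "f_value",
        "df1",
        "df2",
        "significance",
        "band",
        "krippendorff_alpha",
        "fp_rate",
    )

    def to_dict(self) -> dict:
        def _num(v):
            if v is None:
                return None
            return None if isinstance(v, float) and not math.isfinite(v) else v

        out: dict = {"strata": [], "descriptives": {}}
        for s in self.strata:
            out["strata"].append(
                {
                    "stratum": s.stratum,
                    "n_grids": s.n_grids,
                    "icc": _num(s.icc.icc),
                    "ci_low": _num(s.icc.ci_low),
                    "ci_high": _num(s.icc.ci_high),
                    "f_value": _num(s.icc.f_value),
                    "df1": _num(s.icc.df1),
                    "df2": _num(s.icc.df2),
                    "p_value": _num(s.icc.p_value),
                    "band": s.icc.band,
                    "icc_flag": s.icc.flag,
                    "krippendorff_alpha": _num(s.alpha.alpha),
                    "alpha_metric": s.alpha.metric,
                    "alpha_flag": s.alpha.flag,
                    "fp_rate": _num(s.fp_rate),
                    "fn_rate": _num(s.fn_rate),
                }
            )
        if self.paired is not None:
            out["descriptives"]["paired_t"] = {
                "t": _num(self.paired.t),
                "df": self.paired.df,
                "p_value": _num(self.paired.p_value),
                "mean_diff": _num(self.paired.mean_diff),
                "sd_diff": _num(self.paired.sd_diff),
                "flag": self.paired.flag,
            }
        if self.bland_altman is not None:
            out["descriptives"]["bland_altman"] = {
                "bias": self.bland_altman.bias,
                "sd_diff": self.bland_altman.sd_diff,
                "loa_low": self.bland_altman.loa_low,
                "loa_high": self.bland_altman.loa_high,
            }
        out["descriptives"]["agreement_rate_tol0"] = _num(self.agreement_tol0)
        out["descriptives"]["agreement_rate_tol1"] = _num(self.agreement_tol1)
        return out

    def to_csv_rows(self) -> list:
        """Rows mirroring the validation-table layout; significance to 3
        decimals ("0.000" means < 0.0005)."""
        rows = [list(self.CSV_COLUMNS)]
        for s in self.strata:
            rows.append(
                [
                    s.stratum,
                    s.n_grids,
                    _fmt(s.icc.icc),
                    _fmt(s.icc.ci_low),
                    _fmt(s.icc.ci_high),
                    _fmt(s.icc.f_value, 2),
                    _fmt(s.icc.df1, 0),
                    _fmt(s.icc.df2, 0),
                    _fmt(s.icc.p_value),
                    s.icc.band or "",
                    _fmt(s.alpha.alpha),
                    _fmt(s.fp_rate),
                ]
            )
        return rows


def _fmt(v, digits: int = 3) -> str:
    if v is None or (isinstance(v, float) and not math.isfinite(v)):
        return ""
    return f"{v:.{digits}f}"


def run_validation(
    pairs_overall,
    confusion_overall=None,
    pairs_market_corrected=None,
    confusion_market_corrected=None,
    pairs_by_category: Optional[Dict] = None,
    confusion_by_category: Optional[Dict] = None,
    alpha_metric: str = "interval",
) -> ValidationReport:
    """Assemble the full validation report from per-grid count pairs.

    Every stratum gets ICC(A,2), Krippendorff's alpha and the FP/FN
    rates; the overall stratum additionally drives the paired t-test,
    the Bland-Altman limits and the agreement rates at tolerance 0 and
    1.  Strata with fewer than 3 cells are skipped with a warning.
    """
    from .validation import agreement_rate, fp_fn_rates  # cycle-free late import

    strata: list[StratumResult] = []

    def _add(name: str, pairs, confusion) -> None:
        if pairs is None:
            return
        pairs = list(pairs)
        if len(pairs) < 3:
            logger.warning("stratum %s has %d < 3 grids; skipped", name, len(pairs))
            return
        table = np.array([[p.n_flc, p.n_audit] for p in pairs], dtype=float)
        icc = icc_a_k(table)
        alpha = kripp_alpha(table, metric=alpha_metric)
        fp = fn = None
        if confusion is not None:
            fp, fn = fp_fn_rates(confusion)
        strata.append(StratumResult(name, len(pairs), icc, alpha, fp, fn))

    _add("overall", pairs_overall, confusion_overall)
    _add("overall_market_corrected", pairs_market_corrected, confusion_market_corrected)
    for cat, pairs in (pairs_by_category or {}).items():
        conf = (confusion_by_category or {}).get(cat)
        _add(str(cat), pairs, conf)

    pairs = list(pairs_overall)
    x = [p.n_flc for p in pairs]
    y = [p.n_audit for p in pairs]
    return ValidationReport(
        strata=strata,
        paired=paired_t(x, y) if len(pairs) >= 2 else None,
        bland_altman=bland_altman(x, y) if len(pairs) >= 2 else None,
        agreement_tol0=agreement_rate(pairs, 0) if pairs else None,
        agreement_tol1=agreement_rate(pairs, 1) if pairs else None,
    )
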