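"""Nonparametric group comparisons and distribution summaries.

The measurement distributions (d², fractional radius) are skewed, so group
contrasts use rank tests throughout: a two-sample Mann-Whitney U test
between tissue regions or conditions, and a paired Wilcoxon signed-rank
test across explant pairs.  Exact p-values are computed by integer counting
of the null distribution (all C(n1+n2, n1) rank arrangements for U; all 2^n
sign patterns for W) whenever samples are small and tie-free; otherwise the
normal approximation with tie and continuity corrections is used.  Box
summaries follow the whiskers-to-extremes convention (no outlier trimming);
quartiles use linear interpolation between order statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MeasurementGroup",
    "GroupComparison",
    "PairedComparison",
    "BoxSummary",
    "RadialDistribution",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "box_summary",
    "radial_distribution",
    "compare_design",
    "select_group",
]

#: Largest pooled sample for which the exact Mann-Whitney null is enumerated.
EXACT_MWU_MAX_N = 20
#: Largest number of non-zero pairs for which the exact Wilcoxon null is used.
EXACT_WILCOXON_MAX_N = 15


@dataclass
class MeasurementGroup:
    label: str
    values: np.ndarray
    embryo_ids: Optional[Sequence] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size < 1:
            raise ValueError(f"group {self.label!r} is empty")
        if not np.isfinite(self.values).all():
            raise ValueError(f"group {self.label!r} has non-finite values")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class GroupComparison:
    label_x: str
    label_y: str
    statistic_U: float
    n1: int
    n2: int
    p_two_sided: float
    median_x: float
    median_y: float
    method: str  # exact | normal_approx
    u_less: float = math.nan  # unfolded U = #{x_i < y_j} + ties/2


@dataclass
class PairedComparison:
    label_x: str
    label_y: str
    statistic_W: float
    n_nonzero: int
    p_two_sided: float
    method: str


@dataclass
class BoxSummary:
    """Five-number summary; whiskers are the data extremes."""

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float


@dataclass
class RadialDistribution:
    bin_edges: np.ndarray
    frequency: np.ndarray   # relative frequencies, sum to 1
    ecdf_x: np.ndarray
    ecdf_y: np.ndarray


# ---------------------------------------------------------------------------
# Exact null distributions (integer counting)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _mwu_count(m: int, n: int, u: int) -> int:
    """Number of rank arrangements of m x's among m+n values with U = u,
    where U counts (x, y) pairs with x ranked below y.

    Classic recursion: condition on whether the largest value is an x
    (contributes n to U) or a y.
    """
    if u < 0 or u > m * n:
        return 0
    if m == 0 or n == 0:
        return 1 if u == 0 else 0
    return _mwu_count(m - 1, n, u - n) + _mwu_count(m, n - 1, u)


def _mwu_exact_p(m: int, n: int, u_obs: int) -> float:
    total = math.comb(m + n, m)
    cdf_le = sum(_mwu_count(m, n, u) for u in range(0, u_obs + 1))
    cdf_ge = sum(_mwu_count(m, n, u) for u in range(u_obs, m * n + 1))
    p = 2 * Fraction(min(cdf_le, cdf_ge), total)
    return float(min(p, Fraction(1)))


def _wilcoxon_counts(n: int):
    """Counts of W = sum of 'positive' ranks over all 2^n sign patterns."""
    poly = [1]
    for r in range(1, n + 1):
        new = [0] * (len(poly) + r)
        for w, c in enumerate(poly):
            new[w] += c
            new[w + r] += c
        poly = new
    return poly


def _wilcoxon_exact_p(n: int, w_obs: int) -> float:
    counts = _wilcoxon_counts(n)
    total = 2 ** n
    cdf_le = sum(counts[: w_obs + 1])
    cdf_ge = sum(counts[w_obs:])
    p = 2 * Fraction(min(cdf_le, cdf_ge), total)
    return float(min(p, Fraction(1)))


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def mann_whitney_u(x, y, label_x: str = "x", label_y: str = "y",
                   method: str = "auto") -> GroupComparison:
    """Two-sample Mann-Whitney U test (two-sided).

    U counts the (x_i, y_j) pairs with x_i < y_j (plus ½ per tie); the
    reported statistic is the folded min(U, n1·n2 − U).  The exact two-sided
    p-value, 2·min(P(U ≤ obs), P(U ≥ obs)) capped at 1, is enumerated when
    n1 + n2 <= 20 and the pooled sample is tie-free; otherwise the normal
    approximation with tie and continuity corrections is used.  ``method``
    can force ``"exact"`` or ``"normal_approx"``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = ranks[:n1].sum()
    u_greater = r_x - n1 * (n1 + 1) / 2.0   # #{x > y} + ties/2
    u_less = n1 * n2 - u_greater            # #{x < y} + ties/2
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    if method == "auto":
        use_exact = (n1 + n2 <= EXACT_MWU_MAX_N) and not has_ties
    elif method == "exact":
        if has_ties:
            raise ValueError("exact Mann-Whitney p is undefined with ties")
        use_exact = True
    elif method == "normal_approx":
        use_exact = False
    else:
        raise ValueError("method must be auto|exact|normal_approx")
    if use_exact:
        p = _mwu_exact_p(n1, n2, int(round(u_less)))
        used = "exact"
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        tie_term = ((tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
                    if n > 1 else 0.0)
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            raise ValueError("all pooled values identical; test undefined")
        # continuity correction: shrink |U - mu| by 1/2
        z = (u_less - mu - 0.5 * np.sign(u_less - mu)) / math.sqrt(sigma2)
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        used = "normal_approx"
    return GroupComparison(
        label_x=label_x, label_y=label_y,
        statistic_U=float(min(u_less, n1 * n2 - u_less)),
        n1=n1, n2=n2, p_two_sided=float(p),
        median_x=float(np.median(x)), median_y=float(np.median(y)),
        method=used, u_less=float(u_less),
    )


def wilcoxon_signed_rank(before, after=None, label_x: str = "before",
                         label_y: str = "after",
                         method: str = "auto") -> PairedComparison:
    """Paired Wilcoxon signed-rank test (two-sided).

    Call with two paired sequences, or with a single sequence of
    differences.  Zero differences are dropped; |differences| are mid-ranked;
    W is the sum of ranks of positive differences.  Exact p by sign-pattern
    enumeration when n_nonzero <= 15 and no |difference| is tied, else the
    normal approximation with tie and continuity corrections.
    """
    before = np.asarray(before, dtype=np.float64)
    diffs = (np.asarray(after, dtype=np.float64) - before
             if after is not None else before)
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        raise ValueError("all differences are zero: no information")
    absd = np.abs(diffs)
    ranks = sps.rankdata(absd)
    w_pos = float(ranks[diffs > 0].sum())
    _, tie_counts = np.unique(absd, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    if method == "auto":
        use_exact = n <= EXACT_WILCOXON_MAX_N and not has_ties
    elif method == "exact":
        if has_ties:
            raise ValueError("exact Wilcoxon p is undefined with tied |differences|")
        use_exact = True
    elif method == "normal_approx":
        use_exact = False
    else:
        raise ValueError("method must be auto|exact|normal_approx")
    if use_exact:
        p = _wilcoxon_exact_p(n, int(round(w_pos)))
        used = "exact"
    else:
        mu = n * (n + 1) / 4.0
        sigma2 = (n * (n + 1) * (2 * n + 1)
                  - 0.5 * (tie_counts ** 3 - tie_counts).sum()) / 24.0
        z = (w_pos - mu - 0.5 * np.sign(w_pos - mu)) / math.sqrt(sigma2)
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        used = "normal_approx"
    return PairedComparison(label_x=label_x, label_y=label_y,
                            statistic_W=w_pos, n_nonzero=n,
                            p_two_sided=float(p), method=used)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def box_summary(values) -> BoxSummary:
    """Five-number box summary with whiskers at the data extremes."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty sample")
    mn, q1, med, q3, mx = np.percentile(v, [0, 25, 50, 75, 100])
    return BoxSummary(float(mn), float(q1), float(med), float(q3), float(mx))


def radial_distribution(values, bins: int = 10) -> RadialDistribution:
    """Relative-frequency polygon over equal-width bins on [0, 1] + ECDF."""
    v = np.asarray(values, dtype=np.float64)
    if bins < 2:
        raise ValueError("need at least 2 bins")
    if v.size == 0:
        raise ValueError("empty sample")
    if (v < 0).any() or (v > 1).any():
        raise ValueError("fractional radii outside [0, 1]; flag or filter first")
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts, _ = np.histogram(v, bins=edges)
    xs = np.sort(v)
    ys = np.arange(1, v.size + 1) / v.size
    return RadialDistribution(bin_edges=edges,
                              frequency=counts / counts.sum(),
                              ecdf_x=xs, ecdf_y=ys)


# ---------------------------------------------------------------------------
# Figure-level comparison plans
# ---------------------------------------------------------------------------

def select_group(table: pd.DataFrame, selector, metric: str) -> MeasurementGroup:
    """Extract a MeasurementGroup from a measurement table.

    ``selector`` is either a region label or a dict of column -> value
    (e.g. ``{"region": "stem_zone", "condition": "control"}``).
    """
    if isinstance(selector, str):
        selector = {"region": selector}
    mask = np.ones(len(table), dtype=bool)
    for col, val in selector.items():
        if col not in table.columns:
            raise KeyError(f"no column {col!r} in measurement table")
        mask &= (table[col] == val).to_numpy()
    sub = table[mask]
    if sub.empty:
        avail = sorted(table[list(selector)[0] if isinstance(selector, dict)
                             else "region"].unique().tolist())
        raise KeyError(f"no rows match {selector}; available: {avail}")
    label = "/".join(str(v) for v in selector.values())
    return MeasurementGroup(label, sub[metric].to_numpy(),
                            embryo_ids=sub["embryo_id"].tolist()
                            if "embryo_id" in sub else None)


def compare_design(table: pd.DataFrame, plan, correction: str = "none") -> pd.DataFrame:
    """Run a list of planned two-group contrasts on a measurement table.

    Each plan row is a mapping with keys ``metric`` (column name),
    ``group_a``/``group_b`` (selectors for :func:`select_group`), and the
    optional booleans ``paired`` (explant-pair design: a Wilcoxon
    signed-rank on per-pair medians, pairing arms on embryo_id, plus one
    Mann-Whitney row per individual pair) and ``per_embryo`` (additional
    embryo-stratified Mann-Whitney rows).  Multiplicity handling defaults to
    none (each contrast reported raw); ``correction="holm"`` appends
    Holm-adjusted p-values across all report rows.
    """
    rows = []
    for item in plan:
        metric = item["metric"]
        ga = select_group(table, item["group_a"], metric)
        gb = select_group(table, item["group_b"], metric)
        if item.get("paired"):
            rows.extend(_paired_rows(table, item, metric, ga, gb))
        else:
            cmpres = mann_whitney_u(ga.values, gb.values, ga.label, gb.label)
            rows.append(_mwu_row(metric, cmpres, stratum="pooled"))
            if item.get("per_embryo"):
                rows.extend(_per_embryo_rows(table, item, metric))
    report = pd.DataFrame(rows)
    if correction == "holm" and not report.empty:
        from statsmodels.stats.multitest import multipletests
        report["p_holm"] = multipletests(report["p_two_sided"], method="holm")[1]
    elif correction != "none":
        raise ValueError("correction must be 'none' or 'holm'")
    return report


def _mwu_row(metric, c: GroupComparison, stratum: str):
    return dict(metric=metric, test="mann_whitney_u", stratum=stratum,
                group_a=c.label_x, group_b=c.label_y, n1=c.n1, n2=c.n2,
                statistic=c.statistic_U, p_two_sided=c.p_two_sided,
                median_a=c.median_x, median_b=c.median_y, method=c.method)


def _per_embryo_rows(table, item, metric):
    rows = []
    sel_a = item["group_a"] if isinstance(item["group_a"], dict) else {"region": item["group_a"]}
    sel_b = item["group_b"] if isinstance(item["group_b"], dict) else {"region": item["group_b"]}
    embryos = sorted(set(table["embryo_id"]))
    for e in embryos:
        try:
            ga = select_group(table[table["embryo_id"] == e], sel_a, metric)
            gb = select_group(table[table["embryo_id"] == e], sel_b, metric)
        except KeyError:
            continue
        c = mann_whitney_u(ga.values, gb.values, ga.label, gb.label)
        rows.append(_mwu_row(metric, c, stratum=f"embryo:{e}"))
    return rows


def _paired_rows(table, item, metric, ga: MeasurementGroup, gb: MeasurementGroup):
    """Explant-pair analysis: Wilcoxon on per-pair medians + per-pair MWU."""
    pa = pd.Series(ga.values).groupby(pd.Series(ga.embryo_ids)).median()
    pb = pd.Series(gb.values).groupby(pd.Series(gb.embryo_ids)).median()
    common = sorted(set(pa.index) & set(pb.index))
    if len(common) < 1:
        raise ValueError("paired design: no common pair ids between arms")
    w = wilcoxon_signed_rank(pa[common].to_numpy(), pb[common].to_numpy(),
                             ga.label, gb.label)
    rows = [dict(metric=metric, test="wilcoxon_signed_rank", stratum="pairs",
                 group_a=ga.label, group_b=gb.label,
                 n1=w.n_nonzero, n2=w.n_nonzero, statistic=w.statistic_W,
                 p_two_sided=w.p_two_sided,
                 median_a=float(np.median(ga.values)),
                 median_b=float(np.median(gb.values)), method=w.method)]
    sa = pd.Series(ga.values, index=pd.Index(ga.embryo_ids))
    sb = pd.Series(gb.values, index=pd.Index(gb.embryo_ids))
    for pair_id in common:
        c = mann_whitney_u(np.atleast_1d(sa[pair_id]), np.atleast_1d(sb[pair_id]),
                           ga.label, gb.label)
        rows.append(_mwu_row(metric, c, stratum=f"pair:{pair_id}"))
    return rows
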