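"""Rank tests against brute-force enumeration oracles, summaries, and
comparison plans."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from fishloc.stats import (box_summary, compare_design, mann_whitney_u,
                           radial_distribution, select_group,
                           wilcoxon_signed_rank)


# ---------------------------------------------------------------------------
# Enumeration oracles (independent of the implementation)
# ---------------------------------------------------------------------------

def mwu_enumeration_p(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all rank arrangements."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    u_obs = sum(1 for xi in x for yj in y if xi < yj)
    counts = {}
    for xpos in itertools.combinations(range(n), n1):
        xset = set(xpos)
        u = sum(1 for p in xpos for q in range(n) if q not in xset and q > p)
        counts[u] = counts.get(u, 0) + 1
    total = math.comb(n, n1)
    cle = sum(c for u, c in counts.items() if u <= u_obs)
    cge = sum(c for u, c in counts.items() if u >= u_obs)
    return float(min(2 * Fraction(min(cle, cge), total), Fraction(1)))


def wilcoxon_enumeration_p(diffs):
    """Two-sided exact Wilcoxon p by enumerating all sign patterns."""
    diffs = np.asarray(diffs, float)
    diffs = diffs[diffs != 0]
    n = len(diffs)
    ranks = sps.rankdata(np.abs(diffs)).astype(int)
    w_obs = int(ranks[diffs > 0].sum())
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([0, 1], repeat=n)]
    cle = sum(1 for w in ws if w <= w_obs)
    cge = sum(1 for w in ws if w >= w_obs)
    return float(min(2 * Fraction(min(cle, cge), 2 ** n), Fraction(1)))


class TestMannWhitney:
    def test_fully_separated_small_sample(self):
        c = mann_whitney_u([1, 2], [3, 4])
        assert c.statistic_U == 0
        assert c.p_two_sided == pytest.approx(1 / 3)
        assert c.method == "exact"

    def test_interleaved_small_sample(self):
        c = mann_whitney_u([1, 3], [2, 4])
        assert c.u_less == 3  # 3 of 4 pairs have x < y; folded U = 1
        assert c.statistic_U == 1
        assert c.p_two_sided == pytest.approx(2 / 3)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=6), rng.normal(0.5, 1, size=5)
        a = mann_whitney_u(x, y)
        b = mann_whitney_u(y, x)
        assert a.u_less + b.u_less == a.n1 * a.n2
        assert a.p_two_sided == b.p_two_sided
        assert a.statistic_U == b.statistic_U

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            n1, n2 = rng.integers(1, 6, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            assert mann_whitney_u(x, y).p_two_sided == mwu_enumeration_p(x, y)

    def test_normal_approx_close_to_exact(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            n1, n2 = rng.integers(4, 11, size=2)
            x, y = rng.normal(size=n1), rng.normal(0.3, 1, size=n2)
            pe = mann_whitney_u(x, y, method="exact").p_two_sided
            pa = mann_whitney_u(x, y, method="normal_approx").p_two_sided
            assert abs(pe - pa) < 0.05

    def test_monotone_invariance_d_vs_d_squared(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            d1 = rng.gamma(2, 0.2, size=rng.integers(3, 30))
            d2 = rng.gamma(2, 0.3, size=rng.integers(3, 30))
            assert (mann_whitney_u(d1, d2).p_two_sided
                    == mann_whitney_u(d1 ** 2, d2 ** 2).p_two_sided)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestWilcoxon:
    def test_all_positive_differences(self):
        c = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert c.statistic_W == 6
        assert c.p_two_sided == pytest.approx(0.25)
        assert c.method == "exact"

    def test_sign_symmetry(self):
        c = wilcoxon_signed_rank([-1.0, -2.0, -3.0])
        assert c.statistic_W == 0
        assert c.p_two_sided == pytest.approx(0.25)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([0.0, 0.0, 0.0])

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(60):
            n = rng.integers(1, 11)
            diffs = rng.normal(0.2, 1, size=n)
            if (diffs == 0).any():
                continue
            assert (wilcoxon_signed_rank(diffs).p_two_sided
                    == wilcoxon_enumeration_p(diffs))

    def test_before_after_form(self):
        before = np.array([1.0, 2.0, 3.0, 4.0])
        after = before + np.array([0.5, -0.2, 0.9, 0.1])
        a = wilcoxon_signed_rank(before, after)
        b = wilcoxon_signed_rank(after - before)
        assert a.p_two_sided == b.p_two_sided


class TestSummaries:
    def test_box_summary_odd_n(self):
        b = box_summary([1, 2, 3, 4, 5])
        assert (b.minimum, b.q1, b.median, b.q3, b.maximum) == (1, 2, 3, 4, 5)

    def test_box_summary_singleton(self):
        b = box_summary([5.0])
        assert b.minimum == b.q1 == b.median == b.q3 == b.maximum == 5.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40))
    def test_box_summary_ordering_invariant(self, values):
        b = box_summary(values)
        assert b.minimum <= b.q1 <= b.median <= b.q3 <= b.maximum

    def test_radial_distribution_point_mass(self):
        rd = radial_distribution([0.5] * 100, bins=10)
        assert rd.frequency[5] == 1.0
        assert rd.frequency.sum() == pytest.approx(1.0)
        assert (rd.ecdf_x == 0.5).all()

    def test_radial_distribution_normalised(self):
        rng = np.random.default_rng(5)
        rd = radial_distribution(rng.uniform(0, 1, 500), bins=7)
        assert rd.frequency.sum() == pytest.approx(1.0)

    def test_radial_distribution_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            radial_distribution([0.5, 1.2])


def _toy_table(seed=0, effect=2.0):
    rng = np.random.default_rng(seed)
    rows = []
    for region, scale in (("stem_zone", 1.0), ("neural_tube", effect)):
        for e in ("e1", "e2", "e3"):
            for i in range(20):
                rows.append((f"{region}_{e}_{i}", e, region, "control",
                             rng.gamma(1.5, 0.05 * scale),
                             rng.beta(2, 2)))
    return pd.DataFrame(rows, columns=["nucleus_id", "embryo_id", "region",
                                       "condition", "d2_um2", "frac_radius"])


class TestCompareDesign:
    def test_pooled_and_per_embryo_rows(self):
        table = _toy_table()
        plan = [{"metric": "d2_um2", "group_a": "stem_zone",
                 "group_b": "neural_tube", "per_embryo": True}]
        report = compare_design(table, plan)
        assert (report.stratum == "pooled").sum() == 1
        assert report.stratum.str.startswith("embryo:").sum() == 3
        assert (report.loc[report.stratum == "pooled", "p_two_sided"] < 0.05).all()

    def test_unknown_group_lists_available(self):
        with pytest.raises(KeyError, match="stem_zone"):
            select_group(_toy_table(), "notochord", "d2_um2")

    def test_paired_design_reports_wilcoxon_and_per_pair(self):
        rng = np.random.default_rng(6)
        rows = []
        for pair in range(5):
            for cond, shift in (("DMSO", 0.0), ("RA", 0.04)):
                for i in range(12):
                    rows.append((f"p{pair}_{cond}_{i}", f"pair{pair}", "explant",
                                 cond, rng.gamma(1.5, 0.05) + shift, 0.5))
        table = pd.DataFrame(rows, columns=["nucleus_id", "embryo_id", "region",
                                            "condition", "d2_um2", "frac_radius"])
        plan = [{"metric": "d2_um2",
                 "group_a": {"condition": "DMSO"},
                 "group_b": {"condition": "RA"}, "paired": True}]
        report = compare_design(table, plan)
        w = report[report.test == "wilcoxon_signed_rank"]
        assert len(w) == 1 and w.iloc[0].stratum == "pairs"
        assert report.stratum.str.startswith("pair:").sum() == 5

    def test_holm_correction_appends_column(self):
        report = compare_design(_toy_table(), [
            {"metric": "d2_um2", "group_a": "stem_zone", "group_b": "neural_tube"},
            {"metric": "frac_radius", "group_a": "stem_zone",
             "group_b": "neural_tube"}], correction="holm")
        assert "p_holm" in report.columns
        assert (report.p_holm >= report.p_two_sided).all()
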