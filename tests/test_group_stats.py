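"""Rank-sum and correlation statistics, checked against independent
oracles: full enumeration of rank splits, scipy's exact Mann-Whitney,
and a hand-written two-pass correlation formula."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from thermotrait.group_stats import (
    compare_cohort, comparisons_table, correlate, holm_correction,
    ranksum_test,
)


def enumeration_p(x, y):
    """Brute-force exact two-sided p: enumerate all C(N, n1) rank
    splits of the pooled tie-free data."""
    pooled = sorted(x + y)
    ranks_of = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks_of[v] for v in x)
    n = len(pooled)
    n1 = len(x)
    sums = [sum(combo)
            for combo in itertools.combinations(range(1, n + 1), n1)]
    total = len(sums)
    p_le = sum(s <= w_obs for s in sums) / total
    p_ge = sum(s >= w_obs for s in sums) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestExactRanksum:
    @pytest.mark.parametrize("x,y,expected", [
        ([1, 2], [3, 4], 2 / 6),
        ([1, 2, 3], [4, 5, 6], 2 / 20),
    ])
    def test_canonical_examples(self, x, y, expected):
        result = ranksum_test(x, y)
        assert result.method == "exact"
        assert result.p_two_sided == pytest.approx(expected, abs=1e-12)

    def test_identical_groups_give_p_one_direction_none(self):
        result = ranksum_test([5, 5], [5, 5])
        assert result.p_two_sided == 1.0
        assert result.direction == "none"

    def test_matches_enumeration_on_randomized_small_samples(self, rng):
        for _ in range(200):
            n1 = int(rng.integers(1, 7))
            n2 = int(rng.integers(1, 7))
            pooled = rng.choice(10_000, size=n1 + n2, replace=False)
            x, y = list(pooled[:n1].astype(float)), list(
                pooled[n1:].astype(float))
            ours = ranksum_test(x, y, method="exact").p_two_sided
            assert ours == pytest.approx(enumeration_p(x, y), abs=1e-12)

    def test_matches_scipy_exact_mannwhitney(self, rng):
        for _ in range(50):
            x = rng.normal(size=8)
            y = rng.normal(size=9, loc=0.5)
            ours = ranksum_test(list(x), list(y),
                                method="exact").p_two_sided
            ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_exact_method_refuses_ties(self):
        with pytest.raises(ValueError, match="tie-free"):
            ranksum_test([1, 1], [2, 3], method="exact")

    def test_auto_switches_to_normal_beyond_20(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=18)
        assert ranksum_test(x, y).method == "normal_approx"

    def test_normal_approx_close_to_exact_at_moderate_n(self, rng):
        x, y = list(rng.normal(size=10)), list(rng.normal(size=10))
        exact = ranksum_test(x, y, method="exact").p_two_sided
        approx = ranksum_test(x, y, method="normal_approx").p_two_sided
        assert approx == pytest.approx(exact, abs=0.03)

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=8,
                    unique=True),
           st.lists(st.floats(-100, 100), min_size=2, max_size=8,
                    unique=True))
    def test_invariant_under_monotone_transform(self, x, y):
        pooled = x + y
        if len(set(pooled)) != len(pooled):
            return
        before = ranksum_test(x, y)
        fx = [math.atan(v / 50) * 10 for v in x]
        fy = [math.atan(v / 50) * 10 for v in y]
        if len(set(fx + fy)) != len(pooled):
            return  # transform collided in float precision
        after = ranksum_test(fx, fy)
        assert before.p_two_sided == pytest.approx(
            after.p_two_sided, abs=1e-12)
        assert before.statistic_w == after.statistic_w

    def test_direction_follows_the_larger_group_values(self):
        up = ranksum_test([10, 11, 12], [1, 2, 3])
        assert up.direction == "group1>group2"
        down = ranksum_test([1, 2, 3], [10, 11, 12])
        assert down.direction == "group2>group1"


class TestCorrelate:
    def test_perfect_linear_relation(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2 * v + 1 for v in x]
        assert correlate(x, y).r == pytest.approx(1.0)

    def test_spearman_on_monotone_decreasing(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [10.0, 5.0, 2.0, 1.0]
        assert correlate(x, y, "spearman").r == pytest.approx(-1.0)

    def test_pearson_matches_two_pass_oracle(self, rng):
        x = rng.normal(size=30)
        y = 0.3 * x + rng.normal(size=30)
        mx, my = x.mean(), y.mean()
        naive = (((x - mx) * (y - my)).sum()
                 / math.sqrt(((x - mx) ** 2).sum()
                             * ((y - my) ** 2).sum()))
        assert correlate(x, y).r == pytest.approx(naive, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlate([1, 1, 1], [1, 2, 3])


class TestCompareCohort:
    def _table(self, rng, shift=0.0):
        vals1 = rng.normal(size=12) + shift
        vals2 = rng.normal(size=18)
        return pd.DataFrame({
            "genome_id": [f"g{i}" for i in range(30)],
            "habitat": ["thermal"] * 12 + ["non_thermal"] * 18,
            "size_bp": np.concatenate([vals1, vals2]),
        })

    def test_single_property_single_row(self, rng):
        out = compare_cohort(self._table(rng), properties=("size_bp",))
        assert len(out) == 1
        assert out[0].n1 == 12 and out[0].n2 == 18

    def test_large_shift_detected_with_direction(self, rng):
        table = self._table(rng)
        table.loc[table.habitat == "non_thermal", "size_bp"] += 10.0
        (c,) = compare_cohort(table, properties=("size_bp",))
        assert c.direction == "group2>group1"
        assert c.p_two_sided < 1e-4

    def test_missing_values_excluded_pairwise(self, rng):
        table = self._table(rng)
        table.loc[0, "size_bp"] = np.nan
        (c,) = compare_cohort(table, properties=("size_bp",))
        assert c.n1 == 11

    def test_holm_correction_is_monotone_and_bounded(self, rng):
        table = self._table(rng)
        table["gc_pct"] = rng.normal(size=30)
        table["charged"] = np.concatenate(
            [rng.normal(size=12) + 5, rng.normal(size=18)])
        comps = compare_cohort(table,
                               properties=("size_bp", "gc_pct",
                                           "charged"))
        adjusted = holm_correction(comps)
        for c in comps:
            assert adjusted[c.property_name] >= c.p_two_sided
            assert adjusted[c.property_name] <= 1.0

    def test_report_table_has_one_row_per_property(self, rng):
        table = self._table(rng)
        table["gc_pct"] = rng.normal(size=30)
        df = comparisons_table(
            compare_cohort(table, properties=("size_bp", "gc_pct")))
        assert list(df["property"]) == ["size_bp", "gc_pct"]
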