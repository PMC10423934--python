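"""Rank-sum tests (exact and normal) and median/IQR summaries."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ethochunk import (
    GroupSample,
    compare_groups,
    median_iqr,
    midranks,
    rank_sum_exact,
    rank_sum_normal,
)
from ethochunk.errors import ValidationError


def brute_force_exact_p(x, y):
    """Independent enumeration oracle built on pairwise Mann-Whitney counts.

    For every assignment of the pooled values to group 1, U is computed
    by directly counting pairs (x > y) + 0.5 * ties -- a different route
    from the implementation's rank-sum arithmetic.
    """
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_of(subset):
        g1 = [pooled[i] for i in subset]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in subset]
        u = 0.0
        for a in g1:
            for b in g2:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    u_obs = u_of(set(range(n1)))
    us = [u_of(set(c)) for c in combinations(range(len(pooled)), n1)]
    le = sum(u <= u_obs + 1e-9 for u in us)
    ge = sum(u >= u_obs - 1e-9 for u in us)
    return min(1.0, 2.0 * min(le, ge) / len(us))


class TestMidranks:
    def test_textbook_tie_example(self):
        assert midranks([10, 20, 20, 30]).tolist() == [1.0, 2.5, 2.5, 4.0]

    def test_distinct_values_give_a_permutation(self):
        ranks = midranks([5.0, 1.0, 3.0])
        assert sorted(ranks.tolist()) == [1.0, 2.0, 3.0]

    def test_all_equal_share_the_mean_rank(self):
        assert midranks([7, 7, 7, 7]).tolist() == [2.5] * 4

    def test_ranks_sum_to_triangular_number(self):
        rng = np.random.default_rng(0)
        values = rng.integers(0, 5, size=9)
        assert midranks(values).sum() == 9 * 10 / 2


class TestRankSumExact:
    def test_three_vs_three_separation(self):
        result = rank_sum_exact([1, 2, 3], [4, 5, 6])
        assert result.p_two_sided == pytest.approx(0.1)
        assert result.method == "exact_enumeration"
        assert result.w_stat == 6.0

    def test_singletons_force_p_one(self):
        assert rank_sum_exact([5], [10]).p_two_sided == 1.0

    def test_complete_separation_five_vs_six(self):
        result = rank_sum_exact([1, 2, 3, 4, 5], [6, 7, 8, 9, 10, 11])
        assert result.p_two_sided == pytest.approx(2 / 462)

    def test_refuses_above_enumeration_limit(self):
        with pytest.raises(ValidationError, match="rank_sum_normal"):
            rank_sum_exact(list(range(8)), list(range(8)))

    def test_matches_brute_force_oracle_with_ties(self):
        """200 random small datasets, tie-rich, vs the pairwise-count oracle."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n1 = int(rng.integers(1, 6))
            n2 = int(rng.integers(1, 11 - n1))
            x = rng.integers(0, 6, size=n1).tolist()
            y = rng.integers(0, 6, size=n2).tolist()
            result = rank_sum_exact(x, y)
            assert result.p_two_sided == pytest.approx(brute_force_exact_p(x, y)), (x, y)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 7))
            pooled = rng.permutation(100)[: n1 + n2].astype(float)
            x, y = pooled[:n1], pooled[n1:]
            ours = rank_sum_exact(x, y).p_two_sided
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(ref)

    def test_invariant_to_monotone_transform(self):
        x = [1.0, 4.0, 9.0, 2.0]
        y = [3.0, 8.0, 8.0]
        base = rank_sum_exact(x, y).p_two_sided
        fx = [math.exp(v) for v in x]
        fy = [math.exp(v) for v in y]
        assert rank_sum_exact(fx, fy).p_two_sided == pytest.approx(base)

    def test_rank_sums_of_both_orientations_cover_all_ranks(self):
        x, y = [1, 5, 5, 9], [2, 5, 7]
        n = len(x) + len(y)
        w_xy = rank_sum_exact(x, y).w_stat
        w_yx = rank_sum_exact(y, x).w_stat
        assert w_xy + w_yx == n * (n + 1) / 2


class TestRankSumNormal:
    def test_degenerate_all_equal_gives_p_one_with_warning(self):
        with pytest.warns(UserWarning, match="identical"):
            result = rank_sum_normal([3, 3, 3], [3, 3])
        assert result.p_two_sided == 1.0

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=12).tolist()
        y = rng.normal(1.0, size=10).tolist()
        assert rank_sum_normal(x, y).p_two_sided == pytest.approx(
            rank_sum_normal(y, x).p_two_sided)

    def test_close_to_exact_for_moderate_n(self):
        """|p_normal - p_exact| < 0.01 over 100 tie-free datasets, n1=n2=10.

        The exact reference is scipy's exact Mann-Whitney distribution,
        which our own enumeration matches (tested above at small n).
        """
        rng = np.random.default_rng(11)
        for _ in range(100):
            pooled = rng.permutation(1000)[:20].astype(float)
            x, y = pooled[:10], pooled[10:]
            p_exact = sps.mannwhitneyu(x, y, alternative="two-sided",
                                       method="exact").pvalue
            p_norm = rank_sum_normal(x, y).p_two_sided
            assert abs(p_norm - p_exact) < 0.01

    def test_agrees_with_scipy_tie_corrected(self):
        rng = np.random.default_rng(13)
        x = rng.integers(0, 8, size=20).astype(float)
        y = rng.integers(1, 9, size=25).astype(float)
        ours = rank_sum_normal(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                               use_continuity=True)
        assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)


class TestMedianIqr:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1, 2, 3, 4, 5], (3.0, 2.0, 4.0)),
            ([7], (7.0, 7.0, 7.0)),
            ([4, 4, 4, 4], (4.0, 4.0, 4.0)),
        ],
    )
    def test_linear_interpolation_quartiles(self, values, expected):
        s = median_iqr(values)
        assert (s.median, s.q1, s.q3) == expected

    def test_ordering_invariant(self):
        assert median_iqr([9, 1, 5, 3]) == median_iqr([1, 3, 5, 9])


class TestCompareGroups:
    def _measures(self, c57, dba, days=(1, 3, 5)):
        rows = []
        for day in days:
            for v in c57:
                rows.append({"strain": "C57BL/6", "lactation_day": day, "lat": float(v)})
            for v in dba:
                rows.append({"strain": "DBA/2J", "lactation_day": day, "lat": float(v)})
        return pd.DataFrame(rows)

    def test_complete_separation_every_stratum(self):
        table = self._measures([10, 20, 30, 40, 50], [100, 150, 200, 250, 300, 300])
        out = compare_groups(table, "lat", "strain", "lactation_day")
        assert list(out["stratum"]) == [1, 3, 5]
        assert (out["method"] == "exact_enumeration").all()
        assert out["p_two_sided"].tolist() == pytest.approx([2 / 462] * 3)

    def test_single_group_stratum_is_an_error_naming_it(self):
        table = self._measures([1, 2], [3, 4])
        table = table[~((table["lactation_day"] == 3) & (table["strain"] == "DBA/2J"))]
        with pytest.raises(ValidationError, match="3"):
            compare_groups(table, "lat", "strain", "lactation_day")

    def test_falls_back_to_normal_above_enumeration_limit(self):
        rng = np.random.default_rng(3)
        table = self._measures(rng.normal(size=10), rng.normal(size=10), days=(1,))
        out = compare_groups(table, "lat", "strain", "lactation_day")
        assert out.loc[0, "method"] == "normal_tie_corrected"

    def test_type_one_error_under_identical_distributions(self):
        """With no group difference, ~alpha of replicates reject at alpha."""
        rng = np.random.default_rng(77)
        n_rep = 400
        alpha = 0.1
        hits = 0
        for _ in range(n_rep):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            if rank_sum_exact(x, y).p_two_sided < alpha:
                hits += 1
        # exact test is conservative for discrete W: reject rate <= alpha + 3 sigma
        sigma = math.sqrt(alpha * (1 - alpha) / n_rep)
        assert hits / n_rep <= alpha + 3 * sigma
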