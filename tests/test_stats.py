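"""Rank statistics against independent oracles.

The oracles here never share code with the implementation: quartiles are
re-derived by explicit order-statistic interpolation, the Kruskal-Wallis H
for the small fixture was computed by hand from a rank table, p-values are
cross-checked by Monte-Carlo permutation, and Spearman's rho is rebuilt
from first principles (Pearson's formula on manually averaged ranks).
"""

import numpy as np
import pytest

from androgenaxis.stats import (
    compare_groups,
    dagostino_pearson,
    dunn_posthoc,
    kruskal_wallis,
    median_iqr,
    spearman,
)


def manual_ranks(values):
    """Average ranks by explicit sorting, independent of scipy."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while (j + 1 < len(values)
               and values[order[j + 1]] == values[order[i]]):
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def manual_kw_h(groups):
    """Kruskal-Wallis H from the textbook formula with tie correction."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = manual_ranks(pooled)
    bounds = np.cumsum([0] + [len(g) for g in groups])
    h = 0.0
    for i in range(len(groups)):
        r = ranks[bounds[i]:bounds[i + 1]]
        h += r.sum() ** 2 / len(r)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return h / correction


class TestMedianIqr:
    def test_symmetric_odd_list(self):
        assert median_iqr([1, 2, 3, 4, 5]) == (3.0, 2.0, 4.0)

    def test_singleton(self):
        assert median_iqr([7]) == (7.0, 7.0, 7.0)

    def test_matches_sorted_order_statistic_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(1.0, 0.8, size=200)
        med, q1, q3 = median_iqr(x)
        s = np.sort(x)

        def interp(p):
            # linear interpolation between order statistics at h=(n-1)p
            h = (len(s) - 1) * p
            lo = int(np.floor(h))
            return s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])

        assert med == pytest.approx(interp(0.50), rel=1e-12)
        assert q1 == pytest.approx(interp(0.25), rel=1e-12)
        assert q3 == pytest.approx(interp(0.75), rel=1e-12)
        assert q1 <= med <= q3

    def test_invariant_under_reordering(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=37)
        assert median_iqr(x) == median_iqr(x[::-1])

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            median_iqr([])


class TestNormalityScreen:
    def test_rejects_skewed_sample(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(0.0, 1.0, size=94)
        k2, p = dagostino_pearson(x)
        assert p < 0.05 and k2 > 0

    def test_calibrated_on_normal_data(self):
        # ~5% nominal rejection; allow sampling slack on 100 fixed draws
        rng = np.random.default_rng(3)
        rejections = sum(
            dagostino_pearson(rng.normal(size=500))[1] <= 0.05
            for _ in range(100))
        assert rejections <= 10

    def test_small_sample_is_an_error(self):
        with pytest.raises(ValueError, match="n >= 20"):
            dagostino_pearson(np.arange(10.0))

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ValueError):
            dagostino_pearson(np.full(30, 2.5))


class TestKruskalWallis:
    def test_identical_groups_no_separation(self):
        g = list(range(1, 11))
        h, p = kruskal_wallis([g, g, g])
        assert h == pytest.approx(0.0, abs=1e-10) or p > 0.9

    def test_hand_computed_fixture(self):
        # 3 groups x 5 integers; hand rank table: rank sums 25, 30, 65,
        # H = 12/(15*16) * (125 + 180 + 845) - 3*16 = 9.5 (no ties)
        groups = [[1, 3, 5, 7, 9], [2, 4, 6, 8, 10], [11, 12, 13, 14, 15]]
        h, p = kruskal_wallis(groups)
        assert h == pytest.approx(manual_kw_h(groups), rel=1e-12)
        assert h == pytest.approx(9.5, abs=1e-12)

    def test_two_group_equivalence_with_rank_sum(self):
        # with k=2, H equals the squared standardized rank-sum statistic
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 6)
        h, _ = kruskal_wallis([a, b])
        ranks = manual_ranks(np.concatenate([a, b]))
        n1, n2, n = len(a), len(b), len(a) + len(b)
        r1 = ranks[:n1].sum()
        z = (r1 - n1 * (n + 1) / 2) / np.sqrt(n1 * n2 * (n + 1) / 12)
        assert h == pytest.approx(z ** 2, rel=1e-10)

    def test_permutation_p_value_agreement(self):
        # Monte-Carlo permutation oracle on a small fixture, +/- 0.02
        groups = [[1.2, 2.4, 3.1, 4.0], [2.2, 3.3, 4.4, 5.5],
                  [5.1, 6.2, 7.3, 8.4]]
        h_obs, p_chi2 = kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        rng = np.random.default_rng(5)
        count = 0
        n_perm = 20_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            count += manual_kw_h(parts) >= h_obs - 1e-12
        p_perm = count / n_perm
        assert p_chi2 == pytest.approx(p_perm, abs=0.02)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(size=7), rng.normal(1, 1, size=7)]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


class TestDunn:
    def test_identical_groups_all_adjusted_p_one(self):
        g = [1, 2, 3, 4, 5]
        for pair in dunn_posthoc([g, g, g]):
            assert pair.p_adjusted == 1.0

    def test_shifted_group_has_smallest_p(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 1, 10)
        c = rng.normal(4, 1, 10)  # clearly shifted
        pairs = dunn_posthoc([a, b, c])
        by_pair = {(p.group_i, p.group_j): p.p_unadjusted for p in pairs}
        assert by_pair[(0, 2)] < by_pair[(0, 1)]
        assert by_pair[(1, 2)] < by_pair[(0, 1)]

    def test_two_group_z_squared_equals_h(self):
        # algebraic identity between Dunn's z and the Kruskal-Wallis H
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 9), rng.normal(0.8, 1, 7)
        (pair,) = dunn_posthoc([a, b])
        h, _ = kruskal_wallis([a, b])
        assert pair.z ** 2 == pytest.approx(h, rel=1e-10)

    def test_errors(self):
        with pytest.raises(ValueError):
            dunn_posthoc([[1, 2, 3]])


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, x).rho == pytest.approx(1.0)
        assert spearman(x, [-v for v in x]).rho == pytest.approx(-1.0)

    def test_eight_pair_fixture_with_tie_against_hand_formula(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        y = [2.1, 1.0, 3.0, 2.9, 5.0, 4.8, 7.2, 6.5]
        res = spearman(x, y)
        rx, ry = manual_ranks(x), manual_ranks(y)
        # Pearson's formula applied to the average ranks
        rho_hand = (np.sum((rx - rx.mean()) * (ry - ry.mean()))
                    / np.sqrt(np.sum((rx - rx.mean()) ** 2)
                              * np.sum((ry - ry.mean()) ** 2)))
        assert res.rho == pytest.approx(rho_hand, rel=1e-12)

    def test_permutation_p_agreement(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 8.0, 5.0, 7.0]
        res = spearman(x, y)
        rng = np.random.default_rng(9)
        rx = manual_ranks(x)
        ry = manual_ranks(y)

        def rho_of(perm):
            return np.corrcoef(rx, ry[perm])[0, 1]

        obs = abs(res.rho)
        n_perm = 20_000
        count = sum(abs(rho_of(rng.permutation(len(x)))) >= obs - 1e-12
                    for _ in range(n_perm))
        assert res.p_value == pytest.approx(count / n_perm, abs=0.02)

    def test_pairwise_deletion_and_n(self):
        x = [1.0, 2.0, None, 4.0, 5.0]
        y = [1.1, None, 3.0, 3.9, 5.2]
        res = spearman(x, y)
        assert res.n == 3

    def test_zero_variance_flagged_undefined(self):
        res = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert res.rho is None and res.p_value is None
        assert not res.significant

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            spearman([1.0, 2.0], [2.0, 1.0])


class TestCompareGroups:
    def test_summary_and_dunn_gating(self):
        rng = np.random.default_rng(10)
        groups = {"eugonadal": rng.normal(7, 1, 30),
                  "compensated": rng.normal(8, 1, 10),
                  "overt": rng.normal(3, 1, 12)}
        res = compare_groups(groups, "TT (ng/ml)")
        assert res.p_value <= 0.05 and res.dunn_pairs is not None
        assert len(res.dunn_pairs) == 3
        for (med, q1, q3) in res.group_summaries:
            assert q1 <= med <= q3

    def test_no_dunn_when_not_significant(self):
        rng = np.random.default_rng(12)
        groups = {"a": rng.normal(0, 1, 15), "b": rng.normal(0, 1, 15)}
        res = compare_groups(groups, "x")
        if res.p_value > 0.05:
            assert res.dunn_pairs is None
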