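"""Mann-Whitney statistics, cluster formation, permutation inference."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ierp import (
    ClusterPermutationTest,
    ClusterTestConfig,
    assess_normality,
    choose_normality_test,
    cluster_permutation_test,
    form_clusters,
    mann_whitney_z,
    z_threshold,
)
from ierp.cluster import mann_whitney_z_series


class TestNormalityChoice:
    @pytest.mark.parametrize("n,expected", [
        (200, "dagostino_pearson"), (20, "dagostino_pearson"),
        (19, "shapiro_wilk"), (8, "shapiro_wilk"),
    ])
    def test_selection_by_sample_size(self, n, expected):
        assert choose_normality_test(n) == expected

    def test_too_small_errors(self):
        with pytest.raises(ValueError, match="n >= 3"):
            choose_normality_test(2)


class TestAssessNormality:
    def test_heavy_tails_rejected(self, make_window_set):
        rng = np.random.default_rng(0)
        a = make_window_set(rng.standard_t(df=2, size=(200, 100)))
        b = make_window_set(rng.standard_t(df=2, size=(200, 100)), "reference")
        rep = assess_normality(a, b)
        assert rep.test_a == "dagostino_pearson"
        assert rep.fraction_nonnormal_a > 0.5

    def test_gaussian_rejection_near_alpha(self, make_window_set):
        rng = np.random.default_rng(1)
        a = make_window_set(rng.normal(size=(200, 400)))
        b = make_window_set(rng.normal(size=(200, 400)), "reference")
        rep = assess_normality(a, b, alpha=0.05)
        se = np.sqrt(0.05 * 0.95 / 400)
        assert abs(rep.fraction_nonnormal_a - 0.05) < 3 * se + 1e-9

    def test_constant_flagged_nonnormal(self, make_window_set):
        a = make_window_set(np.ones((50, 10)))
        b = make_window_set(np.random.default_rng(2).normal(size=(50, 10)),
                            "reference")
        rep = assess_normality(a, b)
        assert rep.nonnormal_a.all()


class TestZThreshold:
    def test_reference_values(self):
        assert z_threshold(0.05) == pytest.approx(1.959964, abs=1e-6)
        assert z_threshold(0.317311) == pytest.approx(1.0, abs=1e-5)
        assert z_threshold(0.01) == pytest.approx(2.575829, abs=1e-6)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1, 2.0])
    def test_out_of_range_errors(self, alpha):
        with pytest.raises(ValueError):
            z_threshold(alpha)


class TestMannWhitney:
    def test_identical_samples_centre(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, z = mann_whitney_z(x, x)
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert z == 0.0

    def test_fully_separated_samples(self):
        u, z = mann_whitney_z([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert z == pytest.approx(-4.5 / np.sqrt(5.25), abs=1e-4)  # -1.9640
        # exact two-sided p by enumerating all C(6,3)=20 rank assignments
        us = [sum(c) - 6 for c in combinations(range(1, 7), 3)]
        p_exact = 2 * np.mean([uu <= 0 for uu in us])
        assert p_exact == pytest.approx(0.1)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(size=11)
        _, z1 = mann_whitney_z(x, y)
        _, z2 = mann_whitney_z(y, x)
        assert z1 == pytest.approx(-z2, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.lists(st.integers(0, 6), min_size=2, max_size=12),
        st.lists(st.integers(0, 6), min_size=2, max_size=12),
    )
    def test_u_matches_bruteforce_pair_counting(self, xs, ys):
        x = np.array(xs, float)
        y = np.array(ys, float)
        u, _ = mann_whitney_z(x, y)
        brute = sum(
            1.0 if xi > yj else 0.5 if xi == yj else 0.0 for xi in x for yj in y
        )
        assert u == pytest.approx(brute)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10**6))
    def test_z_matches_scipy_asymptotic(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, size=rng.integers(3, 15)).astype(float)
        y = rng.integers(0, 5, size=rng.integers(3, 15)).astype(float)
        u, z = mann_whitney_z(x, y)
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert u == pytest.approx(res.statistic)
        if z != 0.0:
            assert abs(z) == pytest.approx(
                stats.norm.isf(res.pvalue / 2), abs=1e-8
            )

    def test_degenerate_all_equal(self):
        u, z = mann_whitney_z([2.0, 2.0], [2.0, 2.0, 2.0])
        assert z == 0.0


class TestFormClusters:
    def test_runs_split_by_gaps(self):
        z = np.array([0.0, 2.5, 2.6, 0.0, 3.0])
        clusters = form_clusters(z, 1.96)
        assert [(c.start_idx, c.end_idx) for c in clusters] == [(1, 2), (4, 4)]
        assert clusters[0].stat == pytest.approx(2.6)
        assert clusters[1].stat == pytest.approx(3.0)

    def test_subthreshold_gives_none(self):
        assert form_clusters(np.array([1.0, -1.5, 0.3]), 1.96) == []

    def test_opposite_signs_split(self):
        clusters = form_clusters(np.array([2.5, -2.5]), 1.96)
        assert len(clusters) == 2
        assert clusters[0].sign == 1 and clusters[1].sign == -1


class TestPermutationTest:
    def test_constructed_effect_recovered(self, make_window_set):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(30, 100))
        shifted = rng.normal(size=(30, 100))
        shifted[:, 40:61] += 10.0
        a = make_window_set(shifted, "phrase_boundary")
        b = make_window_set(rng.normal(size=(30, 100)), "reference")
        cfg = ClusterTestConfig(n_permutations=200, seed=0)
        res = cluster_permutation_test(a, b, cfg)
        sig = res.significant_clusters
        assert len(sig) >= 1
        big = max(sig, key=lambda c: c.length)
        assert big.sign == 1
        assert abs(big.start_idx - 40) <= 2 and abs(big.end_idx - 60) <= 2
        assert big.p_value == pytest.approx(1 / 201)

    def test_minimum_p_is_add_one(self, make_window_set):
        rng = np.random.default_rng(8)
        w = rng.normal(size=(40, 60))
        a = make_window_set(w)
        b = make_window_set(w[rng.permutation(40)], "reference")
        res = cluster_permutation_test(
            a, b, ClusterTestConfig(n_permutations=100, seed=1)
        )
        for c in res.clusters:
            assert c.p_value >= 1 / 101

    def test_deterministic(self, make_window_set):
        rng = np.random.default_rng(9)
        a = make_window_set(rng.normal(size=(25, 80)))
        b = make_window_set(rng.normal(size=(25, 80)), "reference")
        cfg = ClusterTestConfig(n_permutations=150, seed=3)
        r1 = cluster_permutation_test(a, b, cfg)
        r2 = cluster_permutation_test(a, b, cfg)
        np.testing.assert_array_equal(r1.z_series, r2.z_series)
        np.testing.assert_array_equal(r1.null_max_stats, r2.null_max_stats)
        assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]

    def test_effect_monotonicity(self, make_window_set):
        rng = np.random.default_rng(10)
        base_a = rng.normal(size=(25, 80))
        base_b = rng.normal(size=(25, 80))
        stats_ladder = []
        for amp in (0.5, 1.0, 2.0, 4.0):
            a = make_window_set(base_a + amp * np.pad(
                np.ones(21), (30, 29))[None, :], "phrase_boundary")
            b = make_window_set(base_b, "reference")
            res = cluster_permutation_test(
                a, b, ClusterTestConfig(n_permutations=100, seed=4)
            )
            covering = [
                c for c in res.clusters if c.start_idx <= 40 <= c.end_idx
            ]
            stats_ladder.append(max((c.stat for c in covering), default=0.0))
        assert all(s2 >= s1 for s1, s2 in zip(stats_ladder, stats_ladder[1:]))

    def test_window_length_mismatch_errors(self, make_window_set):
        a = make_window_set(np.zeros((5, 10)))
        b = make_window_set(np.zeros((5, 12)), "reference")
        with pytest.raises(ValueError, match="length"):
            ClusterPermutationTest(a, b)

    def test_too_few_permutations_errors(self, make_window_set):
        a = make_window_set(np.zeros((5, 10)))
        with pytest.raises(ValueError, match="permutations"):
            ClusterPermutationTest(a, a, ClusterTestConfig(n_permutations=50))

    def test_source_null_matches_direct_recomputation(self, make_window_set):
        """The optimized source-level null equals a literal re-run of the
        pipeline statistic on permuted-and-rebootstrapped source windows."""
        rng = np.random.default_rng(11)
        src_a = rng.normal(size=(8, 40))
        src_b = np.vstack([rng.normal(size=(20, 40)), src_a[:3]])  # shared rows
        ia, ib = rng.integers(0, 8, 50), rng.integers(0, 23, 50)
        ws_a = make_window_set(src_a[ia], "phrase_boundary")
        ws_b = make_window_set(src_b[ib], "reference")
        cfg = ClusterTestConfig(n_permutations=100, seed=6,
                                permutation_unit="source")
        t = ClusterPermutationTest(ws_a, ws_b, cfg,
                                   make_window_set(src_a, "phrase_boundary"),
                                   make_window_set(src_b, "reference"))
        fast = t._null_source(50, 50, np.random.default_rng(6))
        src = np.vstack([src_a, src_b])
        rng2 = np.random.default_rng(6)
        slow = []
        for _ in range(100):
            perm = rng2.permutation(31)
            rows_a = perm[:8][rng2.integers(0, 8, 50)]
            rows_b = perm[8:][rng2.integers(0, 23, 50)]
            _, z = mann_whitney_z_series(src[rows_a], src[rows_b], True)
            slow.append(np.abs(z).max())
        np.testing.assert_allclose(fast, slow, atol=1e-10)
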