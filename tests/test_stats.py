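import itertools

import numpy as np
import pytest
from scipy import stats as sps

from domainscope import synthetic_data as sd
from domainscope.core import BinGrid, BinTrack, GenomicRegion
from domainscope.stats import (
    RegionPairSample,
    contact_scaling,
    fit_scaling_exponent,
    intergenic_percentiles,
    paired_wilcoxon,
    region_pair_counts,
    stratified_contacts,
    virtual_anchor_profile,
)

from conftest import make_map, random_symmetric_map


class TestVirtualAnchor:
    def test_single_bin_anchor_equals_matrix_row(self):
        rng = np.random.default_rng(0)
        cmap = random_symmetric_map(8, rng)
        mean, sd_ = virtual_anchor_profile(cmap, (3, 4))
        for j in range(8):
            if j == 3:
                assert np.isnan(mean[j])
            else:
                assert mean[j] == cmap.counts[3, j]
                assert sd_[j] == 0.0

    def test_uniform_matrix_flat_profile(self):
        cmap = make_map(np.full((6, 6), 2.5))
        mean, sd_ = virtual_anchor_profile(cmap, (0, 3))
        np.testing.assert_allclose(mean[3:], 2.5)
        np.testing.assert_allclose(sd_[3:], 0.0)

    def test_hand_computed_profile(self):
        rng = np.random.default_rng(5)
        cmap = random_symmetric_map(8, rng)
        anchor = (2, 7)  # 5-bin anchor
        mean, sd_ = virtual_anchor_profile(cmap, anchor)
        for j in list(range(0, 2)) + [7]:
            col = np.array([cmap.counts[a, j] for a in range(2, 7)])
            assert mean[j] == pytest.approx(col.mean())
            assert sd_[j] == pytest.approx(col.std())
        assert np.isnan(mean[3])  # anchor-internal

    def test_empty_anchor_is_error(self):
        cmap = make_map(np.ones((4, 4)), mask=np.array([False, True, True, True]))
        with pytest.raises(ValueError):
            virtual_anchor_profile(cmap, (0, 1))


class TestRegionPairCounts:
    def test_whole_grid_gives_all_pairs(self):
        rng = np.random.default_rng(1)
        cmap = random_symmetric_map(7, rng)
        s = region_pair_counts(cmap, (0, 7), (0, 7))
        assert len(s.keys) == 7 * 6 // 2

    def test_disjoint_intervals_full_cross_product(self):
        rng = np.random.default_rng(2)
        cmap = random_symmetric_map(10, rng)
        s = region_pair_counts(cmap, (0, 3), (4, 8))
        assert len(s.keys) == 12

    def test_distance_threshold_unit_conversion(self):
        # 60 kb at 5 kb resolution keeps only |i - j| > 12
        n = 30
        grid = BinGrid(GenomicRegion("chr14", 0, n * 5000), 5000)
        rng = np.random.default_rng(3)
        cmap = random_symmetric_map(n, rng)
        from domainscope.core import ContactMap

        cmap = ContactMap(grid, cmap.counts)
        s = region_pair_counts(cmap, (0, n), (0, n), d_min_bp=60_000)
        assert all(j - i > 12 for i, j in s.keys)
        assert any(j - i == 13 for i, j in s.keys)

    def test_masked_out_everything_is_error(self):
        cmap = make_map(np.ones((5, 5)), mask=np.zeros(5, bool))
        with pytest.raises(ValueError, match="mask"):
            region_pair_counts(cmap, (0, 2), (3, 5))


class TestPairedWilcoxon:
    def _samples(self, x, y):
        keys = [(0, i + 1) for i in range(len(x))]
        return RegionPairSample(keys, x), RegionPairSample(keys, y)

    def test_identical_samples_report_no_test(self):
        x = np.arange(1.0, 11.0)
        s1, s2 = self._samples(x, x.copy())
        res = paired_wilcoxon(s1, s2, "greater")
        assert res.n_effective == 0
        assert np.isnan(res.p_value)
        assert res.method == "none"

    def test_uniform_shift_attains_smallest_exact_p(self):
        x = np.arange(1.0, 21.0)
        s1, s2 = self._samples(x, x + 1.0)
        res = paired_wilcoxon(s1, s2, "less")
        assert res.statistic == 0.0  # no positive differences
        assert res.p_value == pytest.approx(2.0 ** -20)
        assert res.method == "exact"

    def test_exact_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(10)
        for trial in range(5):
            x = rng.normal(0, 1, 18)
            y = x + rng.normal(0.4, 1, 18)
            s1, s2 = self._samples(x, y)
            for alt in ("greater", "less"):
                mine = paired_wilcoxon(s1, s2, alt)
                ref = sps.wilcoxon(x, y, alternative=alt, method="exact")
                assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_normal_approx_matches_scipy_with_ties(self):
        rng = np.random.default_rng(11)
        x = rng.integers(0, 6, 60).astype(float)
        y = x + rng.integers(-2, 3, 60)
        keep = x != y
        x, y = x[keep], y[keep]
        s1, s2 = self._samples(x, y)
        mine = paired_wilcoxon(s1, s2, "greater")
        ref = sps.wilcoxon(x, y, alternative="greater", method="approx", correction=False)
        assert mine.method == "normal"
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_distribution_by_enumeration_small_n(self):
        # full enumeration oracle over all 2^n sign assignments, n = 8
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 8)
        y = x + rng.normal(0.5, 1, 8)
        s1, s2 = self._samples(x, y)
        res = paired_wilcoxon(s1, s2, "greater")
        d = x - y
        d = d[d != 0]
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        count = sum(
            1
            for signs in itertools.product([0, 1], repeat=len(d))
            if ranks[np.array(signs, bool)].sum() >= w_obs - 1e-12
        )
        assert res.p_value == pytest.approx(count / 2 ** len(d), rel=1e-12)

    def test_key_mismatch_is_error(self):
        s1 = RegionPairSample([(0, 1)], [1.0])
        s2 = RegionPairSample([(0, 2)], [1.0])
        with pytest.raises(ValueError):
            paired_wilcoxon(s1, s2)

    def test_type_one_error_calibration(self):
        # null: both samples i.i.d. resamples of the same expectation
        rng = np.random.default_rng(1234)
        alpha, n_pairs, reps = 0.05, 100, 400
        lam = rng.uniform(5, 50, n_pairs)
        rejections = 0
        keys = [(0, i + 1) for i in range(n_pairs)]
        for _ in range(reps):
            x = rng.poisson(lam).astype(float)
            y = rng.poisson(lam).astype(float)
            res = paired_wilcoxon(
                RegionPairSample(keys, x), RegionPairSample(keys, y), "greater"
            )
            if res.p_value < alpha:
                rejections += 1
        assert rejections / reps == pytest.approx(alpha, abs=0.025)


class TestContactScaling:
    def test_uniform_matrix_flat_curve(self):
        cmap = make_map(np.full((10, 10), 4.0))
        norm, raw = contact_scaling(cmap)
        np.testing.assert_allclose(raw, 4.0)
        assert norm.sum() == pytest.approx(1.0)

    def test_exponent_recovery(self):
        slopes = []
        for seed in range(10):
            params = sd.MapSimParams(
                grid=BinGrid(GenomicRegion("chr14", 0, 60 * 30_000), 30_000),
                decay_exponent=-1.0,
                depth=5e5,
                seed=seed,
            )
            cmap, _ = sd.simulate_contact_map(params)
            _, raw = contact_scaling(cmap)
            slopes.append(fit_scaling_exponent(raw))
        assert abs(np.mean(slopes) + 1.0) < 0.1

    def test_exclusion_drops_subregion_pairs(self):
        X = np.full((10, 10), 2.0)
        X[2:5, 2:5] = 50.0  # hot sub-domain
        cmap = make_map(X)
        _, with_hot = contact_scaling(cmap, (0, 10))
        _, without = contact_scaling(cmap, (0, 10), exclude=(2, 5))
        assert with_hot[1] > without[1]
        assert without[1] == pytest.approx(2.0)

    def test_exclude_whole_region_is_error(self):
        cmap = make_map(np.ones((6, 6)))
        with pytest.raises(ValueError):
            contact_scaling(cmap, (0, 6), exclude=(0, 6))


class TestStratifiedContacts:
    def test_constant_track_is_error(self):
        cmap = make_map(np.ones((8, 8)))
        track = BinTrack(cmap.grid, np.ones(8), "t")
        with pytest.raises(ValueError):
            stratified_contacts(cmap, track, n_groups=4)

    def test_uniform_matrix_equal_group_means(self):
        cmap = make_map(np.full((12, 12), 3.0))
        track = BinTrack(cmap.grid, np.arange(12.0), "t")
        groups, edges = stratified_contacts(cmap, track, n_groups=2)
        means = {k: v.mean() for k, v in groups.items()}
        assert all(m == pytest.approx(3.0) for m in means.values())
        assert len(groups) == 3  # (0,0), (0,1), (1,1)

    def test_no_trend_under_transcription_independent_null(self):
        # planted map has no transcription coupling: group-pair means show no
        # monotone trend (regression slope CI covers 0 across seeds)
        slopes = []
        for seed in range(10):
            params = sd.default_5c_params(seed=seed, depth=5e5)
            cmap, _ = sd.simulate_contact_map(params)
            rng = np.random.default_rng(seed + 500)
            track = BinTrack(params.grid, rng.uniform(0, 10, cmap.n_bins), "txn")
            groups, _ = stratified_contacts(cmap, track, n_groups=4)
            xs, ys = [], []
            for (g1, g2), vals in groups.items():
                if vals.size:
                    xs.append(g1 + g2)
                    ys.append(np.log1p(vals.mean()))
            slopes.append(np.polyfit(xs, ys, 1)[0])
        lo = np.mean(slopes) - 2 * np.std(slopes) / np.sqrt(len(slopes))
        hi = np.mean(slopes) + 2 * np.std(slopes) / np.sqrt(len(slopes))
        assert lo <= 0.0 <= hi


class TestIntergenicPercentiles:
    def _grid(self, n=20, res=1000):
        return BinGrid(GenomicRegion("chr14", 0, n * res), res)

    def test_global_doubling_ties_all_at_midpoint(self):
        grid = self._grid()
        rng = np.random.default_rng(0)
        cov = BinTrack(grid, rng.uniform(1, 5, grid.n_bins), "a")
        cov2 = BinTrack(grid, 2 * cov.values, "b")
        genes = [GenomicRegion("chr14", 5000, 6000), GenomicRegion("chr14", 12_000, 13_000)]
        table = intergenic_percentiles(genes, cov, cov2, epsilon=0.0)
        np.testing.assert_allclose(table.log2fc, 1.0)
        # all N regions tied: mid-rank (N+1)/2 -> percentile 100(N+1)/(2N)
        n = len(table.regions)
        np.testing.assert_allclose(table.percentile, 100 * (n + 1) / (2 * n))

    def test_top_region_gets_percentile_100(self):
        grid = self._grid()
        base = np.ones(grid.n_bins)
        boosted = base.copy()
        boosted[:5] = 100.0  # first intergenic region hugely up
        genes = [
            GenomicRegion("chr14", 5000, 6000),
            GenomicRegion("chr14", 10_000, 11_000),
            GenomicRegion("chr14", 15_000, 16_000),
        ]
        table = intergenic_percentiles(
            genes, BinTrack(grid, base, "a"), BinTrack(grid, boosted, "b")
        )
        top = np.argmax(table.log2fc)
        assert table.regions[top].start == 0
        assert table.percentile[top] == pytest.approx(100.0)

    def test_hand_ranked_toy(self):
        # 10 intergenic regions with log2fc 1..10: top rank 100, rank 5 -> 50
        grid = self._grid(n=21)
        genes = [
            GenomicRegion("chr14", 2000 * k - 1000, 2000 * k) for k in range(1, 11)
        ]
        cov_a = np.ones(grid.n_bins)
        cov_b = np.ones(grid.n_bins)
        for k in range(10):  # intergenic region k spans [2000k, 2000k+1000)
            cov_b[2 * k] = 2.0 ** (k + 1)
        table = intergenic_percentiles(
            genes,
            BinTrack(grid, cov_a, "a"),
            BinTrack(grid, cov_b, "b"),
            epsilon=0.0,
        )
        assert len(table.regions) == 11  # 10 planted + trailing remainder
        order = np.argsort(table.log2fc)
        assert table.percentile[order[-1]] == pytest.approx(100.0)
        rank5 = np.flatnonzero(np.isclose(table.log2fc, 5.0 * np.log2(2.0)))[0]
        # log2fc = 5 sits 6th from bottom of 11 -> mid-rank percentile 6/11
        assert table.percentile[rank5] == pytest.approx(100 * 6 / 11)

    def test_genes_covering_region_warns_empty(self):
        grid = self._grid(n=4)
        genes = [GenomicRegion("chr14", 0, 4000)]
        cov = BinTrack(grid, np.ones(4), "a")
        with pytest.warns(UserWarning):
            table = intergenic_percentiles(genes, cov, cov)
        assert len(table.regions) == 0
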