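import numpy as np
import pytest

from domainscope import synthetic_data as sd
from domainscope.compartments import (
    CompartmentTrack,
    compartment_pca,
    expected_by_distance,
    orient_and_call,
)
from domainscope.core import BinTrack, ContactMap

from conftest import make_map


def checkerboard_map(n=20, strength=4.0, base=10.0):
    """Two interleaved label blocks: same-label contacts boosted."""
    labels = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
    same = np.equal.outer(labels, labels)
    counts = np.where(same, base * strength, base).astype(float)
    return make_map(counts), labels


class TestExpectedByDistance:
    def test_uniform_matrix_constant(self):
        cmap = make_map(np.full((6, 6), 3.5))
        np.testing.assert_allclose(expected_by_distance(cmap), 3.5)

    def test_distance_matrix_recovers_distance(self):
        n = 8
        counts = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        cmap = make_map(counts)
        np.testing.assert_allclose(expected_by_distance(cmap), np.arange(n))

    def test_masked_pairs_excluded(self):
        counts = np.full((5, 5), 2.0)
        counts[0, 1] = counts[1, 0] = 100.0  # would skew d=1 if bin 0 counted
        mask = np.array([False, True, True, True, True])
        cmap = make_map(counts, mask=mask)
        assert expected_by_distance(cmap)[1] == pytest.approx(2.0)

    def test_power_law_slope_recovered(self):
        from domainscope.core import BinGrid, GenomicRegion

        slopes = []
        for seed in range(10):
            params = sd.MapSimParams(
                grid=BinGrid(GenomicRegion("chr14", 0, 60 * 30_000), 30_000),
                decay_exponent=-1.0,
                depth=5e5,
                seed=seed,
            )
            cmap, _ = sd.simulate_contact_map(params)
            exp = expected_by_distance(cmap)
            d = np.arange(exp.size)
            ok = (d >= 1) & (exp > 0)
            slope, _ = np.polyfit(np.log(d[ok] + 1), np.log(exp[ok]), 1)
            slopes.append(slope)
        assert abs(np.mean(slopes) + 1.0) < 0.1


class TestCompartmentPCA:
    def test_two_block_signs(self):
        cmap, labels = checkerboard_map()
        track = compartment_pca(cmap)
        pc1 = track.pc1
        assert np.all(np.sign(pc1[labels == "A"]) == np.sign(pc1[labels == "A"][0]))
        assert np.all(np.sign(pc1[labels == "B"]) == np.sign(pc1[labels == "B"][0]))
        assert np.sign(pc1[0]) != np.sign(pc1[-1])

    def test_ideal_two_block_correlation_has_uniform_magnitude(self):
        # for an exact within +1 / cross -1 correlation matrix, the leading
        # eigenvector is the label indicator: uniform magnitude, opposite signs
        n = 10
        labels = np.array(["A"] * 5 + ["B"] * 5)
        corr = np.where(np.equal.outer(labels, labels), 1.0, -1.0)
        vals, vecs = np.linalg.eigh(corr)
        v = vecs[:, -1]
        assert np.ptp(np.abs(v)) < 1e-9
        assert np.sign(v[0]) != np.sign(v[-1])

    def test_scale_invariance(self):
        cmap, _ = checkerboard_map()
        scaled = ContactMap(cmap.grid, cmap.counts * 13.7, cmap.mask.copy())
        a, b = compartment_pca(cmap).pc1, compartment_pca(scaled).pc1
        # eigenvectors agree up to sign
        assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-9

    def test_label_swap_flips_sign_only(self):
        cmap, labels = checkerboard_map(n=10)
        # relabeling A<->B permutes bins; on this symmetric geometry the
        # correlation structure is identical, so |pc1| is unchanged
        perm = np.r_[np.arange(5, 10), np.arange(5)]
        swapped = ContactMap(cmap.grid, cmap.counts[np.ix_(perm, perm)])
        a = compartment_pca(cmap).pc1
        b = compartment_pca(swapped).pc1
        np.testing.assert_allclose(np.abs(a), np.abs(b), atol=1e-9)

    def test_masked_bins_carry_no_value(self):
        cmap, _ = checkerboard_map()
        mask = cmap.mask.copy()
        mask[3] = False
        cmap = ContactMap(cmap.grid, cmap.counts, mask)
        track = compartment_pca(cmap)
        assert np.isnan(track.pc1[3])

    def test_too_few_bins_error(self):
        cmap = make_map(np.full((4, 4), 1.0), mask=np.array([True, True, False, False]))
        with pytest.raises(ValueError):
            compartment_pca(cmap)


class TestOrientAndCall:
    def _track(self, pc1, grid):
        return CompartmentTrack(grid, np.asarray(pc1, dtype=float))

    def test_reference_equal_to_pc1_flips_under_a_negative(self):
        cmap, _ = checkerboard_map(n=10)
        pc1 = np.r_[np.full(5, 0.5), np.full(5, -0.5)]
        track = self._track(pc1, cmap.grid)
        ref = BinTrack(cmap.grid, pc1.copy(), "ref")
        out = orient_and_call(track, ref, convention="A_negative")
        np.testing.assert_allclose(out.pc1, -pc1)

    def test_single_bin_blip_absorbed(self):
        cmap, _ = checkerboard_map(n=11)
        pc1 = np.full(11, -0.5)
        pc1[5] = 0.5  # one-bin blip
        track = self._track(pc1, cmap.grid)
        ref = BinTrack(cmap.grid, -pc1 + np.linspace(0, 0.01, 11), "ref")
        out = orient_and_call(track, ref, min_run=2)
        assert out.borders == []
        assert len(set(out.labels)) == 1

    def test_zero_variance_reference_error(self):
        cmap, _ = checkerboard_map(n=10)
        track = self._track(np.linspace(-1, 1, 10), cmap.grid)
        ref = BinTrack(cmap.grid, np.ones(10), "flat")
        with pytest.raises(ValueError):
            orient_and_call(track, ref)

    def test_borders_stable_under_label_involution(self):
        cmap, _ = checkerboard_map(n=12)
        pc1 = np.r_[np.full(4, -0.4), np.full(4, 0.4), np.full(4, -0.4)]
        ref = BinTrack(cmap.grid, -pc1, "activity")
        a = orient_and_call(self._track(pc1, cmap.grid), ref, "A_negative")
        b = orient_and_call(self._track(pc1, cmap.grid), ref, "A_positive")
        assert a.borders == b.borders == [4, 8]
        # the convention flips the displayed sign, never the biological labels
        assert list(a.labels) == list(b.labels)
        np.testing.assert_allclose(a.pc1, -b.pc1)

    def test_default_geometry_recovers_two_borders(self):
        # the study-like A-B-A layout: exactly 2 borders at the planted spots
        params = sd.default_5c_params(seed=3, depth=1e6)
        cmap, truth = sd.simulate_contact_map(params)
        from domainscope.normalize import iterative_correction

        corrected = iterative_correction(cmap).corrected
        track = compartment_pca(corrected)
        activity = BinTrack(
            params.grid,
            np.array([1.0 if l == "A" else 0.0 for l in truth["labels"]]),
            "genes",
        )
        out = orient_and_call(track, activity)
        assert len(out.borders) == 2
        for got, want in zip(out.borders, sd.DEFAULT_COMPARTMENT_BORDERS):
            assert abs(got - want) <= 1

    def test_label_recovery_on_planted_checkerboard(self):
        hits, total = 0, 0
        for seed in range(5):
            params = sd.default_5c_params(seed=seed, depth=1e6)
            cmap, truth = sd.simulate_contact_map(params)
            track = compartment_pca(cmap)
            activity = BinTrack(
                params.grid,
                np.array([1.0 if l == "A" else 0.0 for l in truth["labels"]]),
                "genes",
            )
            out = orient_and_call(track, activity)
            got = np.asarray(out.labels)
            want = np.asarray(truth["labels"])
            hits += (got == want).sum()
            total += len(want)
        assert hits / total >= 0.95
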