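import numpy as np
import pytest

from pg4scape.io_formats import BinGrid, GenomeIndex, GenomicInterval
from pg4scape.rt_segmentation import (
    RT_WEIGHTS,
    mask_blacklist,
    minmax_scale,
    partition_classes,
    rt_score,
    rt_scores,
    segment_rt,
)


class TestRtScore:
    @pytest.mark.parametrize(
        "vec,expected",
        [
            ((1, 0, 0, 0, 0, 0), 0.917),
            ((0, 0, 0, 1, 0, 0), 0.417),
            ((0, 0, 0, 0, 0, 1), 0.0),
        ],
    )
    def test_single_phase_reproduces_weight(self, vec, expected):
        assert rt_score(np.array(vec, dtype=float)) == expected

    def test_uniform_signal_gives_mean_weight(self):
        # (2,2,2,...,2) normalizes to 1/6 each: score = sum(weights)/6 = 0.48616...
        assert rt_score(np.full(6, 2.0)) == pytest.approx(RT_WEIGHTS.sum() / 6)

    def test_scale_invariance(self, rng):
        v = rng.uniform(0.1, 5, size=6)
        for c in (0.01, 3.7, 1e4):
            assert rt_score(c * v) == pytest.approx(rt_score(v))

    def test_early_shift_strictly_increases_score(self, rng):
        v = rng.uniform(1, 2, size=6)
        for later in range(1, 6):
            for earlier in range(later):
                shifted = v.copy()
                shifted[later] -= 0.5
                shifted[earlier] += 0.5
                assert rt_score(shifted) > rt_score(v)

    def test_zero_vector_unscored(self):
        assert np.isnan(rt_score(np.zeros(6)))
        out = rt_scores(np.array([[1, 0, 0, 0, 0, 0], [0.0] * 6]))
        assert out[0] == 0.917 and np.isnan(out[1])

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError):
            rt_score(np.array([1, -1, 0, 0, 0, 1.0]))


class TestMinmaxScale:
    def test_endpoints(self):
        np.testing.assert_allclose(minmax_scale(np.array([0.0, 0.917])), [0.0, 1.0])

    def test_linearity(self):
        np.testing.assert_allclose(minmax_scale(np.array([0.2, 0.4, 0.6])), [0.0, 0.5, 1.0])

    def test_idempotent_after_first_scaling(self, rng):
        x = rng.uniform(size=50)
        once = minmax_scale(x)
        np.testing.assert_allclose(minmax_scale(once), once)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            minmax_scale(np.array([0.5, 0.5, 0.5]))


class TestMaskBlacklist:
    def test_empty_blacklist_noop(self, toy_grid):
        assert mask_blacklist(toy_grid, []).all()

    def test_full_chromosome_masked(self, toy_grid):
        m = mask_blacklist(toy_grid, [GenomicInterval("chr1", 0, 500_000)])
        assert not m[toy_grid.chrom_slice("chr1")].any()
        assert m[toy_grid.chrom_slice("chr2")].all()

    def test_matches_brute_force_overlap(self, toy_grid, rng):
        bl = []
        for _ in range(20):
            s = int(rng.integers(0, 490_000))
            bl.append(GenomicInterval("chr1", s, s + int(rng.integers(1, 9_000))))
        m = mask_blacklist(toy_grid, bl)
        for i in range(len(toy_grid)):
            expect = not any(
                iv.chrom == toy_grid.chrom[i]
                and iv.start < toy_grid.end[i]
                and toy_grid.start[i] < iv.end
                for iv in bl
            )
            assert m[i] == expect

    def test_min_overlap_fraction_rule(self, toy_grid):
        # 10 kb of a 50 kb bin blacklisted: removed at any-overlap, kept at 0.5
        bl = [GenomicInterval("chr1", 0, 10_000)]
        assert not mask_blacklist(toy_grid, bl)[0]
        assert mask_blacklist(toy_grid, bl, min_overlap_frac=0.5)[0]


class TestPartitionClasses:
    def _grid(self, n_bins):
        return BinGrid(GenomeIndex([("chr1", n_bins * 1_000)]), 1_000)

    @pytest.mark.parametrize("n", [10, 1000])
    def test_divisible_counts_are_exact_fifths(self, n, rng):
        grid = self._grid(n)
        scores = rng.permutation(n).astype(float) / n
        rt = partition_classes(grid, scores)
        counts = np.bincount(rt.classes, minlength=5)
        assert list(counts) == [n // 5] * 5

    def test_seven_bins_class_sizes(self):
        # ranks 0..6 through floor(5*i/7): classes 0,0,1,2,2,3,4 -> sizes (2,1,2,1,1)
        grid = self._grid(7)
        scores = np.array([0.9, 0.1, 0.5, 0.7, 0.3, 1.0, 0.0])
        rt = partition_classes(grid, scores)
        assert list(np.bincount(rt.classes, minlength=5)) == [2, 1, 2, 1, 1]

    def test_labels_monotone_in_score(self, rng):
        grid = self._grid(101)
        scores = rng.uniform(size=101)
        rt = partition_classes(grid, scores)
        for k in range(4):
            assert scores[rt.classes == k].min() >= scores[rt.classes == k + 1].max()

    def test_every_mappable_bin_classified_once(self, rng):
        grid = self._grid(50)
        scores = rng.uniform(size=50)
        scores[3] = np.nan
        mappable = np.ones(50, dtype=bool)
        mappable[10:15] = False
        rt = partition_classes(grid, scores, mappable)
        classified = rt.classes >= 0
        assert classified.sum() == 44
        assert not classified[3] and not classified[10:15].any()

    def test_too_few_bins_rejected(self):
        grid = self._grid(4)
        with pytest.raises(ValueError):
            partition_classes(grid, np.arange(4, dtype=float))

    def test_ties_broken_by_genomic_order(self):
        grid = self._grid(10)
        rt = partition_classes(grid, np.zeros(10) + np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0.0]))
        # equal-score bins keep genomic order: first of the 1s is earliest
        assert rt.classes[0] <= rt.classes[4]
        assert rt.classes[5] <= rt.classes[9]


def test_segment_rt_end_to_end(toy_grid, tmp_path):
    """Six concentrated tracks -> correct raw scores, scaling and quintiles."""
    from pg4scape.io_formats import BinnedTrack

    n = len(toy_grid)
    rng = np.random.default_rng(0)
    # bin i concentrated in phase i % 6
    phases = np.zeros((n, 6))
    phases[np.arange(n), np.arange(n) % 6] = 10.0
    tracks = [BinnedTrack(toy_grid, phases[:, j]) for j in range(6)]
    rt = segment_rt(tracks, blacklist=[])
    np.testing.assert_allclose(rt.raw, RT_WEIGHTS[np.arange(n) % 6])
    assert np.nanmax(rt.scaled) == 1.0 and np.nanmin(rt.scaled) == 0.0
    assert (rt.classes >= 0).all()
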