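import numpy as np
import pytest

from pg4scape.io_formats import GenomicInterval
from pg4scape.pg4_clusters import combine_strands, detect_clusters

from conftest import random_intervals


def iv(start, end, strand="+", chrom="chr1"):
    return GenomicInterval(chrom, start, end, strand)


def brute_force_clusters(motifs, max_gap, min_motifs):
    """O(n^2) transitive-closure merge oracle, independent of the sweep-line path."""
    out = []
    keys = {(m.chrom, m.strand) for m in motifs}
    for chrom, strand in keys:
        ms = [m for m in motifs if m.chrom == chrom and m.strand == strand]
        groups = [[m] for m in ms]
        changed = True
        while changed:
            changed = False
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    si = min(g.start for g in groups[i]); ei = max(g.end for g in groups[i])
                    sj = min(g.start for g in groups[j]); ej = max(g.end for g in groups[j])
                    gap = max(si, sj) - min(ei, ej)
                    if gap <= max_gap:
                        groups[i] += groups[j]
                        del groups[j]
                        changed = True
                        break
                if changed:
                    break
        for g in groups:
            if len(g) >= min_motifs:
                out.append((chrom, min(m.start for m in g), max(m.end for m in g),
                            strand, len(g)))
    return sorted(out)


class TestDetectClusters:
    def test_two_motifs_gap_below_threshold_merge(self):
        (c,) = detect_clusters([iv(100, 120), iv(180, 205)])
        assert (c.interval.start, c.interval.end, c.motif_count) == (100, 205, 2)
        assert c.strand == "+"

    def test_opposite_strand_singletons_never_cluster(self):
        assert detect_clusters([iv(100, 120, "+"), iv(130, 150, "-")]) == []

    @pytest.mark.parametrize("gap,expect_cluster", [(99, True), (100, True), (101, False)])
    def test_threshold_sharpness(self, gap, expect_cluster):
        """Gap exactly 100 merges; 101 does not."""
        clusters = detect_clusters([iv(0, 50), iv(50 + gap, 80 + gap)])
        assert bool(clusters) is expect_cluster

    def test_unstranded_motif_rejected(self):
        with pytest.raises(ValueError, match="unstranded"):
            detect_clusters([GenomicInterval("chr1", 0, 10)])

    def test_abutting_motifs_merge(self):
        (c,) = detect_clusters([iv(0, 10), iv(10, 20)])
        assert c.motif_count == 2

    def test_overlapping_same_strand_motifs_merge(self):
        (c,) = detect_clusters([iv(0, 30), iv(10, 25)])
        assert (c.interval.start, c.interval.end) == (0, 30)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_transitive_merge_oracle(self, seed):
        rng = np.random.default_rng(seed)
        motifs = random_intervals(rng, "chr1", 30_000, 200, max_len=60, stranded=True)
        got = sorted(
            (c.interval.chrom, c.interval.start, c.interval.end, c.strand, c.motif_count)
            for c in detect_clusters(motifs, max_gap=100, min_motifs=2)
        )
        assert got == brute_force_clusters(motifs, 100, 2)

    def test_monotone_in_max_gap(self, rng):
        """Larger max_gap never decreases clustered motifs, never increases cluster count."""
        motifs = random_intervals(rng, "chr1", 50_000, 150, max_len=50, stranded=True)
        prev_motifs, prev_clusters = -1, len(motifs) + 1
        for gap in (0, 25, 50, 100, 400, 2_000):
            cs = detect_clusters(motifs, max_gap=gap, min_motifs=1)
            n_motifs = sum(c.motif_count for c in cs if c.motif_count >= 2)
            assert n_motifs >= prev_motifs
            assert len(cs) <= prev_clusters
            prev_motifs, prev_clusters = n_motifs, len(cs)

    def test_idempotent_on_cluster_intervals(self, rng):
        """Re-clustering cluster spans with the same gap never splits them."""
        motifs = random_intervals(rng, "chr1", 40_000, 120, max_len=60, stranded=True)
        cs = detect_clusters(motifs, max_gap=100, min_motifs=2)
        again = detect_clusters(
            [c.interval for c in cs], max_gap=100, min_motifs=1
        )
        assert len(again) <= len(cs)
        covered = lambda xs: sum(x.interval.length for x in xs)
        assert covered(again) >= covered(cs) - 0  # spans only ever merge


class TestCombineStrands:
    def _mk(self, motifs):
        cs = detect_clusters(motifs)
        return ([c for c in cs if c.strand == "+"], [c for c in cs if c.strand == "-"])

    def test_disjoint_union_keeps_spans(self):
        plus, minus = self._mk(
            [iv(100, 120), iv(150, 205), iv(400, 440, "-"), iv(480, 520, "-")]
        )
        combined = combine_strands(plus, minus)
        spans = [(c.interval.start, c.interval.end) for c in combined]
        assert spans == [(100, 205), (400, 520)]
        assert all(c.strand == "combined" for c in combined)

    def test_overlap_merges_into_one(self):
        plus, minus = self._mk(
            [iv(100, 130), iv(160, 205), iv(150, 200, "-"), iv(250, 300, "-")]
        )
        (c,) = combine_strands(plus, minus)
        assert (c.interval.start, c.interval.end) == (100, 300)
        assert c.motif_count == 4

    @pytest.mark.parametrize("seed", range(5))
    def test_covered_bp_equals_boolean_union_oracle(self, seed):
        rng = np.random.default_rng(seed)
        motifs = random_intervals(rng, "chr1", 20_000, 300, max_len=80, stranded=True)
        cs = detect_clusters(motifs)
        combined = combine_strands(
            [c for c in cs if c.strand == "+"], [c for c in cs if c.strand == "-"]
        )
        base = np.zeros(20_000, dtype=bool)
        for c in cs:
            base[c.interval.start : c.interval.end] = True
        assert sum(c.interval.length for c in combined) == int(base.sum())
        # output disjoint and sorted
        spans = [(c.interval.start, c.interval.end) for c in combined]
        assert spans == sorted(spans)
        assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))
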