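import numpy as np
import pytest

from pg4scape.gene_classes import GeneRecord
from pg4scape.io_formats import GenomeIndex, GenomicInterval
from pg4scape.pg4_clusters import PG4Cluster
from pg4scape.tss_profile import (
    class_profile,
    smooth_profile,
    smooth_values,
    tss_coverage_matrix,
)


def gene(gid, start, end, strand, chrom="chr1"):
    return GeneRecord(id=gid, interval=GenomicInterval(chrom, start, end, strand))


def cluster(start, end, chrom="chr1"):
    return PG4Cluster(GenomicInterval(chrom, start, end), "combined", 2)


class TestTssCoverageMatrix:
    def test_plus_strand_downstream_placement(self):
        g = gene("g", 50_000, 80_000, "+")
        mat = tss_coverage_matrix([g], [cluster(50_000, 50_100)], flank=1_000)
        row = mat[0]
        assert row[1_000 : 1_100].all()  # offsets 0..99 covered
        assert row[:1_000].sum() == 0 and row[1_100:].sum() == 0

    def test_minus_strand_orientation_flip(self):
        # minus gene: TSS at end-1; bases genomically upstream (higher coords)
        # are downstream offsets 0..99 after orientation
        g = gene("g", 20_000, 50_000, "-")
        tss = 49_999
        mat = tss_coverage_matrix([g], [cluster(tss - 99, tss + 1)], flank=1_000)
        row = mat[0]
        assert row[1_000 : 1_100].all()
        assert np.nansum(row) == 100

    def test_off_chromosome_positions_flagged_missing(self):
        genome = GenomeIndex([("chr1", 5_000)])
        g = gene("g", 100, 4_000, "+")
        mat = tss_coverage_matrix([g], [], flank=1_000, genome=genome)
        assert np.isnan(mat[0][:900]).all()  # offsets -1000..-101 fall below 0
        assert np.isfinite(mat[0][900:]).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_base_membership_oracle(self, seed):
        rng = np.random.default_rng(seed)
        chrom_len = 100_000
        base = np.zeros(chrom_len, dtype=bool)
        clusters = []
        pos = 0
        while pos < chrom_len - 500:
            length = int(rng.integers(30, 300))
            clusters.append(cluster(pos, pos + length))
            base[pos : pos + length] = True
            pos += length + int(rng.integers(50, 3_000))
        genes = [
            gene(f"g{i}", int(s), int(s) + 5_000, str(st))
            for i, (s, st) in enumerate(
                zip(rng.integers(3_000, 90_000, size=10), rng.choice(["+", "-"], size=10))
            )
        ]
        flank = 2_000
        mat = tss_coverage_matrix(genes, clusters, flank=flank)
        for gi, g in enumerate(genes):
            sign = 1 if g.interval.strand == "+" else -1
            for off in (-flank, -137, 0, 1, 999, flank):
                p = g.tss + sign * off
                assert mat[gi][off + flank] == base[p]


class TestClassProfile:
    def test_single_gene_profile_is_its_vector(self):
        mat = np.zeros((1, 21))
        mat[0, 10] = 1
        prof = class_profile(mat)
        np.testing.assert_array_equal(prof.fraction, mat[0])
        assert prof.offsets[10] == 0

    def test_two_genes_average(self):
        mat = np.vstack([np.ones(11), np.zeros(11)])
        prof = class_profile(mat)
        np.testing.assert_allclose(prof.fraction, 0.5)

    def test_missing_entries_excluded_from_denominator(self):
        mat = np.array([[1.0, np.nan], [0.0, np.nan]])
        prof = class_profile(mat)
        assert prof.fraction[0] == 0.5
        assert np.isnan(prof.fraction[1])

    def test_fractions_are_proportions(self, rng):
        mat = (rng.random((30, 101)) < 0.3).astype(float)
        prof = class_profile(mat)
        assert np.all((prof.fraction >= 0) & (prof.fraction <= 1))
        assert prof.fraction.max() >= prof.fraction.mean()


class TestSmoothing:
    def test_constant_profile_is_fixed_point(self):
        prof = class_profile(np.full((3, 51), 0.4))
        sm = smooth_profile(prof, 200)
        np.testing.assert_allclose(sm.fraction, 0.4)

    def test_impulse_response_plateau(self):
        x = np.zeros(601)
        x[300] = 1.0
        sm = smooth_values(x, 201)
        np.testing.assert_allclose(sm[200:401], 1 / 201)
        assert sm[199] == 0.0 and sm[401] == 0.0

    def test_matches_windowed_mean_oracle(self, rng):
        x = rng.uniform(size=401)
        w = 201
        sm = smooth_values(x, w)
        for i in (0, 1, 57, 200, 399, 400):
            lo, hi = max(0, i - w // 2), min(len(x), i + w // 2 + 1)
            assert sm[i] == pytest.approx(x[lo:hi].mean())

    def test_even_window_widened_to_stay_centered(self, rng):
        x = rng.uniform(size=300)
        np.testing.assert_allclose(smooth_values(x, 200), smooth_values(x, 201))

    def test_mean_preserved_up_to_edge_effects(self, rng):
        x = rng.uniform(size=2_001)
        sm = smooth_values(x, 201)
        assert abs(sm.mean() - x.mean()) < 201 / 2_001

    def test_output_bounded_by_input_range(self, rng):
        x = rng.uniform(0.2, 0.7, size=500)
        sm = smooth_values(x, 51)
        assert sm.min() >= 0.2 and sm.max() <= 0.7


def test_strand_symmetry_of_class_profile():
    """Mirroring coordinates and strands leaves the profile unchanged."""
    chrom_len = 200_000
    rng = np.random.default_rng(7)
    clusters, genes = [], []
    for i in range(30):
        s = int(rng.integers(20_000, 180_000))
        clusters.append(cluster(s, s + int(rng.integers(30, 200))))
    for i in range(12):
        s = int(rng.integers(15_000, 150_000))
        genes.append(gene(f"g{i}", s, s + 20_000, "+"))
    mirror_clusters = [
        cluster(chrom_len - c.interval.end, chrom_len - c.interval.start) for c in clusters
    ]
    mirror_genes = [
        gene(g.id, chrom_len - g.interval.end, chrom_len - g.interval.start, "-")
        for g in genes
    ]
    p1 = class_profile(tss_coverage_matrix(genes, clusters, flank=3_000))
    p2 = class_profile(tss_coverage_matrix(mirror_genes, mirror_clusters, flank=3_000))
    np.testing.assert_array_equal(p1.fraction, p2.fraction)
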