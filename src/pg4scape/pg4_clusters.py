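"""Strand-aware detection of clustered G-quadruplex motifs.

A pG4 cluster is a run of >= 2 pG4 motifs on the same strand in which
consecutive motifs are separated by at most ``max_gap`` bases (100 bp by
default). The gap is measured between intervals (next.start - prev.end), so
overlapping or abutting motifs always chain. Clusters from the two strands
are then combined by interval union for all strand-blind downstream
coverage analyses.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np

from ._intervals import merge_intervals
from .io_formats import (
    STRAND_MINUS,
    STRAND_NONE,
    STRAND_PLUS,
    GenomicInterval,
)

STRAND_COMBINED = "combined"


@dataclasses.dataclass(frozen=True)
class PG4Cluster:
    """A merged run of same-strand pG4 motifs (or a strand-combined union)."""

    interval: GenomicInterval
    strand: str  # "+", "-" or "combined"
    motif_count: int

    def __post_init__(self):
        if self.strand not in (STRAND_PLUS, STRAND_MINUS, STRAND_COMBINED):
            raise ValueError(f"invalid cluster strand {self.strand!r}")
        if self.motif_count < 1:
            raise ValueError("motif_count must be >= 1")


def detect_clusters(
    motifs: Iterable[GenomicInterval],
    max_gap: int = 100,
    min_motifs: int = 2,
) -> list[PG4Cluster]:
    """Chain same-strand motifs separated by <= max_gap into clusters.

    Motifs must be stranded (+/-). Chains with fewer than ``min_motifs``
    members are discarded. Returns clusters sorted by (chrom, start); the
    cluster interval spans from the first member's start to the last
    member's end.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if min_motifs < 1:
        raise ValueError("min_motifs must be >= 1")
    by_key: dict[tuple[str, str], list[GenomicInterval]] = defaultdict(list)
    for m in motifs:
        if m.strand == STRAND_NONE:
            raise ValueError(f"unstranded motif {m.chrom}:{m.start}-{m.end}")
        by_key[(m.chrom, m.strand)].append(m)

    clusters: list[PG4Cluster] = []
    for (chrom, strand), ms in by_key.items():
        starts = np.array([m.start for m in ms], dtype=np.int64)
        ends = np.array([m.end for m in ms], dtype=np.int64)
        cs, ce, group = merge_intervals(starts, ends, max_gap=max_gap)
        counts = np.bincount(group, minlength=cs.size)
        for s, e, n in zip(cs, ce, counts):
            if n >= min_motifs:
                clusters.append(
                    PG4Cluster(GenomicInterval(chrom, int(s), int(e), strand), strand, int(n))
                )
    clusters.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    return clusters


def combine_strands(
    plus: Sequence[PG4Cluster], minus: Sequence[PG4Cluster]
) -> list[PG4Cluster]:
    """Union the two strand-specific cluster sets into disjoint intervals.

    Overlapping or abutting clusters from either strand merge into one
    combined interval whose motif_count is the sum over merged members, so
    downstream coverage never double-counts bases covered on both strands.
    """
    all_clusters = list(plus) + list(minus)
    by_chrom: dict[str, list[PG4Cluster]] = defaultdict(list)
    for c in all_clusters:
        by_chrom[c.interval.chrom].append(c)
    combined: list[PG4Cluster] = []
    for chrom, cs in by_chrom.items():
        starts = np.array([c.interval.start for c in cs], dtype=np.int64)
        ends = np.array([c.interval.end for c in cs], dtype=np.int64)
        counts = np.array([c.motif_count for c in cs], dtype=np.int64)
        order = np.lexsort((ends, starts))
        # gap 0 merges (abutting intervals join)
        ms, me, group = merge_intervals(starts, ends, max_gap=0)
        gcounts = np.zeros(ms.size, dtype=np.int64)
        np.add.at(gcounts, group, counts[order])
        for s, e, n in zip(ms, me, gcounts):
            combined.append(
                PG4Cluster(
                    GenomicInterval(chrom, int(s), int(e)), STRAND_COMBINED, int(n)
                )
            )
    combined.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return combined


def clusters_to_bed(clusters: Sequence[PG4Cluster], path) -> None:
    """Write clusters as BED6 with motif_count in the score column."""
    from .io_formats import write_bed

    intervals = [
        GenomicInterval(
            c.interval.chrom,
            c.interval.start,
            c.interval.end,
            c.strand if c.strand != STRAND_COMBINED else STRAND_NONE,
        )
        for c in clusters
    ]
    names = [f"pG4_cluster_{i + 1}" for i in range(len(clusters))]
    scores = [c.motif_count for c in clusters]
    write_bed(intervals, path, names=names, scores=scores)


def clusters_from_bed(path, genome=None) -> list[PG4Cluster]:
    """Read clusters back from BED6 (score column = motif count)."""
    from .io_formats import read_bed

    clusters = []
    intervals = read_bed(path, stranded=False, genome=genome)
    with open(path) as fh:
        lines = [l.rstrip("\n").split("\t") for l in fh if l.strip() and not l.startswith("#")]
    for iv, fields in zip(intervals, lines):
        count = int(fields[4]) if len(fields) >= 5 else 2
        strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else STRAND_COMBINED
        clusters.append(
            PG4Cluster(
                GenomicInterval(iv.chrom, iv.start, iv.end,
                                strand if strand in "+-" else STRAND_NONE),
                strand,
                count,
            )
        )
    return clusters
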