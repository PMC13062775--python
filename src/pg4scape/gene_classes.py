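"""Gene classification (CFS / long non-CFS / short) and gene-body coverage.

Common fragile sites (CFSs) in lymphoblasts are hosted by large genes whose
replication is significantly delayed (SDR/SDW regions). Genes are split
into three classes — CFS (> 200 kb and overlapping an SDR/SDW), long
non-CFS (> 200 kb, no overlap) and short (< 200 kb, no overlap) — and their
log2 pG4-cluster coverage is compared with a Kruskal-Wallis test, with an
option to exclude the first 2 kb downstream of the TSS to mitigate the
TSS-proximal enrichment bias.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._intervals import IntervalSet
from .io_formats import STRAND_MINUS, STRAND_PLUS, GenomicInterval
from .pg4_clusters import PG4Cluster
from .coverage_analysis import clusters_by_chrom

CFS = "CFS"
LONG_NON_CFS = "LONG_NON_CFS"
SHORT = "SHORT"
EXCLUDED = "EXCLUDED"

GENE_CLASSES = (CFS, LONG_NON_CFS, SHORT)

DEFAULT_LENGTH_THRESHOLD = 200_000
DEFAULT_PSEUDOCOUNT = 1e-4


@dataclasses.dataclass
class GeneRecord:
    """One gene: stranded span, TSS, length, SDR/SDW overlap and class."""

    id: str
    interval: GenomicInterval
    sdr_overlap: bool = False
    gene_class: str | None = None

    def __post_init__(self):
        if self.interval.strand not in (STRAND_PLUS, STRAND_MINUS):
            raise ValueError(f"gene {self.id!r} must be stranded")

    @property
    def tss(self) -> int:
        """Transcription start: leftmost base for +, rightmost for -."""
        if self.interval.strand == STRAND_PLUS:
            return self.interval.start
        return self.interval.end - 1

    @property
    def length(self) -> int:
        return self.interval.length


def read_genes(path, genome=None) -> list[GeneRecord]:
    """Read genes from BED6 (column 4 = gene id)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: gene BED needs 6 columns")
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]), f[5])
            if genome is not None:
                genome.validate(iv)
            genes.append(GeneRecord(id=f[3], interval=iv))
    return genes


def classify_genes(
    genes: Sequence[GeneRecord],
    sdr: Sequence[GenomicInterval],
    length_threshold: int = DEFAULT_LENGTH_THRESHOLD,
) -> list[GeneRecord]:
    """Assign each gene a class from its length and SDR/SDW overlap.

    CFS: length > threshold and any-overlap with an SDR/SDW interval.
    LONG_NON_CFS: length > threshold, no overlap.
    SHORT: length < threshold, no overlap.
    Everything else (short genes overlapping an SDR/SDW, and genes of
    exactly the threshold length without overlap) is EXCLUDED.
    """
    sdr_by_chrom: dict[str, IntervalSet] = {}
    by: dict[str, list[GenomicInterval]] = {}
    for iv in sdr:
        by.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by.items():
        sdr_by_chrom[chrom] = IntervalSet(
            np.array([i.start for i in ivs]), np.array([i.end for i in ivs])
        )
    out = []
    for g in genes:
        iset = sdr_by_chrom.get(g.interval.chrom)
        overlap = bool(
            iset is not None
            and iset.overlap_bp(g.interval.start, g.interval.end)[0] > 0
        )
        if g.length > length_threshold:
            cls = CFS if overlap else LONG_NON_CFS
        elif g.length < length_threshold and not overlap:
            cls = SHORT
        else:
            cls = EXCLUDED
        out.append(dataclasses.replace(g, sdr_overlap=overlap, gene_class=cls))
    return out


def gene_body(gene: GeneRecord, exclude_tss_bp: int = 0) -> GenomicInterval:
    """Gene body, optionally minus the first ``exclude_tss_bp`` downstream of the TSS.

    The excluded window follows transcription direction: [start, start+k)
    for + genes, [end-k, end) for - genes.
    """
    iv = gene.interval
    if exclude_tss_bp <= 0:
        return iv
    if iv.length <= exclude_tss_bp:
        raise ValueError(
            f"gene {gene.id!r} ({iv.length} bp) shorter than TSS exclusion"
        )
    if iv.strand == STRAND_PLUS:
        return GenomicInterval(iv.chrom, iv.start + exclude_tss_bp, iv.end, iv.strand)
    return GenomicInterval(iv.chrom, iv.start, iv.end - exclude_tss_bp, iv.strand)


def gene_body_coverage(
    genes: Sequence[GeneRecord],
    clusters: Sequence[PG4Cluster],
    exclude_tss_bp: int = 0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene pG4-cluster coverage over the (possibly TSS-trimmed) body.

    Returns a DataFrame with gene id, class, body length, covered bp,
    fraction and log2(fraction + pseudocount). Zero-coverage genes are
    retained (the pseudocount keeps log2 finite); genes shorter than the
    exclusion window are dropped with a warning.
    """
    by_chrom = clusters_by_chrom(clusters)
    rows = []
    for g in genes:
        try:
            body = gene_body(g, exclude_tss_bp)
        except ValueError as exc:
            warnings.warn(str(exc))
            continue
        iset = by_chrom.get(body.chrom)
        covered = int(iset.overlap_bp(body.start, body.end)[0]) if iset else 0
        fraction = covered / body.length
        rows.append(
            {
                "gene_id": g.id,
                "gene_class": g.gene_class,
                "body_length": body.length,
                "covered_bp": covered,
                "fraction": fraction,
                "log2_coverage": float(np.log2(fraction + pseudocount)),
            }
        )
    return pd.DataFrame(rows)


def compare_classes(groups: dict[str, Sequence[float]]) -> pd.DataFrame:
    """Kruskal-Wallis omnibus test across gene classes.

    ``groups`` maps class name -> log2 coverage values. Returns a one-row
    summary (H with tie correction, chi-square p at df = k-1) plus per-group
    n and median columns.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for name, vals in groups.items():
        if len(vals) == 0:
            raise ValueError(f"group {name!r} is empty")
    h, p = stats.kruskal(*groups.values())
    row = {"H": float(h), "p_value": float(p), "df": len(groups) - 1}
    for name, vals in groups.items():
        row[f"n_{name}"] = len(vals)
        row[f"median_{name}"] = float(np.median(vals))
    return pd.DataFrame([row])
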