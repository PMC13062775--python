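"""Strand-oriented pG4-cluster coverage metaprofiles around TSSs.

For every gene a binary vector over offsets -flank..+flank (transcription
direction positive) marks whether the base at each offset falls inside a
combined pG4 cluster. The class profile is the per-offset mean over genes —
the fraction of genes covered at that distance from the TSS — smoothed with
a centered sliding window (the nominal 200 bp window is widened to 201
offsets so it stays centered).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage_analysis import clusters_by_chrom
from .gene_classes import GeneRecord
from .io_formats import STRAND_PLUS, GenomeIndex
from .pg4_clusters import PG4Cluster

DEFAULT_FLANK = 10_000
DEFAULT_SMOOTH_BP = 200


def tss_coverage_matrix(
    genes: Sequence[GeneRecord],
    clusters: Sequence[PG4Cluster],
    flank: int = DEFAULT_FLANK,
    genome: GenomeIndex | None = None,
) -> np.ndarray:
    """Per-gene binary coverage over TSS offsets -flank..+flank.

    Row g, column j corresponds to offset j - flank applied in transcription
    direction (genomic position TSS + offset for + genes, TSS - offset for -
    genes). Entries whose genomic position falls off the chromosome are NaN.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    width = 2 * flank + 1
    by_chrom = clusters_by_chrom(clusters)
    mat = np.zeros((len(genes), width), dtype=float)
    offsets = np.arange(-flank, flank + 1, dtype=np.int64)
    for gi, g in enumerate(genes):
        sign = 1 if g.interval.strand == STRAND_PLUS else -1
        positions = g.tss + sign * offsets
        valid = positions >= 0
        if genome is not None:
            valid &= positions < genome.length(g.interval.chrom)
        iset = by_chrom.get(g.interval.chrom)
        row = np.zeros(width)
        if iset is not None:
            row[valid] = iset.covers(positions[valid]).astype(float)
        row[~valid] = np.nan
        mat[gi] = row
    return mat


@dataclasses.dataclass
class TSSProfile:
    """A per-offset coverage profile for one gene class."""

    offsets: np.ndarray
    fraction: np.ndarray
    n_genes: int
    smooth_bp: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "fraction": self.fraction, "n_genes": self.n_genes}
        )


def class_profile(matrix: np.ndarray, flank: int | None = None) -> TSSProfile:
    """Mean binary coverage per offset over genes (NaN entries excluded).

    An offset where every gene is off-chromosome stays NaN.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 1:
        raise ValueError("need a (n_genes, n_offsets) matrix with >= 1 gene")
    width = matrix.shape[1]
    if flank is None:
        flank = (width - 1) // 2
    n_obs = np.isfinite(matrix).sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac = np.where(n_obs > 0, np.nansum(np.nan_to_num(matrix), axis=0), np.nan)
        frac = frac / np.where(n_obs > 0, n_obs, 1)
    return TSSProfile(
        offsets=np.arange(-flank, width - flank),
        fraction=frac,
        n_genes=matrix.shape[0],
    )


def smooth_values(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation, NaN-aware.

    Even windows are widened by one so the window stays centered. NaN
    entries are excluded from both numerator and denominator; a window with
    no finite entry yields NaN.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window % 2 == 0:
        window += 1
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    filled = np.where(finite, values, 0.0)
    kernel = np.ones(window)
    half = (window - 1) // 2
    # full-mode slice stays aligned even when window exceeds the array length
    num = np.convolve(filled, kernel, mode="full")[half : half + values.size]
    den = np.convolve(finite.astype(float), kernel, mode="full")[half : half + values.size]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def smooth_profile(profile: TSSProfile, window_bp: int = DEFAULT_SMOOTH_BP) -> TSSProfile:
    """Smooth a TSS profile with a centered sliding window of ~window_bp."""
    return TSSProfile(
        offsets=profile.offsets,
        fraction=smooth_values(profile.fraction, window_bp),
        n_genes=profile.n_genes,
        smooth_bp=window_bp if window_bp % 2 else window_bp + 1,
    )


def profiles_by_class(
    genes: Sequence[GeneRecord],
    clusters: Sequence[PG4Cluster],
    flank: int = DEFAULT_FLANK,
    smooth_bp: int = DEFAULT_SMOOTH_BP,
    genome: GenomeIndex | None = None,
) -> dict[str, tuple[TSSProfile, TSSProfile]]:
    """Raw and smoothed TSS profiles per gene class (classes present in input)."""
    out: dict[str, tuple[TSSProfile, TSSProfile]] = {}
    classes = sorted({g.gene_class for g in genes if g.gene_class})
    for cls in classes:
        members = [g for g in genes if g.gene_class == cls]
        mat = tss_coverage_matrix(members, clusters, flank=flank, genome=genome)
        raw = class_profile(mat, flank=flank)
        out[cls] = (raw, smooth_profile(raw, smooth_bp))
    return out
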