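"""Replication-timing scoring and segmentation from six-phase Repli-seq.

Each 50 kb bin carries a six-component signal vector (S1 earliest ... S6
latest S-phase fraction). The vector is normalized to fractions and dotted
with the ENCODE six-phase weights

    RT = S1*0.917 + S2*0.75 + S3*0.583 + S4*0.417 + S5*0.25 + S6*0

so a bin replicating entirely in S1 scores 0.917 and one replicating in S6
scores 0. Scores are min-max scaled to [0, 1] (1 = earliest), blacklist
bins are masked, and the remaining mappable genome is ranked and cut into
five quintile classes: Early, Mid-early, Mid, Mid-late, Late.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from ._intervals import IntervalSet
from .io_formats import BinGrid, BinnedTrack, GenomicInterval

#: ENCODE six-phase weights, S1 (earliest) to S6 (latest).
RT_WEIGHTS = np.array([0.917, 0.75, 0.583, 0.417, 0.25, 0.0])

#: Quintile class names, earliest first.
RT_CLASSES = ("Early", "Mid-early", "Mid", "Mid-late", "Late")

N_CLASSES = len(RT_CLASSES)
UNCLASSIFIED = -1


def rt_score(phase: np.ndarray, weights: np.ndarray = RT_WEIGHTS) -> float:
    """Weighted RT score of one six-phase signal vector.

    The vector is normalized to fractions summing to 1 before weighting, so
    the score reflects timing only, not coverage depth. All-zero vectors
    have no defined timing and return NaN.
    """
    phase = np.asarray(phase, dtype=float)
    if phase.shape != weights.shape:
        raise ValueError(f"expected {weights.size} phase components")
    if np.any(phase < 0):
        raise ValueError("phase signal must be non-negative")
    total = phase.sum()
    if total == 0:
        return float("nan")
    return float(phase @ weights / total)


def rt_scores(phases: np.ndarray, weights: np.ndarray = RT_WEIGHTS) -> np.ndarray:
    """Vectorized rt_score over an (n_bins, 6) signal matrix; zero rows -> NaN."""
    phases = np.asarray(phases, dtype=float)
    if np.any(phases < 0):
        raise ValueError("phase signal must be non-negative")
    totals = phases.sum(axis=1)
    out = np.full(phases.shape[0], np.nan)
    nz = totals > 0
    out[nz] = phases[nz] @ weights / totals[nz]
    return out


def minmax_scale(scores: np.ndarray) -> np.ndarray:
    """Min-max scale scores to [0, 1] ignoring NaNs (1 = earliest).

    Raises on a degenerate range (all scored values identical).
    """
    scores = np.asarray(scores, dtype=float)
    finite = scores[~np.isnan(scores)]
    if finite.size < 2:
        raise ValueError("need >= 2 scored bins to scale")
    lo, hi = finite.min(), finite.max()
    if lo == hi:
        raise ValueError("degenerate score range: all scores identical")
    return (scores - lo) / (hi - lo)


def mask_blacklist(
    grid: BinGrid,
    blacklist: Sequence[GenomicInterval],
    min_overlap_frac: float = 0.0,
) -> np.ndarray:
    """Boolean mappable mask per bin after blacklist exclusion.

    By default any overlap (> 0 bp) with a blacklist interval removes the
    bin; ``min_overlap_frac`` > 0 instead requires at least that fraction of
    the bin to be blacklisted.
    """
    mappable = np.ones(len(grid), dtype=bool)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in blacklist:
        grid.genome.validate(iv)
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by_chrom.items():
        sl = grid.chrom_slice(chrom)
        iset = IntervalSet(
            np.array([i.start for i in ivs]), np.array([i.end for i in ivs])
        )
        ov = iset.overlap_bp(grid.start[sl], grid.end[sl])
        lengths = grid.end[sl] - grid.start[sl]
        if min_overlap_frac > 0:
            hit = ov >= min_overlap_frac * lengths
        else:
            hit = ov > 0
        mappable[sl] &= ~hit
    return mappable


@dataclasses.dataclass
class RTTrack:
    """Per-bin RT scores and quintile class labels on a bin grid.

    ``classes[i]`` is 0 (Early) .. 4 (Late) for classified bins and -1 for
    bins that are blacklisted or unscored.
    """

    grid: BinGrid
    raw: np.ndarray
    scaled: np.ndarray
    classes: np.ndarray
    mappable: np.ndarray

    def class_bins(self, class_index: int) -> np.ndarray:
        return np.flatnonzero(self.classes == class_index)

    def to_dataframe(self):
        import pandas as pd

        labels = np.array(list(RT_CLASSES) + ["NA"])
        return pd.DataFrame(
            {
                "chrom": self.grid.chrom,
                "start": self.grid.start,
                "end": self.grid.end,
                "rt_raw": self.raw,
                "rt_scaled": self.scaled,
                "rt_class": labels[np.where(self.classes >= 0, self.classes, N_CLASSES)],
            }
        )


def rt_from_dataframe(df) -> RTTrack:
    """Rebuild an RTTrack from a to_dataframe()/rt_segmentation.tsv table.

    The bin grid is inferred from the chrom/start/end columns; bins must be
    the complete, in-order tiling that to_dataframe() wrote. Bins labelled
    "NA" become unclassified and non-mappable.
    """
    from .io_formats import BinGrid, GenomeIndex

    chrom_sizes = []
    for chrom in dict.fromkeys(df["chrom"]):
        chrom_sizes.append((str(chrom), int(df.loc[df["chrom"] == chrom, "end"].max())))
    genome = GenomeIndex(chrom_sizes)
    bin_size = int((df["end"] - df["start"]).max())
    grid = BinGrid(genome, bin_size)
    if len(grid) != len(df) or not (
        (grid.start == df["start"].to_numpy()).all()
        and (grid.chrom == df["chrom"].to_numpy().astype(str)).all()
    ):
        raise ValueError("table is not a complete in-order bin tiling")
    label_to_idx = {label: i for i, label in enumerate(RT_CLASSES)}
    classes = np.array([label_to_idx.get(c, -1) for c in df["rt_class"]], dtype=np.int64)
    return RTTrack(
        grid=grid,
        raw=df["rt_raw"].to_numpy(dtype=float),
        scaled=df["rt_scaled"].to_numpy(dtype=float),
        classes=classes,
        mappable=classes >= 0,
    )


def partition_classes(
    grid: BinGrid,
    scaled: np.ndarray,
    mappable: np.ndarray | None = None,
) -> RTTrack:
    """Rank mappable scored bins by scaled RT and cut into five quintiles.

    Bins are sorted by scaled score descending (earliest first), ties broken
    by genomic order; the bin at rank i of N gets class floor(5*i/N). Bins
    that are blacklisted or unscored (NaN) are labeled -1.
    """
    scaled = np.asarray(scaled, dtype=float)
    if mappable is None:
        mappable = np.ones(len(grid), dtype=bool)
    eligible = mappable & ~np.isnan(scaled)
    idx = np.flatnonzero(eligible)
    n = idx.size
    if n < N_CLASSES:
        raise ValueError(f"need >= {N_CLASSES} scored mappable bins, got {n}")
    # stable sort on descending score keeps genomic order within ties
    order = idx[np.argsort(-scaled[idx], kind="stable")]
    classes = np.full(len(grid), UNCLASSIFIED, dtype=np.int64)
    ranks = np.arange(n, dtype=np.int64)
    classes[order] = (N_CLASSES * ranks) // n
    return RTTrack(grid=grid, raw=scaled.copy(), scaled=scaled, classes=classes, mappable=mappable)


def segment_rt(
    phase_tracks: Sequence[BinnedTrack],
    blacklist: Sequence[GenomicInterval] = (),
    min_overlap_frac: float = 0.0,
) -> RTTrack:
    """Full segmentation: six phase tracks -> scored, scaled, classified bins."""
    if len(phase_tracks) != 6:
        raise ValueError("expected exactly six phase tracks (S1..S6)")
    grid = phase_tracks[0].grid
    for t in phase_tracks[1:]:
        if t.grid is not grid and len(t.grid) != len(grid):
            raise ValueError("phase tracks defined on different grids")
    phases = np.column_stack([np.nan_to_num(t.values, nan=0.0) for t in phase_tracks])
    raw = rt_scores(phases)
    scaled = minmax_scale(raw)
    mappable = mask_blacklist(grid, blacklist, min_overlap_frac)
    track = partition_classes(grid, scaled, mappable)
    track.raw = raw
    return track
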