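"""pG4-cluster coverage in fixed genome bins and its summary by RT class.

Coverage uses the strand-combined, disjoint cluster intervals, so a base is
counted once regardless of how many motifs or strands cover it. The
headline statistic is the early:late enrichment fold — the ratio of the
Early-quintile coverage statistic to the Late-quintile one.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Sequence

import numpy as np
import pandas as pd

from ._intervals import IntervalSet
from .io_formats import BinGrid
from .pg4_clusters import PG4Cluster
from .rt_segmentation import N_CLASSES, RT_CLASSES, RTTrack


@dataclasses.dataclass
class CoverageTrack:
    """Per-bin covered bp and coverage fraction of the combined cluster set."""

    grid: BinGrid
    covered_bp: np.ndarray
    fraction: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.grid.chrom,
                "start": self.grid.start,
                "end": self.grid.end,
                "covered_bp": self.covered_bp,
                "fraction": self.fraction,
            }
        )


def clusters_by_chrom(clusters: Sequence[PG4Cluster]) -> dict[str, IntervalSet]:
    """Index disjoint cluster intervals per chromosome for fast queries."""
    by: dict[str, list[PG4Cluster]] = defaultdict(list)
    for c in clusters:
        by[c.interval.chrom].append(c)
    return {
        chrom: IntervalSet(
            np.array([c.interval.start for c in cs], dtype=np.int64),
            np.array([c.interval.end for c in cs], dtype=np.int64),
        )
        for chrom, cs in by.items()
    }


def bin_coverage(clusters: Sequence[PG4Cluster], grid: BinGrid) -> CoverageTrack:
    """Covered bp and fraction per bin from the combined cluster set.

    Cluster intervals beyond the chromosome end are a validation error; the
    terminal (possibly short) bin's fraction uses its true length.
    """
    for c in clusters:
        grid.genome.validate(c.interval)
    covered = np.zeros(len(grid), dtype=np.int64)
    for chrom, iset in clusters_by_chrom(clusters).items():
        sl = grid.chrom_slice(chrom)
        covered[sl] = iset.overlap_bp(grid.start[sl], grid.end[sl])
    fraction = covered / grid.lengths
    return CoverageTrack(grid=grid, covered_bp=covered, fraction=fraction)


@dataclasses.dataclass
class ClassCoverageSummary:
    """Per-RT-class coverage statistics and the Early/Late enrichment fold."""

    table: pd.DataFrame  # one row per RT class: n_bins, mean, median
    fold_mean: float  # Early mean / Late mean; inf when Late mean is 0
    fold_median: float

    @property
    def fold(self) -> float:
        return self.fold_mean


def class_summary(
    coverage: CoverageTrack,
    rt: RTTrack,
    *,
    include_partial_bins: bool = True,
) -> ClassCoverageSummary:
    """Summarize bin coverage fractions within each RT quintile.

    Reports n, mean and median fraction per class and the Early/Late fold
    on both statistics (the fold is flagged infinite when the Late
    statistic is zero and NaN when both are zero).
    """
    if len(coverage.grid) != len(rt.grid):
        raise ValueError("coverage and RT tracks defined on different grids")
    frac = coverage.fraction
    keep = rt.classes >= 0
    if not include_partial_bins:
        keep &= coverage.grid.lengths == coverage.grid.bin_size
    rows = []
    stats = {}
    for k in range(N_CLASSES):
        vals = frac[keep & (rt.classes == k)]
        mean = float(np.mean(vals)) if vals.size else np.nan
        median = float(np.median(vals)) if vals.size else np.nan
        rows.append(
            {"rt_class": RT_CLASSES[k], "n_bins": int(vals.size), "mean_fraction": mean,
             "median_fraction": median}
        )
        stats[RT_CLASSES[k]] = (mean, median)
    table = pd.DataFrame(rows)

    def _fold(early: float, late: float) -> float:
        if np.isnan(early) or np.isnan(late):
            return float("nan")
        if late == 0:
            return float("nan") if early == 0 else float("inf")
        return early / late

    fold_mean = _fold(stats["Early"][0], stats["Late"][0])
    fold_median = _fold(stats["Early"][1], stats["Late"][1])
    return ClassCoverageSummary(table=table, fold_mean=fold_mean, fold_median=fold_median)
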