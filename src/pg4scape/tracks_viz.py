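"""Display-ready genome tracks and optional figure rendering.

Everything here is presentational: values are transformed (fourth root for
the heavy-tailed coverage fractions), smoothed with a 21-bin sliding window
that never crosses a chromosome boundary, and the earliest/latest 20% of
the mappable genome is highlighted. No operation in this module changes a
numeric analysis result — figures are drawn from already-computed tables.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import BinGrid, GenomicInterval
from .rt_segmentation import N_CLASSES, RTTrack


def _centered_window_sum(x: np.ndarray, window: int) -> np.ndarray:
    """Sum over a centered window of odd width, truncated at the edges.

    Unlike np.convolve(mode="same") this stays aligned when the window is
    wider than the array itself.
    """
    half = (window - 1) // 2
    full = np.convolve(x, np.ones(window), mode="full")
    return full[half : half + x.size]


def fourth_root(values: np.ndarray) -> np.ndarray:
    """y = x**0.25 elementwise; order-preserving, maps [0,1] onto [0,1]."""
    values = np.asarray(values, dtype=float)
    if np.any(values[np.isfinite(values)] < 0):
        raise ValueError("fourth_root requires non-negative input")
    return values**0.25


def sliding_smooth_bins(
    values: np.ndarray,
    grid: BinGrid,
    window: int = 21,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Centered masked moving average per chromosome.

    ``mask`` marks bins to exclude (blacklisted/missing); excluded bins
    contribute to neither numerator nor denominator and stay NaN in the
    output. The window truncates at chromosome edges.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    excluded = np.isnan(values)
    if mask is not None:
        excluded = excluded | np.asarray(mask, dtype=bool)
    for chrom in grid.genome.chroms:
        sl = grid.chrom_slice(chrom)
        v = values[sl]
        ok = ~excluded[sl]
        num = _centered_window_sum(np.where(ok, v, 0.0), window)
        den = _centered_window_sum(ok.astype(float), window)
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = num / den
        sm[den == 0] = np.nan
        sm[~ok] = np.nan
        out[sl] = sm
    return out


def _runs_to_intervals(grid: BinGrid, indices: np.ndarray) -> list[GenomicInterval]:
    """Merge adjacent selected bins into maximal highlight intervals."""
    out: list[GenomicInterval] = []
    if indices.size == 0:
        return out
    indices = np.sort(indices)
    breaks = np.flatnonzero(
        (np.diff(indices) != 1) | (grid.chrom[indices[1:]] != grid.chrom[indices[:-1]])
    )
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [indices.size - 1]))
    for a, b in zip(starts, ends):
        i, j = indices[a], indices[b]
        out.append(GenomicInterval(str(grid.chrom[i]), int(grid.start[i]), int(grid.end[j])))
    return out


def highlight_extremes(
    rt: RTTrack, fraction: float = 0.20
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Earliest- and latest-replicating highlight intervals.

    Selects the top ``fraction`` of mappable bins by scaled RT (and the
    bottom ``fraction``), using the same descending-score / genomic-order
    ranking as the quintile partition, so at fraction 0.2 the two sets
    coincide exactly with the Early and Late quintile classes. Adjacent
    selected bins merge into one interval.
    """
    if not (0 < fraction <= 0.5):
        raise ValueError("fraction must be in (0, 0.5]")
    eligible = rt.mappable & ~np.isnan(rt.scaled)
    idx = np.flatnonzero(eligible)
    n = idx.size
    if n == 0:
        raise ValueError("no mappable scored bins")
    order = idx[np.argsort(-rt.scaled[idx], kind="stable")]
    # counts mirror the quintile rule (ceil(f*n) earliest, floor(f*n) latest),
    # in exact rational arithmetic so 0.2 * 15 selects 3 bins, not 4
    frac = Fraction(fraction).limit_denominator(10**6)
    n_early = -((-n * frac.numerator) // frac.denominator)
    n_late = (n * frac.numerator) // frac.denominator
    early_idx = order[:n_early]
    late_idx = order[n - n_late :] if n_late > 0 else order[:0]
    return _runs_to_intervals(rt.grid, early_idx), _runs_to_intervals(rt.grid, late_idx)


def prepare_coverage_display(
    fraction: np.ndarray,
    grid: BinGrid,
    window: int = 21,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Coverage ring values: fourth root then sliding-window smoothing."""
    return sliding_smooth_bins(fourth_root(fraction), grid, window=window, mask=mask)


# ---------------------------------------------------------------------------
# rendering (matplotlib; optional, never computes numbers)

def _require_matplotlib():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def render_circos(
    grid: BinGrid,
    rings: dict[str, np.ndarray],
    highlights: tuple[Sequence[GenomicInterval], Sequence[GenomicInterval]] | None,
    cfs_intervals: Sequence[GenomicInterval],
    path,
) -> pd.DataFrame:
    """Multi-ring circular genome plot (coverage, RT, GC, CFS, extremes).

    Returns the plotted series as a tidy DataFrame so determinism can be
    checked on data rather than pixels.
    """
    plt = _require_matplotlib()
    n = len(grid)
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(7, 7))
    ax.set_xticks([])
    ax.set_yticks([])
    series = []
    radius = 1.0
    for name, vals in rings.items():
        vals = np.asarray(vals, dtype=float)
        scaled = np.where(np.isfinite(vals), vals, 0.0)
        ax.bar(theta, 0.18 * scaled, width=2 * np.pi / n, bottom=radius, linewidth=0)
        series.append(pd.DataFrame({"ring": name, "bin": np.arange(n), "value": vals}))
        radius += 0.25
    if highlights is not None:
        for label, ivset, color in (
            ("earliest", highlights[0], "grey"),
            ("latest", highlights[1], "orange"),
        ):
            for iv in ivset:
                sl = grid.chrom_slice(iv.chrom)
                b0 = sl.start + iv.start // grid.bin_size
                b1 = sl.start + (iv.end - 1) // grid.bin_size
                ax.axvspan(theta[b0], theta[min(b1, n - 1)], color=color, alpha=0.2)
    for iv in cfs_intervals:
        sl = grid.chrom_slice(iv.chrom)
        b0 = sl.start + iv.start // grid.bin_size
        ax.plot([theta[b0]], [radius], marker="|", color="red")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return pd.concat(series, ignore_index=True) if series else pd.DataFrame()


def render_violin(gene_coverage: pd.DataFrame, test_table: pd.DataFrame, path) -> pd.DataFrame:
    """Violin plot of log2 gene-body coverage per gene class."""
    plt = _require_matplotlib()
    classes = sorted(gene_coverage["gene_class"].dropna().unique())
    data = [gene_coverage.loc[gene_coverage["gene_class"] == c, "log2_coverage"].to_numpy()
            for c in classes]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(classes) + 1), classes)
    ax.set_ylabel("log2 pG4 cluster coverage")
    if not test_table.empty:
        p = test_table["p_value"].iloc[0]
        ax.set_title(f"Kruskal-Wallis p = {p:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return gene_coverage[["gene_class", "log2_coverage"]].copy()


def render_tss_profiles(profiles: dict[str, pd.DataFrame], path) -> pd.DataFrame:
    """Line plot of smoothed TSS coverage profiles per gene class."""
    plt = _require_matplotlib()
    fig, ax = plt.subplots(figsize=(6, 4))
    frames = []
    for cls, df in profiles.items():
        ax.plot(df["offset"], df["fraction"], label=cls)
        tagged = df.copy()
        tagged["gene_class"] = cls
        frames.append(tagged)
    ax.set_xlabel("distance from TSS (bp)")
    ax.set_ylabel("fraction of genes covered")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
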