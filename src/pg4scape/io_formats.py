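"""Readers and writers for the UCSC-ecosystem formats the pipeline consumes.

All coordinates are 0-based half-open (BED convention) throughout the
package. Missing data is always explicit (NaN in tracks), never zero:
a bin with no signal and a bin with zero signal are different things.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

STRAND_PLUS = "+"
STRAND_MINUS = "-"
STRAND_NONE = "."

_VALID_STRANDS = frozenset({STRAND_PLUS, STRAND_MINUS, STRAND_NONE})


class BedParseError(ValueError):
    """Raised for a malformed BED/bedGraph line; carries the line number."""


@dataclasses.dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = STRAND_NONE

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomeIndex:
    """Ordered chromosome names and lengths (a chrom.sizes equivalent)."""

    def __init__(self, sizes: Iterable[tuple[str, int]]):
        self._sizes: dict[str, int] = {}
        for name, length in sizes:
            if name in self._sizes:
                raise ValueError(f"duplicate chromosome name {name!r}")
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            self._sizes[name] = int(length)

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeIndex":
        sizes = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise BedParseError(f"{path}:{lineno}: expected 2 columns")
                sizes.append((fields[0], int(fields[1])))
        return cls(sizes)

    def to_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self._sizes.items():
                fh.write(f"{name}\t{length}\n")

    @property
    def chroms(self) -> list[str]:
        return list(self._sizes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __len__(self) -> int:
        return len(self._sizes)

    def length(self, chrom: str) -> int:
        return self._sizes[chrom]

    def items(self):
        return self._sizes.items()

    @property
    def total_bp(self) -> int:
        return sum(self._sizes.values())

    def validate(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self._sizes:
            raise ValueError(f"chromosome {iv.chrom!r} not in genome index")
        if iv.end > self._sizes[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} extends beyond "
                f"chromosome length {self._sizes[iv.chrom]}"
            )


class BinGrid:
    """Non-overlapping fixed-size bins tiling every chromosome of a genome.

    The last bin of a chromosome may be shorter than ``bin_size``. Bins are
    stored as flat arrays in chromosome order; every per-bin track in the
    package is aligned to this flat order.
    """

    def __init__(self, genome: GenomeIndex, bin_size: int = 50_000):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.genome = genome
        self.bin_size = int(bin_size)
        chroms, starts, ends = [], [], []
        self._offsets: dict[str, tuple[int, int]] = {}
        pos = 0
        for name, length in genome.items():
            n = -(-length // bin_size)  # ceil division
            bs = np.arange(n, dtype=np.int64) * bin_size
            be = np.minimum(bs + bin_size, length)
            chroms.extend([name] * n)
            starts.append(bs)
            ends.append(be)
            self._offsets[name] = (pos, pos + n)
            pos += n
        self.chrom = np.array(chroms)
        self.start = np.concatenate(starts) if starts else np.empty(0, np.int64)
        self.end = np.concatenate(ends) if ends else np.empty(0, np.int64)

    def __len__(self) -> int:
        return int(self.start.size)

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def chrom_slice(self, chrom: str) -> slice:
        lo, hi = self._offsets[chrom]
        return slice(lo, hi)

    def bin_index(self, chrom: str, pos: int) -> int:
        lo, _ = self._offsets[chrom]
        return lo + pos // self.bin_size


@dataclasses.dataclass
class BinnedTrack:
    """A per-bin numeric value on a BinGrid; NaN marks missing bins."""

    grid: BinGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.grid),):
            raise ValueError("track length does not match grid")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)


def _parse_bed_line(line: str, lineno: int, path, stranded: bool) -> GenomicInterval:
    fields = line.split("\t")
    min_cols = 6 if stranded else 3
    if len(fields) < min_cols:
        raise BedParseError(f"{path}:{lineno}: expected >= {min_cols} columns, got {len(fields)}")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
    strand = STRAND_NONE
    if stranded:
        strand = fields[5]
        if strand not in (STRAND_PLUS, STRAND_MINUS):
            raise BedParseError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
    try:
        return GenomicInterval(chrom, start, end, strand)
    except ValueError as exc:
        raise BedParseError(f"{path}:{lineno}: {exc}") from exc


def read_bed(
    path: str | Path, stranded: bool = False, genome: GenomeIndex | None = None
) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into GenomicIntervals, preserving input order.

    With ``stranded=True`` the strand column (6) is required and must be
    + or -. If a genome index is given every record is validated against it.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            iv = _parse_bed_line(line, lineno, path, stranded)
            if genome is not None:
                genome.validate(iv)
            out.append(iv)
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence | None = None,
) -> None:
    """Write intervals as BED3, or BED6 when any record is stranded.

    ``names``/``scores`` fill columns 4-5 (defaults "." and 0) whenever six
    columns are emitted.
    """
    six = any(iv.strand != STRAND_NONE for iv in intervals) or names is not None or scores is not None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if six:
                name = names[i] if names is not None else "."
                score = scores[i] if scores is not None else 0
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bedgraph_binned(path: str | Path, grid: BinGrid) -> BinnedTrack:
    """Aggregate a bedGraph onto a bin grid by length-weighted mean.

    Each bin's value is the mean of the bedGraph values over the bases of
    the bin that any record covers; bins no record touches are NaN. This
    conserves signal mass: sum(bin value x covered bp) equals
    sum(record value x record bp) after clipping to the grid.
    """
    n = len(grid)
    wsum = np.zeros(n)
    cov = np.zeros(n, dtype=np.int64)
    bs = grid.bin_size
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 columns")
            chrom = fields[0]
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: bad numeric field") from exc
            if chrom not in grid.genome:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if end > grid.genome.length(chrom) or start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: record {chrom}:{start}-{end} outside chromosome bounds"
                )
            lo, _ = grid._offsets[chrom]
            first = start // bs
            last = (end - 1) // bs
            for b in range(first, last + 1):
                seg = min(end, (b + 1) * bs) - max(start, b * bs)
                wsum[lo + b] += value * seg
                cov[lo + b] += seg
    values = np.full(n, np.nan)
    nz = cov > 0
    values[nz] = wsum[nz] / cov[nz]
    track = BinnedTrack(grid, values)
    track.covered_bp = cov  # covered bases per bin, for mass-conservation checks
    return track


def write_bedgraph(grid: BinGrid, values: np.ndarray, path: str | Path) -> None:
    """Write one value per bin as bedGraph, skipping NaN bins."""
    with open(path, "w") as fh:
        for chrom, start, end, v in zip(grid.chrom, grid.start, grid.end, values):
            if np.isnan(v):
                continue
            fh.write(f"{chrom}\t{start}\t{end}\t{v:g}\n")


def gc_per_bin(fasta_path: str | Path, grid: BinGrid) -> BinnedTrack:
    """GC% per bin: 100*(G+C)/(A+C+G+T), case-insensitive, Ns excluded.

    Bins with no unambiguous base are NaN. Every grid chromosome must be
    present in the FASTA.
    """
    from pyfaidx import Fasta

    fasta = Fasta(str(fasta_path), rebuild=True)
    values = np.full(len(grid), np.nan)
    for chrom in grid.genome.chroms:
        if chrom not in fasta:
            raise ValueError(f"chromosome {chrom!r} missing from FASTA")
        seq = str(fasta[chrom][:]).upper()
        sl = grid.chrom_slice(chrom)
        for i in range(sl.start, sl.stop):
            sub = seq[grid.start[i] : grid.end[i]]
            gc = sub.count("G") + sub.count("C")
            acgt = gc + sub.count("A") + sub.count("T")
            if acgt > 0:
                values[i] = 100.0 * gc / acgt
    return BinnedTrack(grid, values)
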