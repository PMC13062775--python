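"""Seeded synthetic genomes with the statistical structure the analysis assumes.

The generator emits everything the pipeline consumes — chrom.sizes, six
Repli-seq phase bedGraphs, stranded pG4 motif BED, gene/SDR/blacklist BEDs —
plus the ground truth (per-bin timing, per-gene class, planted parameters)
so parameter-recovery tests can quantify what the pipeline gets back.

Model in brief:

* Replication timing is bimodal, as in real mammalian genomes: most domains
  are constitutively early (timing near 1) or late (near 0), with a minority
  of transition domains spanning intermediate values.
* Six-phase signal per bin is a discretized Gaussian bell over the phase
  centers (11/12, 9/12, ... 1/12) at the bin's timing, times multiplicative
  log-normal noise; at zero noise and infinite concentration the signal is
  one-hot, which makes the RT formula checks exact.
* pG4 cluster seeds follow a Poisson process whose rate is log-linear in
  timing, interpolating motif_rate_late -> motif_rate_early, with a
  sharply TSS-centered Gaussian extra rate (sd = tss_window/6; mass equal to a
  (tss_enrichment - 1)-fold boost over a +/- tss_window flat window). Each
  seed expands into k motifs separated by gaps <= 100 bp on one strand.
* Long (> 200 kb) genes are placed in late domains — a configurable subset
  carries an SDR/SDW interval (true CFS class) — and short genes in early
  domains; blacklist intervals avoid genes.

Identical config + seed give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .gene_classes import CFS, LONG_NON_CFS, SHORT, GeneRecord
from .io_formats import (
    STRAND_MINUS,
    STRAND_PLUS,
    BinGrid,
    GenomeIndex,
    GenomicInterval,
    write_bed,
)

PHASE_CENTERS = (np.arange(6)[::-1] * 2 + 1) / 12.0  # 11/12 (S1) ... 1/12 (S6)
PHASE_NAMES = ("S1", "S2", "S3", "S4", "S5", "S6")


@dataclasses.dataclass
class SyntheticConfig:
    """All knobs of the generator; the seed fully determines the output."""

    seed: int = 0
    chrom_sizes: tuple = (("chr1", 60_000_000), ("chr2", 60_000_000))
    bin_size: int = 50_000
    # RT domain structure
    n_domains_per_chrom: int = 30
    p_early_domain: float = 0.35
    p_late_domain: float = 0.35
    extreme_edge: float = 0.08  # early domains: timing in [1-edge, 1]; late: [0, edge]
    # six-phase signal
    phase_concentration: float = 8.0
    noise_sd: float = 0.1  # sigma of multiplicative log-normal noise
    depth: float = 100.0
    # pG4 motif process
    motif_rate_early: float = 10.0  # motifs per 50 kb at timing 1
    motif_rate_late: float = 1.0  # motifs per 50 kb at timing 0
    cluster_size_min: int = 2
    cluster_size_poisson: float = 0.5  # k = min + Poisson(this)
    motif_length_range: tuple = (20, 50)
    intra_cluster_gap_range: tuple = (1, 100)
    tss_enrichment: float = 3.0
    tss_window: int = 2_000
    # gene architecture
    n_long_genes: int = 100
    long_gene_length_range: tuple = (210_000, 300_000)
    sdr_prob: float = 0.4
    n_short_genes: int = 250
    short_gene_length_range: tuple = (5_000, 150_000)
    late_timing_max: float = 0.30  # long genes go to domains at or below
    early_timing_min: float = 0.70  # short genes go to domains at or above
    # blacklist
    blacklist_fraction: float = 0.05
    blacklist_interval_len: int = 200_000

    @property
    def planted_fold(self) -> float:
        if self.motif_rate_late == 0:
            return float("inf")
        return self.motif_rate_early / self.motif_rate_late

    @property
    def mean_cluster_size(self) -> float:
        return self.cluster_size_min + self.cluster_size_poisson

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chrom_sizes"] = [list(x) for x in self.chrom_sizes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key in ("chrom_sizes", "motif_length_range", "intra_cluster_gap_range",
                    "long_gene_length_range", "short_gene_length_range"):
            if key in d:
                v = d[key]
                d[key] = tuple(tuple(x) if isinstance(x, (list, tuple)) else x for x in v) \
                    if key == "chrom_sizes" else tuple(v)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclasses.dataclass
class Domain:
    chrom: str
    start: int
    end: int
    timing: float


@dataclasses.dataclass
class SyntheticDataset:
    """A generated genome plus its ground truth."""

    config: SyntheticConfig
    genome: GenomeIndex
    grid: BinGrid
    domains: list
    bin_timing: np.ndarray  # true timing per grid bin
    phases: np.ndarray  # (n_bins, 6) signal
    motifs: list  # stranded GenomicIntervals
    genes: list  # GeneRecords with true gene_class set
    sdr: list
    blacklist: list

    @property
    def truth(self) -> dict:
        return {
            "planted_fold": self.config.planted_fold,
            "tss_enrichment": self.config.tss_enrichment,
            "n_true_cfs": sum(g.gene_class == CFS for g in self.genes),
        }


def _gen_domains(config: SyntheticConfig, rng: np.random.Generator) -> list:
    """Cut each chromosome into bin-aligned domains with bimodal timings."""
    domains = []
    bs = config.bin_size
    edge = config.extreme_edge
    p_mid = 1.0 - config.p_early_domain - config.p_late_domain
    if p_mid < 0:
        raise ValueError("domain-kind probabilities sum to more than 1")
    for chrom, length in config.chrom_sizes:
        n_bins = -(-length // bs)
        n_dom = min(config.n_domains_per_chrom, n_bins)
        # stratified cuts: one boundary per stratum, jittered, so domain sizes
        # stay within ~2.5x of each other and gene packing remains feasible
        u = rng.uniform(0.25, 0.75, size=n_dom - 1)
        cuts = np.unique(((np.arange(n_dom - 1) + 1 + u - 0.5) * n_bins / n_dom).astype(int))
        cuts = cuts[(cuts >= 1) & (cuts < n_bins)]
        n_dom = cuts.size + 1
        bounds = np.concatenate(([0], cuts, [n_bins])) * bs
        kinds = rng.choice(
            3, size=n_dom,
            p=[config.p_early_domain, config.p_late_domain, p_mid],
        )
        for i in range(n_dom):
            if kinds[i] == 0:
                t = rng.uniform(1.0 - edge, 1.0)
            elif kinds[i] == 1:
                t = rng.uniform(0.0, edge)
            else:
                t = rng.uniform(edge, 1.0 - edge)
            domains.append(
                Domain(chrom, int(bounds[i]), int(min(bounds[i + 1], length)), float(t))
            )
    return domains


def _bin_timing(grid: BinGrid, domains: Sequence[Domain]) -> np.ndarray:
    timing = np.zeros(len(grid))
    for d in domains:
        sl = grid.chrom_slice(d.chrom)
        lo = sl.start + d.start // grid.bin_size
        hi = sl.start + -(-d.end // grid.bin_size)
        timing[lo:hi] = d.timing
    return timing


def gen_rt_and_phases(
    config: SyntheticConfig,
    grid: BinGrid,
    domains: Sequence[Domain],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin true timing and noisy six-phase signal matrix.

    Phase j gets weight exp(-kappa * z^2 / 2) with z the timing distance to
    the phase center in units of the inter-center spacing (1/6), normalized
    per bin, scaled by depth and multiplied by log-normal noise.
    """
    timing = _bin_timing(grid, domains)
    z2 = ((timing[:, None] - PHASE_CENTERS[None, :]) * 6.0) ** 2
    # subtract the row minimum (softmax trick) so extreme concentrations
    # underflow to a clean one-hot instead of 0/0
    z2 -= z2.min(axis=1, keepdims=True)
    w = np.exp(-config.phase_concentration * z2 / 2.0)
    w /= w.sum(axis=1, keepdims=True)
    noise = (
        rng.lognormal(mean=0.0, sigma=config.noise_sd, size=w.shape)
        if config.noise_sd > 0
        else 1.0
    )
    phases = config.depth * w * noise
    return timing, phases


def _seed_rate(config: SyntheticConfig, timing: np.ndarray) -> np.ndarray:
    """Cluster-seed rate per bin (seeds / bin_size bp) at each bin's timing."""
    early, late = config.motif_rate_early, config.motif_rate_late
    if late > 0:
        motif_rate = late * (early / late) ** timing  # log-linear in timing
    else:
        motif_rate = early * timing  # degenerate fold: linear, zero at timing 0
    return motif_rate / config.mean_cluster_size


def _expand_seed(
    config: SyntheticConfig,
    chrom: str,
    chrom_len: int,
    pos: int,
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    k = config.cluster_size_min + (
        rng.poisson(config.cluster_size_poisson) if config.cluster_size_poisson > 0 else 0
    )
    strand = STRAND_PLUS if rng.random() < 0.5 else STRAND_MINUS
    lmin, lmax = config.motif_length_range
    gmin, gmax = config.intra_cluster_gap_range
    motifs = []
    cur = pos
    for _ in range(k):
        length = int(rng.integers(lmin, lmax + 1))
        end = cur + length
        if end > chrom_len:
            break
        motifs.append(GenomicInterval(chrom, cur, end, strand))
        cur = end + int(rng.integers(gmin, gmax + 1))
    return motifs


def gen_pg4_motifs(
    config: SyntheticConfig,
    grid: BinGrid,
    timing: np.ndarray,
    genes: Sequence[GeneRecord],
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    """Place cluster seeds by a timing-coupled Poisson process and expand them.

    The TSS component adds Gaussian-positioned seeds (sd = tss_window / 6)
    whose total expected mass equals a (tss_enrichment - 1)-fold boost of the
    local rate over a flat +/- tss_window window.
    """
    motifs: list[GenomicInterval] = []
    rates = _seed_rate(config, timing)
    bin_len = grid.lengths
    counts = rng.poisson(rates * (bin_len / config.bin_size))
    for i in np.flatnonzero(counts):
        chrom = str(grid.chrom[i])
        chrom_len = grid.genome.length(chrom)
        positions = rng.integers(grid.start[i], grid.end[i], size=counts[i])
        for pos in sorted(int(p) for p in positions):
            motifs.extend(_expand_seed(config, chrom, chrom_len, pos, rng))
    if config.tss_enrichment > 1 and genes:
        sd = config.tss_window / 6.0  # sharply promoter-proximal, as real G4 density is
        for g in genes:
            b = grid.bin_index(g.interval.chrom, g.tss)
            local = rates[b]
            mean_extra = (config.tss_enrichment - 1.0) * local * (
                2.0 * config.tss_window / config.bin_size
            )
            n_extra = rng.poisson(mean_extra)
            if n_extra == 0:
                continue
            chrom_len = grid.genome.length(g.interval.chrom)
            offs = rng.normal(0.0, sd, size=n_extra)
            for off in offs:
                pos = int(np.clip(g.tss + off, 0, chrom_len - 1))
                motifs.extend(
                    _expand_seed(config, g.interval.chrom, chrom_len, pos, rng)
                )
    motifs.sort(key=lambda m: (m.chrom, m.start, m.end))
    return motifs


def _place_genes(
    config: SyntheticConfig,
    eligible: list[Domain],
    lengths: np.ndarray,
    prefix: str,
    rng: np.random.Generator,
) -> list[GeneRecord]:
    """Greedy non-overlapping placement of genes into eligible domains."""
    if not eligible:
        raise ValueError(f"no eligible domains to place {prefix} genes into")
    free = [[d.chrom, d.start, d.end] for d in eligible]
    capacity = sum(e - s for _, s, e in free)
    if lengths.sum() > 0.95 * capacity:
        raise ValueError(
            f"cannot pack {prefix} genes: need {lengths.sum()} bp, "
            f"eligible domains offer only {capacity} bp; enlarge the genome, "
            "reduce gene counts/lengths, or relax the timing eligibility bounds"
        )
    genes = []
    # left-pack genes into slots with small random inter-gene gaps; packing
    # by the roomiest slot avoids fragmentation failures at high occupancy
    for gi, length in enumerate(lengths):
        gap = int(rng.integers(2_000, 10_001))
        slots = [j for j, (_, cur, e) in enumerate(free) if e - cur >= length + gap]
        if not slots:
            raise ValueError(
                f"cannot pack {prefix} gene of {length} bp: no remaining slot is "
                "large enough; enlarge the genome, reduce gene counts/lengths, "
                "or relax the timing eligibility bounds"
            )
        j = max(slots, key=lambda j: free[j][2] - free[j][1])
        chrom, cur, e = free[j]
        start = cur + gap
        strand = STRAND_PLUS if rng.random() < 0.5 else STRAND_MINUS
        genes.append(
            GeneRecord(
                id=f"{prefix}_{gi + 1}",
                interval=GenomicInterval(chrom, start, start + int(length), strand),
            )
        )
        free[j][1] = start + int(length)
    return genes


def gen_genes_and_blacklist(
    config: SyntheticConfig,
    genome: GenomeIndex,
    domains: Sequence[Domain],
    rng: np.random.Generator,
) -> tuple[list[GeneRecord], list[GenomicInterval], list[GenomicInterval]]:
    """Genes (with true classes), SDR/SDW intervals, and blacklist intervals."""
    late_doms = [d for d in domains if d.timing <= config.late_timing_max]
    early_doms = [d for d in domains if d.timing >= config.early_timing_min]
    long_lens = rng.integers(*config.long_gene_length_range, size=config.n_long_genes) \
        if config.n_long_genes else np.empty(0, dtype=np.int64)
    short_lens = rng.integers(*config.short_gene_length_range, size=config.n_short_genes) \
        if config.n_short_genes else np.empty(0, dtype=np.int64)
    long_genes = _place_genes(config, late_doms, long_lens, "longgene", rng) \
        if config.n_long_genes else []
    short_genes = _place_genes(config, early_doms, short_lens, "shortgene", rng) \
        if config.n_short_genes else []

    sdr: list[GenomicInterval] = []
    for g in long_genes:
        if rng.random() < config.sdr_prob:
            # SDR/SDW placed inside the gene (middle half) so overlap is certain
            iv = g.interval
            q = iv.length // 4
            sdr.append(GenomicInterval(iv.chrom, iv.start + q, iv.end - q))
            g.sdr_overlap = True
            g.gene_class = CFS
        else:
            g.gene_class = LONG_NON_CFS
    for g in short_genes:
        g.gene_class = SHORT
    genes = long_genes + short_genes
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start))

    blacklist = _gen_blacklist(config, genome, genes, rng)
    return genes, sdr, blacklist


def _gen_blacklist(
    config: SyntheticConfig,
    genome: GenomeIndex,
    genes: Sequence[GeneRecord],
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    target = int(config.blacklist_fraction * genome.total_bp)
    if target <= 0:
        return []
    length = config.blacklist_interval_len
    chroms = genome.chroms
    sizes = np.array([genome.length(c) for c in chroms], dtype=float)
    placed: list[GenomicInterval] = []
    covered = 0
    attempts = 0
    gene_ivs = [(g.interval.chrom, g.interval.start, g.interval.end) for g in genes]
    while covered < target and attempts < 10_000:
        attempts += 1
        ci = rng.choice(len(chroms), p=sizes / sizes.sum())
        chrom = chroms[ci]
        if genome.length(chrom) <= length:
            continue
        start = int(rng.integers(0, genome.length(chrom) - length))
        end = start + length
        clash = any(
            c == chrom and start < e and s < end for c, s, e in gene_ivs
        ) or any(
            iv.chrom == chrom and start < iv.end and iv.start < end for iv in placed
        )
        if clash:
            continue
        placed.append(GenomicInterval(chrom, start, end))
        covered += length
    placed.sort(key=lambda iv: (iv.chrom, iv.start))
    return placed


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset from a config (deterministic in seed)."""
    rng = np.random.default_rng(config.seed)
    genome = GenomeIndex(config.chrom_sizes)
    grid = BinGrid(genome, config.bin_size)
    domains = _gen_domains(config, rng)
    timing, phases = gen_rt_and_phases(config, grid, domains, rng)
    genes, sdr, blacklist = gen_genes_and_blacklist(config, genome, domains, rng)
    motifs = gen_pg4_motifs(config, grid, timing, genes, rng)
    return SyntheticDataset(
        config=config,
        genome=genome,
        grid=grid,
        domains=domains,
        bin_timing=timing,
        phases=phases,
        motifs=motifs,
        genes=genes,
        sdr=sdr,
        blacklist=blacklist,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write a dataset as the plain-text files the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["chrom_sizes"] = outdir / "chrom.sizes"
    ds.genome.to_chrom_sizes(paths["chrom_sizes"])

    grid = ds.grid
    for j, name in enumerate(PHASE_NAMES):
        p = outdir / f"{name.lower()}.bedgraph"
        with open(p, "w") as fh:
            for i in range(len(grid)):
                fh.write(
                    f"{grid.chrom[i]}\t{grid.start[i]}\t{grid.end[i]}\t"
                    f"{ds.phases[i, j]:.6f}\n"
                )
        paths[name.lower()] = p

    paths["motifs"] = outdir / "pg4_motifs.bed"
    write_bed(ds.motifs, paths["motifs"],
              names=[f"pG4_{i+1}" for i in range(len(ds.motifs))])

    paths["genes"] = outdir / "genes.bed"
    write_bed(
        [g.interval for g in ds.genes], paths["genes"],
        names=[g.id for g in ds.genes],
    )
    paths["sdr"] = outdir / "sdr.bed"
    write_bed(ds.sdr, paths["sdr"])
    paths["blacklist"] = outdir / "blacklist.bed"
    write_bed(ds.blacklist, paths["blacklist"])

    paths["truth_bins"] = outdir / "truth_bins.tsv"
    with open(paths["truth_bins"], "w") as fh:
        fh.write("chrom\tstart\tend\ttrue_timing\n")
        for i in range(len(grid)):
            fh.write(f"{grid.chrom[i]}\t{grid.start[i]}\t{grid.end[i]}\t{ds.bin_timing[i]:.6f}\n")

    paths["truth_genes"] = outdir / "truth_genes.tsv"
    with open(paths["truth_genes"], "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\ttrue_class\n")
        for g in ds.genes:
            iv = g.interval
            fh.write(f"{g.id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{g.gene_class}\n")

    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump({**ds.truth, "config": ds.config.to_dict()}, fh, indent=1, sort_keys=True)
    return paths
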