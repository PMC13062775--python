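"""End-to-end pipeline: clusters -> RT segmentation -> coverage -> gene
classes -> TSS profiles -> display tracks, with a run manifest.

Every stage reads and writes plain files (BED/bedGraph/TSV), so stages are
independently re-runnable and a fixed config + seed reproduces numerically
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coverage_analysis import bin_coverage, class_summary
from .gene_classes import (
    GENE_CLASSES,
    classify_genes,
    compare_classes,
    gene_body_coverage,
    read_genes,
)
from .io_formats import (
    BinGrid,
    GenomeIndex,
    read_bed,
    read_bedgraph_binned,
    write_bed,
)
from .pg4_clusters import (
    STRAND_COMBINED,
    clusters_to_bed,
    combine_strands,
    detect_clusters,
)
from .rt_segmentation import segment_rt, RT_CLASSES
from .tracks_viz import highlight_extremes, prepare_coverage_display
from .tss_profile import profiles_by_class

PHASE_KEYS = ("s1", "s2", "s3", "s4", "s5", "s6")
FLOAT_FORMAT = "%.10g"


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclasses.dataclass
class PipelineParams:
    bin_size: int = 50_000
    max_gap: int = 100
    min_motifs: int = 2
    exclude_tss_bp: int = 2_000
    length_threshold: int = 200_000
    pseudocount: float = 1e-4
    flank: int = 10_000
    smooth_bp: int = 200
    window_bins: int = 21
    highlight_fraction: float = 0.20
    min_overlap_frac: float = 0.0


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def validate_inputs(inputs: dict) -> dict[str, Path]:
    """Check that every required input file is declared and exists."""
    required = ["chrom_sizes", "motifs", "genes", "sdr", "blacklist"]
    missing = [k for k in required if k not in inputs]
    phases = inputs.get("phases")
    if not isinstance(phases, (list, tuple)) or len(phases) != 6:
        missing.append("phases (exactly six bedGraph paths, S1..S6)")
    if missing:
        raise ConfigError(f"missing input keys: {', '.join(missing)}")
    paths = {k: Path(inputs[k]) for k in required}
    for j, p in enumerate(phases):
        paths[PHASE_KEYS[j]] = Path(p)
    absent = [k for k, p in paths.items() if not p.exists()]
    if absent:
        raise ConfigError(f"input files not found: {', '.join(sorted(absent))}")
    return paths


def run_all(config: dict, outdir, render: bool = False) -> dict[str, Path]:
    """Run every stage in dependency order; returns the written outputs.

    ``config`` carries either a ``simulate`` section (SyntheticConfig fields)
    or an ``inputs`` section with file paths, plus an optional ``params``
    section overriding PipelineParams fields.
    """
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params_dict = config.get("params", {})
    unknown = set(params_dict) - {f.name for f in dataclasses.fields(PipelineParams)}
    if unknown:
        raise ConfigError(f"unknown params keys: {', '.join(sorted(unknown))}")
    params = PipelineParams(**params_dict)

    if "simulate" in config:
        from .synthetic_data import SyntheticConfig, generate, write_dataset

        sim_cfg = SyntheticConfig.from_dict(config["simulate"])
        ds = generate(sim_cfg)
        sim_dir = outdir / "simulated"
        sim_paths = write_dataset(ds, sim_dir)
        inputs = {
            "chrom_sizes": sim_paths["chrom_sizes"],
            "motifs": sim_paths["motifs"],
            "genes": sim_paths["genes"],
            "sdr": sim_paths["sdr"],
            "blacklist": sim_paths["blacklist"],
            "phases": [sim_paths[k] for k in PHASE_KEYS],
        }
    elif "inputs" in config:
        inputs = config["inputs"]
    else:
        raise ConfigError("config needs a 'simulate' or an 'inputs' section")
    paths = validate_inputs(inputs)

    genome = GenomeIndex.from_chrom_sizes(paths["chrom_sizes"])
    grid = BinGrid(genome, params.bin_size)
    outputs: dict[str, Path] = {}

    # stage 1: pG4 clusters
    motifs = read_bed(paths["motifs"], stranded=True, genome=genome)
    clusters = detect_clusters(motifs, max_gap=params.max_gap, min_motifs=params.min_motifs)
    plus = [c for c in clusters if c.strand == "+"]
    minus = [c for c in clusters if c.strand == "-"]
    combined = combine_strands(plus, minus)
    for label, cs in (("plus", plus), ("minus", minus), ("combined", combined)):
        p = outdir / f"clusters_{label}.bed"
        clusters_to_bed(cs, p)
        outputs[f"clusters_{label}"] = p

    # stage 2: RT segmentation
    phase_tracks = [read_bedgraph_binned(paths[k], grid) for k in PHASE_KEYS]
    blacklist = read_bed(paths["blacklist"], genome=genome)
    rt = segment_rt(phase_tracks, blacklist, params.min_overlap_frac)
    outputs["rt"] = outdir / "rt_segmentation.tsv"
    _write_tsv(rt.to_dataframe(), outputs["rt"])

    # stage 3: bin coverage + class summary
    cov = bin_coverage(combined, grid)
    cov_df = cov.to_dataframe()
    cov_df["rt_class"] = rt.to_dataframe()["rt_class"]
    outputs["coverage"] = outdir / "bin_coverage.tsv"
    _write_tsv(cov_df, outputs["coverage"])
    summary = class_summary(cov, rt)
    sm = summary.table.copy()
    sm["fold_early_late_mean"] = summary.fold_mean
    sm["fold_early_late_median"] = summary.fold_median
    outputs["class_summary"] = outdir / "class_coverage_summary.tsv"
    _write_tsv(sm, outputs["class_summary"])

    # stage 4: gene classes, body coverage, Kruskal-Wallis
    genes = read_genes(paths["genes"], genome=genome)
    sdr = read_bed(paths["sdr"], genome=genome)
    genes = classify_genes(genes, sdr, params.length_threshold)
    gene_frames = {}
    for tag, excl in (("full", 0), ("tss_excluded", params.exclude_tss_bp)):
        df = gene_body_coverage(genes, combined, exclude_tss_bp=excl,
                                pseudocount=params.pseudocount)
        outputs[f"gene_coverage_{tag}"] = outdir / f"gene_coverage_{tag}.tsv"
        _write_tsv(df, outputs[f"gene_coverage_{tag}"])
        gene_frames[tag] = df
        groups = {
            cls: df.loc[df["gene_class"] == cls, "log2_coverage"].to_numpy()
            for cls in GENE_CLASSES
            if (df["gene_class"] == cls).any()
        }
        if len(groups) >= 2:
            test = compare_classes(groups)
            outputs[f"class_test_{tag}"] = outdir / f"class_test_{tag}.tsv"
            _write_tsv(test, outputs[f"class_test_{tag}"])

    # stage 5: TSS profiles per class
    classed = [g for g in genes if g.gene_class in GENE_CLASSES]
    profiles = profiles_by_class(
        classed, combined, flank=params.flank, smooth_bp=params.smooth_bp, genome=genome
    )
    prof_frames = []
    for cls, (raw, smooth) in profiles.items():
        df = raw.to_dataframe().rename(columns={"fraction": "fraction_raw"})
        df["fraction_smoothed"] = smooth.fraction
        df.insert(0, "gene_class", cls)
        prof_frames.append(df)
    outputs["tss_profiles"] = outdir / "tss_profiles.tsv"
    _write_tsv(pd.concat(prof_frames, ignore_index=True), outputs["tss_profiles"])

    # stage 6: display tracks + highlights
    display = prepare_coverage_display(
        cov.fraction, grid, window=params.window_bins, mask=~rt.mappable
    )
    disp_df = pd.DataFrame(
        {
            "chrom": grid.chrom,
            "start": grid.start,
            "end": grid.end,
            "coverage_display": display,
            "rt_scaled": rt.scaled,
        }
    )
    outputs["display_tracks"] = outdir / "display_tracks.tsv"
    _write_tsv(disp_df, outputs["display_tracks"])
    early_hl, late_hl = highlight_extremes(rt, params.highlight_fraction)
    outputs["highlights_early"] = outdir / "highlight_earliest.bed"
    outputs["highlights_late"] = outdir / "highlight_latest.bed"
    write_bed(early_hl, outputs["highlights_early"])
    write_bed(late_hl, outputs["highlights_late"])

    if render:
        from . import tracks_viz

        cfs_ivs = [g.interval for g in genes if g.gene_class == "CFS"]
        outputs["fig_circos"] = outdir / "circos.png"
        tracks_viz.render_circos(
            grid,
            {"pG4_coverage": np.nan_to_num(display), "RT": np.nan_to_num(rt.scaled)},
            (early_hl, late_hl),
            cfs_ivs,
            outputs["fig_circos"],
        )
        test_tag = "class_test_tss_excluded"
        test_df = (
            pd.read_csv(outputs[test_tag], sep="\t") if test_tag in outputs else pd.DataFrame()
        )
        outputs["fig_violin"] = outdir / "violin.png"
        tracks_viz.render_violin(gene_frames["tss_excluded"], test_df, outputs["fig_violin"])
        outputs["fig_tss"] = outdir / "tss_profiles.png"
        tracks_viz.render_tss_profiles(
            {
                cls: pd.DataFrame({"offset": sm.offsets, "fraction": sm.fraction})
                for cls, (raw, sm) in profiles.items()
            },
            outputs["fig_tss"],
        )

    manifest = {
        "tool": "pg4scape",
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "params": dataclasses.asdict(params),
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in paths.items()},
        "outputs": {k: str(p) for k, p in outputs.items()},
        "elapsed_s": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    outputs["manifest"] = outdir / "manifest.json"
    return outputs
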