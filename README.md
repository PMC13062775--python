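# pg4scape

Analysis of clustered putative G-quadruplex (pG4) motifs against replication
timing (RT), gene length classes, and transcription start sites (TSSs), with a
seeded synthetic-data generator so every result in this repository is
reproducible end to end without external data.

G-quadruplexes are four-stranded nucleic-acid structures that form in
G-rich sequence. Individual pG4 motifs are extremely common, so this package
focuses on *clusters* — runs of two or more same-strand motifs separated by at
most 100 bp — and asks three questions:

1. **Where do clusters sit in replication-timing space?** Six-phase Repli-seq
   signal is converted to a per-bin RT score
   (`S1·0.917 + S2·0.75 + S3·0.583 + S4·0.417 + S5·0.25 + S6·0` on per-bin
   normalized fractions), min–max scaled, blacklist-masked, and cut into five
   quintile classes (Early … Late). Cluster coverage per 50 kb bin is then
   summarized per class, with the Early/Late enrichment fold as the headline
   number.
2. **Are long / fragile genes depleted of clusters?** Genes are classified as
   CFS (common-fragile-site genes: >200 kb and overlapping a significantly
   delayed/under-replicated region), LONG_NON_CFS (>200 kb, no overlap), or
   SHORT (<200 kb); per-gene body coverage (optionally excluding the first
   2 kb downstream of the TSS) is compared across classes with a
   Kruskal–Wallis test on log2 coverage.
3. **How is cluster coverage distributed around TSSs?** Strand-oriented
   binary coverage over ±10 kb at bp resolution, averaged over genes per
   class and smoothed with a ~200 bp sliding window.

A display module prepares fourth-root-transformed, 21-bin-smoothed tracks and
highlights the earliest/latest 20% of the mappable genome; optional matplotlib
rendering draws a circular genome overview, per-class violin plots, and TSS
profile figures.

## Worked example

Everything runs from a YAML config. With a `simulate:` section the pipeline
first generates a fully synthetic genome (two 60 Mb chromosomes, six-phase
Repli-seq-like signal, pG4 motifs planted at a 10-fold early:late rate with a
3× TSS boost, 100 long + 250 short genes, 5% blacklist), then analyses it
exactly as it would analyse real files:

```bash
cat > demo.yaml <<'YAML'
simulate:
  seed: 7
params:
  flank: 10000
YAML
pg4scape run-all --config demo.yaml --out demo
```

`demo/class_coverage_summary.tsv` (real output of the commands above):

```text
rt_class   n_bins  mean_fraction   median_fraction  fold_early_late_mean  fold_early_late_median
Early      450     0.01270626667   0.01231          8.758378776           inf
Mid-early  450     0.01072755556   0.00962          8.758378776           inf
Mid        450     0.004033511111  0.00288          8.758378776           inf
Mid-late   450     0.001466933333  0                8.758378776           inf
Late       450     0.001450755556  0                8.758378776           inf
```

The mean-based Early/Late fold of **8.76** recovers the planted 10-fold
enrichment (the median fold is infinite because the median Late bin has zero
coverage — cluster coverage is sparse). `demo/class_test_tss_excluded.tsv`:

```text
H            p_value          df  n_CFS  median_CFS    n_LONG_NON_CFS  median_LONG_NON_CFS  n_SHORT  median_SHORT
133.7405716  9.090837026e-30  2   42     -9.044458354  58              -9.596678639         250      -6.563166187
```

Long genes (CFS and LONG_NON_CFS) are strongly depleted of cluster coverage
relative to short genes (P ≈ 9×10⁻³⁰). The smoothed TSS profile for SHORT
genes peaks at offset **+74 bp** from the TSS (fraction 0.117 of genes
covered), recovering the planted promoter-proximal enrichment.

Each stage is also its own subcommand, chained through files:

```bash
pg4scape simulate --seed 7 --out sim/
pg4scape clusters --motifs sim/pg4_motifs.bed --max-gap 100 --min-motifs 2 --out clu/
pg4scape rt-seg --phases sim/s1.bedgraph sim/s2.bedgraph sim/s3.bedgraph \
    sim/s4.bedgraph sim/s5.bedgraph sim/s6.bedgraph \
    --chrom-sizes sim/chrom.sizes --blacklist sim/blacklist.bed --out rt.tsv
pg4scape coverage --clusters clu/clusters_combined.bed --rt rt.tsv --out cov/
pg4scape gene-classes --genes sim/genes.bed --sdr sim/sdr.bed \
    --clusters clu/clusters_combined.bed --exclude-tss 2000 --out gc/
pg4scape tss-profile --genes sim/genes.bed --sdr sim/sdr.bed \
    --clusters clu/clusters_combined.bed --chrom-sizes sim/chrom.sizes --out tss.tsv
pg4scape tracks --coverage cov/bin_coverage.tsv --rt rt.tsv --out trk/
pg4scape render --out demo/      # figures from an existing run-all directory
```

The per-stage outputs are byte-identical to the corresponding `run-all`
tables (this is asserted in the test suite). Real data plugs in through an
`inputs:` section naming chrom.sizes, a motif BED6, six phase bedGraphs,
gene/SDR/blacklist BEDs.

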