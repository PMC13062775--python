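# Methods

This note records the statistical model, the conventions every module follows,
the synthetic generator's assumptions and parameter rationale, and the
resolution of the interface questions the implementation had to settle.

## Coordinate and data conventions

All intervals are 0-based, half-open `[start, end)` (BED convention); strands
are `+`, `-`, or `.` (unstranded). bedGraph phase signal is aggregated onto the
bin grid as a **length-weighted mean over covered bases only**: a bedGraph
record contributes to a bin in proportion to its overlap, and bases with no
record do not dilute the mean (a bin with no coverage at all is missing, NaN).
This keeps total signal mass conserved under bin-boundary splits, which the
test suite checks directly.

## Replication timing

Per bin, the six phase values (S1 earliest … S6 latest) are normalized to
fractions summing to 1 and combined as

```
RT = S1·0.917 + S2·0.75 + S3·0.583 + S4·0.417 + S5·0.25 + S6·0
```

so a bin whose signal is entirely in S1 scores exactly 0.917 and entirely in
S6 scores exactly 0. Normalize-then-weight makes the score invariant to
sequencing depth. Raw scores are min–max scaled **genome-wide** (not per
chromosome): RT class boundaries are a property of the whole genome's timing
distribution, and per-chromosome scaling would let a uniformly late chromosome
manufacture spurious "early" bins. Bins overlapping the blacklist (any
overlap by default; a minimum-overlap fraction is configurable) are masked
before classification.

Mappable scored bins are ranked by scaled RT descending, ties broken by
genomic order (a stable sort), and bin at rank *i* of *N* gets class
`⌊5·i/N⌋`. For N not divisible by 5 the earlier classes absorb the remainder
(N = 7 → sizes 2,1,2,1,1). The 20% display highlights use the identical
ranking with exact rational arithmetic, so "top/bottom 20%" coincides bin-for-
bin with the Early/Late quintiles (floating-point `0.2 × 15` would otherwise
select 4, not 3, bins).

## pG4 clusters

Motifs on the same strand chain into a cluster when the gap to the previous
motif (`next.start − prev.end`) is ≤ 100 bp; clusters need ≥ 2 motifs.
Because chaining is transitive along the genomic order, single-linkage
chaining equals the transitive closure of the pairwise-gap relation; the test
suite verifies this against an O(n²) merge oracle. The strand-combined track
is the **interval union** of plus and minus clusters (gap 0, i.e. abutting
intervals merge) with motif counts summed — coverage-type downstream analyses
should not double-count overlapping bases from the two strands.

## Coverage and gene classes

Per-bin coverage is exact covered bp from the disjoint combined-cluster
intervals; terminal short bins use their true length as the denominator. The
class summary reports the Early/Late fold on both mean and median fractions;
mean is the headline (medians of sparse coverage are frequently 0, making the
fold infinite).

Gene classes: CFS = length > 200 kb **and** any overlap with an SDR/SDW
(significantly delayed/under-replicated region); LONG_NON_CFS = > 200 kb, no
overlap; SHORT = < 200 kb, no overlap. Genes exactly at the threshold, or
short genes overlapping an SDR, fit no class definition and are excluded.
Body coverage optionally excludes the first 2 kb downstream of the TSS
(strand-aware: `[start, start+2000)` trimmed for `+` genes, `[end−2000, end)`
for `-`), separating promoter-proximal G4 biology from body depletion.
log2 coverage uses a 10⁻⁴ pseudocount so zero-coverage genes stay finite
(log2(10⁻⁴) ≈ −13.3). Classes are compared with the Kruskal–Wallis test
(scipy.stats.kruskal: tie-corrected H, χ² p at df = k−1) — coverage fractions
are zero-inflated and heavy-tailed, so a rank test, not ANOVA.

## TSS metaprofiles

For each gene, binary cluster coverage is sampled at offsets −10000…+10000
relative to the TSS, oriented in the transcription direction (offset +x for a
`-` gene is genomic position TSS − x). The class profile is the per-offset
**fraction of genes covered** (gene-averaged, so long genes do not dominate),
with off-chromosome positions excluded from the denominator. Smoothing is a
centered moving average; the nominal 200 bp window is widened to 201 offsets
so it stays centered, truncating at the profile edges (no padding, which
would bias the ends toward 0).

## Display tracks

Coverage fractions are transformed with the fourth root (order-preserving,
maps [0,1] to [0,1], spreads the heavy mass near zero) and then smoothed with
a 21-bin centered moving average that never crosses a chromosome boundary and
skips masked bins entirely (they contribute to neither numerator nor
denominator). Transform-then-smooth, in that order: smoothing first would let
a single covered bin leak through the concave transform into 20 neighbours at
inflated values. Nothing in this module feeds back into numeric results;
rendering functions return the plotted series as data frames so determinism is
testable without pixel comparison.

## Synthetic data generator

The generator is the package's ground-truth instrument; its defaults are the
study conditions and are not tuned to any particular analysis outcome.

**Genome and timing.** Two 60 Mb chromosomes, 50 kb bins. Each chromosome is
split into 30 domains by stratified jittered cuts (equally spaced cut points
jittered within the middle half of their stratum) — real RT domains have a
characteristic scale, and stratification keeps domain sizes, and hence gene-
packing capacity, stable across seeds. Domain timings are bimodal: 35% early
(timing within 0.08 of 1), 35% late (within 0.08 of 0), 30% uniform
transition — mirroring the compartmentalized timing of real genomes, where
most sequence is firmly early or late.

**Phase signal.** A bin with timing *t* emits signal in phase *p* proportional
to `exp(−c·(t − center_p)²)` with phase centers (11,9,7,5,3,1)/12 and
concentration c = 8, normalized with the softmax trick (subtract the row
minimum before exponentiation, so even c = 10⁶ is finite), then multiplied by
log-normal noise (σ = 0.1) and a depth of 100. At high concentration and zero
noise the resulting RT score reproduces the formula endpoints exactly, which
the tests assert.

**Motifs.** Cluster seeds are Poisson per bin with a log-linear rate in
timing: `rate(t) = late·(early/late)^t` per 50 kb, defaults early = 10,
late = 1, so the planted early:late density fold is exactly
`motif_rate_early / motif_rate_late` = 10. Each seed expands into
`cluster_size_min + Poisson(0.5)` motifs of 20–50 bp separated by 1–100 bp
gaps (within the cluster-merge threshold by construction). TSS enrichment
adds extra seeds from a Gaussian kernel centered on each TSS with
sd = tss_window/6 (≈ 333 bp for the 2 kb window): published G4 density peaks
sharply at promoters, and a sharply peaked kernel also makes the planted peak
statistically identifiable — a flat boost would leave the profile maximum
uniform over the window.

**Genes and blacklist.** 100 long genes (210–300 kb) are placed in late
domains and 250 short genes (5–150 kb) in early domains (late = timing
≤ 0.30, early = ≥ 0.70), left-packed with 2–10 kb random gaps into the
roomiest available slot; infeasible configurations fail with an actionable
error rather than silently dropping genes. 40% of long genes carry an SDR
covering their middle half — these are the planted CFS genes. The blacklist
(5% of the genome in 200 kb pieces) is rejection-sampled to avoid genes, so
masking never removes gene signal. All randomness flows from one
`numpy.random.default_rng(seed)`; identical seeds give byte-identical output
files.

**Known limitations.** No sequence realism (motifs are coordinates, not
G-rich sequence); no transcription; gene placement correlates length with
timing by design (that is the planted effect), so the generator cannot be
used to study length–timing confounding; domain boundaries are sharp rather
than graded.

## Numerical choices

- Moving averages use full-mode convolution sliced to the input length;
  numpy's `mode="same"` mis-aligns when the window exceeds the array (short
  chromosomes, narrow profiles).
- NaN-aware smoothing divides a NaN-zeroed numerator by the finite-count
  denominator; windows with no finite entry yield NaN rather than 0.
- Highlight fractions are converted to exact rationals before computing
  ceil/floor counts (see above).
- All TSV output uses `%.10g` float formatting, which round-trips the values
  used in tests and keeps reruns byte-comparable.

## Testing strategy

Every algorithmic module is tested against an independent oracle: O(n²)
transitive-closure merging for cluster detection, per-base boolean arrays for
all coverage/metaprofile computations, explicit windowed means for both
smoothers, and textbook values for the Kruskal–Wallis statistic. Generator
recovery tests (fold within ±25% of the planted 10, Kruskal–Wallis p < 10⁻⁴,
TSS peak within ±500 bp) run on seed batches disjoint from those used while
developing the generator. `tests/test_acceptance.py` holds the end-to-end
criteria; the remaining files test module behavior and edge cases.
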