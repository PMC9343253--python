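# Methods

This note documents the models, conventions and numerical choices behind
`tempomod`, the defaults that matter, and what the synthetic benchmark does
and does not establish.

## Dynamic-feature rules

Genes: significant (q ≤ 0.05) pairwise change with |log₂FC| ≥ 1.5 and
≥ 10 FPKM in at least one condition *of that comparison* (scope
configurable to "any condition overall" via `FilterSpec.level_scope`).
Peaks: q ≤ 0.01, |log₂FC| ≥ 1.5, ≥ 1 TMM-normalized reads. Fold changes are
taken as supplied (raw, not shrunken).

DMR handling consumes candidate regions from an upstream per-comparison
caller; per-CpG differential testing is deliberately out of scope. The
merge/filter layer: candidates overlapping by ≥ 1 bp collapse into one
region (book-ended regions sharing only an endpoint stay separate under
half-open coordinates); per-sample region methylation is the
coverage-weighted mean of CpG levels, i.e. Σ methylated / Σ total reads
over the region's CpGs; region *coverage* is the summed CpG read count
(the `regionCounts` convention — the alternative, per-CpG mean coverage,
is not used). Regions are kept when coverage strictly exceeds 5 reads in
≥ 3 samples ("more than five" is read as > 5). A region is differential
when the replicate-averaged methylation values span ≥ 0.3 (`delta`) *and*
the region is strictly larger than 100 bp. A second-pass proximity merge
joining regions closer than `dis_merge` = 400 bp is available but off by
default, since that distance is normally applied inside the upstream
caller.

## Module discovery

Transform: per-feature z-score of log₂(x + 1) with the sample standard
deviation (n − 1); constant rows map to all-zero. k-means is Lloyd's
algorithm with k-means++ initialization, best of `n_starts` = 100 random
starts, convergence tolerance 1e-6 on relative inertia, ≤ 300 iterations,
fully seeded.

Gap statistic: W_k is the pooled within-cluster sum of squares;
Gap(k) = (1/B) Σ_b log W*_kb − log W_k with B reference data sets drawn
uniformly over each variable's observed range (no PCA rotation);
s_k = sd_b(log W*_kb) · √(1 + 1/B) with the population (1/B) standard
deviation. Selection follows the "SE-max" rule: the smallest k with
Gap(k) ≥ Gap(k+1) − s_{k+1}; ties resolve toward smaller k; if no k on the
grid qualifies, the largest grid value is returned with the full curve
available for inspection. Degenerate input (all rows identical) returns
k = 1 with a warning.

The historical defaults are k = 2–20, B = 60, 100 starts. The test suite
and acceptance script run the same machinery on grids of k = 1–6 with 3–10
starts inside the gap loop — the package's problem-size choice for its
synthetic benchmarks, where at most three modules are planted; the
selection rule is identical at any grid size.

Manual collapsing of near-duplicate clusters is exposed as
`merge_modules_by_correlation` (iteratively merges centroid pairs with
Pearson r above a configurable threshold, default 0.95) rather than as an
undocumented by-hand step.

Pseudo-bulk construction for single-cell inputs downsamples each cell
cluster to ≤ 500 cells (seeded) before averaging, to avoid cluster-size
bias.

## Pattern assignment

Profiles are normalized per feature by the 95th quantile across cell
clusters (linear-interpolation quantile with plotting position
h = (n − 1)p, the convention of the surrounding software ecosystem) and
capped at 1; rows with zero 95th quantile map to all-zero. The default
prototype library contains one pattern per timepoint, every contiguous
union of ≥ 2 timepoints, one per cell class, and one per individual cell
cluster. Cosine similarity uses raw nonnegative vectors — no mean
centering, which would break the [0, 1] score range. Exact ties break
toward the pattern with fewest active clusters (the most specific
explanation), then lexicographically; all-zero module profiles are labelled
`other`. Temporal labels fold into shared-early / shared-late /
cell-type-specific categories via a configurable early/late timepoint
partition (defaults P1, P7 vs P21, P48).

## Specificity

τ = Σᵢ (1 − x̂ᵢ)/(n − 1) on raw nonnegative values (CAGE-tag-like); a
log1p option exists but is off by default. τ is undefined for all-zero
vectors and requires n ≥ 2. Union peak panels: per tissue, genomic
stretches supported by ≥ 2 replicate peak sets are kept (tissues with fewer
replicate sets contribute what they have, with a warning); the cross-tissue
union is size-standardized to 350 bp around each union peak's midpoint,
clipped at position 0 (width invariant relaxed there and flagged).
External specificity lookup matches each query region to the scored region
with maximal overlap length, ties to the leftmost.

## Sequence and context metrics

PWM p-values are exact: log₂-odds scores (pseudocount 1e-4 on
probabilities) are rounded to a 1e-3 granularity, the background
distribution of the total score is built by dynamic-programming convolution
over motif columns, and the threshold is the smallest score whose tail
probability does not exceed the requested p (default 10⁻⁴). Scanning
counts *all* positions on both strands meeting the threshold — overlapping
matches are not collapsed — and reports matches per kb. Note that under a
uniform background a motif of length L cannot reach a 10⁻⁴ tail unless
4⁻ᴸ ≤ 10⁻⁴, i.e. L ≥ 7; the built-in toy library uses 8-bp motifs.

Entropy is mononucleotide Shannon entropy in bits, N bases excluded from
both numerator and denominator. Promoter windows are strand-independent
TSS ± 1 kb. Nearest-TSS links use distance 0 for a TSS inside the region,
otherwise the gap to the nearer edge, and are dropped beyond 100 kb.
Conservation means exclude uncovered bases (no zero-fill) and flag regions
with > 50 % uncovered. Radar summaries min–max normalize each metric
across modules; a metric constant across modules maps to 0.5 and is
flagged.

## Integration and cross-species

Module-overlap enrichment is one-sided (overrepresentation, P(X ≥ k)) —
the reporting of enrichment odds ratios implies that direction. Odds
ratios use the sample estimate with a Haldane 0.5 correction on zero cells
and are capped at 10; pairs are reported at BH q < 0.001. Regions without
a gene link are excluded before testing.

MDS is classical (Torgerson): double-center −½D², eigendecompose, embed on
the top-2 positive eigenvalues, with D = 1 − |Pearson r|. The divergence
test is a two-sample one-sided Welch t-test on per-pair 2-D inter-cell-type
distances, late vs early timepoints — one reasonable construction of a
test the analysis design leaves open; it is documented as such.

Ortholog tables are reduced to one-to-one pairs; genes with multiple
partners on either side are dropped entirely and counted. Fisher module
similarity is one-sided (greater) over the union of all mappable and
clustered genes. Lifted regions are retained when mapped length ≥ 100 bp
and size ratio < 1.2 (strict). Overlap percentages are directional
(A-regions against B-regions); both directions can be emitted by swapping
arguments.

## The synthetic generator

Every pipeline input is generated with planted ground truth, fully
determined by a master seed; each generator draws from its own stream
(seed + CRC32 of a stable label), so adding one generator never perturbs
another.

- **Signals.** Planted features follow effect × prototype + N(0, noise_sd)
  on log₂ scale over conditions; abundances are 2^signal − 1, so the
  clustering transform recovers the prototype shape. Methylation is
  logit-normal, anti-correlated with activity, keeping values in (0, 1).
  Defaults encode the benchmark conditions: 2 cell types × 4 timepoints,
  three planted modules (shared-early, shared-late, cell-type-specific) of
  80 features each, effect 2, noise 0.2.
- **Differential stats.** n = 2 replicates per condition around the log
  signal; the per-comparison test pools the replicate variance across all
  features (a moderated z-test). A per-feature Welch t-test with n = 2 has
  roughly coin-flip power even at effect 2, which would violate the
  generator's contract that planted features pass the thresholds in
  expectation; the pooled test mirrors the variance-sharing that real
  differential callers perform. q-values are BH per modality and
  comparison.
- **Annotation.** Regions sit on an even grid of one synthetic chromosome,
  paired index-wise with genes; the paired TSS falls in the ± 1 kb promoter
  window with the module's promoter fraction, otherwise 2–50 kb away (still
  linkable within 100 kb, preserving planted region–gene concordance).
  CGIs, per-module GC/CpG sequence composition, and a tiled conservation
  track (10-bp tiles, N(module mean, 0.1)) follow per-module parameters.
- **Panels.** A gene with planted τ gets one maximal tissue at M and the
  rest at M(1 − τ) with multiplicative noise scaled by 4τ(1 − τ) — zero at
  both extremes, so τ = 1 gives a single nonzero tissue and τ = 0 a
  constant profile, and intermediate τ is recovered to ±0.05 at n = 500.
  Binary open-chromatin panels use per-module presence probabilities;
  replicate peak sets jitter the open regions by ≤ 20 bp with 10 % dropout.
- **Homology.** Orthologs are retained i.i.d. at `homolog_retention`
  (default 0.8); region mappings fall into configured classes — expansion
  failures (ratio ≥ 1.2, default 20 %), size failures (< 100 bp, default
  5 %), and clean mappings (ratio 0.85–1.15).

What the generator does *not* emulate: read-level noise, peak-calling
artifacts, correlated replicate structure, realistic genome organization
(repeats, gene clusters, chromatin domains), species-specific sequence
composition, or dependence between modalities beyond the planted module
concordance. Passing benchmarks therefore demonstrate that the pipeline's
logic recovers the structure it is designed to find at realistic effect
sizes and noise — not that any particular biological dataset will behave
as cleanly.

## Problem sizes used by tests and the acceptance script

Full-pipeline runs use 600 genes/regions with three 80-feature modules;
gap-statistic recovery uses 300 features in 3 clusters at 10 σ separation,
B = 60, over 20 seeds; pattern recovery uses 1,000 noisy prototype draws
per noise level; τ recovery uses 500 genes over 30 tissues; the early/late
characterization contrast uses 200 regions per module with one-sided
Mann–Whitney tests per metric. These sizes were chosen so the whole
benchmark completes in well under a minute per stage on a single core
while leaving each statistical check comfortably powered.

## Known limitations

- The DSS-style posterior-probability semantics of the upstream DMR caller
  are approximated by the observed-difference rule on merged regions.
- The divergence t-test construction (which sample pairs enter) is an
  interpretation; alternatives (paired designs, permutation tests) are not
  implemented.
- PWM thresholds are per-motif under a single background; no GC-matched or
  local backgrounds.
- The gap statistic's reference draws are uniform per variable; elongated
  or correlated null structures may prefer the PCA-rotated variant, which
  is not implemented.
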