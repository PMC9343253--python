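# tempomod

Temporal multi-omic regulatory module discovery and characterization for
developing cortical neurons.

## The problem

During postnatal cortical development, projection-neuron classes (CPN,
CThPN, SCPN) switch from class-specific regulatory programs to broadly
shared maturation programs. Dissecting this requires finding *modules* of
genes, accessible-chromatin peaks and differentially methylated regions
(DMRs) that share temporal/cell-type activity profiles, and then asking what
distinguishes, say, a shared-early module from a shared-late one: tissue
specificity, promoter/CpG-island context, transcription-factor motif
density, sequence entropy, evolutionary conservation, cross-modality
concordance and cross-species retention.

`tempomod` implements that analysis as a tested, reusable pipeline for
anyone working with pseudo-bulk multi-omic developmental time courses. A
first-class synthetic-data generator plants known module structure in every
input the pipeline consumes, so the whole chain is verifiable without any
external download.

## Methods at the core

- **Dynamic features.** A gene is dynamic when some pairwise comparison has
  q ≤ 0.05 and |log₂FC| ≥ 1.5 with ≥ 10 FPKM in a condition of that
  comparison (peaks: q ≤ 0.01, ≥ 1 TMM). Candidate DMRs are merged on ≥ 1 bp
  overlap, quantified as coverage-weighted CpG methylation, kept when
  covered by > 5 reads in ≥ 3 samples, and flagged differential when the
  replicate-averaged methylation spans ≥ 0.3 and the region exceeds 100 bp.
- **Module discovery.** Row z-scores of log₂(x+1), k-means with 100 random
  starts, and the gap statistic
  Gap(k) = (1/B) Σ_b log W*_kb − log W_k with the Tibshirani SE rule
  (smallest k with Gap(k) ≥ Gap(k+1) − s_{k+1}, B = 60 reference draws
  uniform over each variable's range).
- **Pattern labels.** A binary prototype indicator matrix (cell clusters ×
  patterns: timepoints, contiguous timepoint unions, cell classes, single
  clusters) is compared by cosine similarity against each module's average
  95th-quantile-normalized profile; the argmax pattern labels the module,
  and temporal labels fold into shared-early / shared-late /
  cell-type-specific categories.
- **Specificity.** τ = Σᵢ (1 − x̂ᵢ) / (n − 1), x̂ᵢ = xᵢ / max(x), over an
  n-tissue panel; region specificity via size-standardized (350 bp) union
  peak panels with per-tissue overlap fractions.
- **Sequence & context metrics.** PWM scanning with exact
  dynamic-programming p-value thresholds (p < 10⁻⁴) on both strands;
  mononucleotide Shannon entropy; mean per-base conservation; promoter
  (TSS ± 1 kb) and CpG-island overlap; min–max normalized radar summaries.
- **Integration & cross-species.** Nearest-TSS linking within 100 kb;
  one-sided hypergeometric region-module × gene-module enrichment with BH
  correction, reported at q < 0.001 with odds ratios capped at 10;
  classical MDS on 1 − |r| with a one-sided divergence test; ortholog-mapped
  Fisher module similarity and liftover-filtered (≥ 100 bp, ratio < 1.2)
  region overlap percentages.

## Worked example

```python
import tempomod as tm

cfg = tm.SynthConfig(
    n_genes=150, n_regions=150,
    planted_modules=[("early", 30, 2.0), ("late", 30, 2.0), ("CPN", 30, 2.0)],
    genome_length=600_000, seed=7,
)
study = tm.generate_all(cfg)
result = tm.run_synthetic_study(study, seed=1)
print("dynamic genes:", len(result["genes"].dynamic_ids))
print("chosen k:", result["genes"].gap.chosen_k)
print("ARI vs planted truth:", result["gene_ari"])
print(result["gene_patterns"].table)
```

```
dynamic genes: 90
chosen k: 3
ARI vs planted truth: 1.0
        pattern    cosine
module
0       P21_P48  0.969582
1         P1_P7  0.970148
2           CPN  0.971922
```

All 90 planted features pass the dynamic-feature thresholds, the gap
statistic selects the planted k = 3, k-means recovers the planted
memberships exactly (adjusted Rand index 1.0), and cosine matching labels
the three modules with their planted patterns: shared-late (P21_P48),
shared-early (P1_P7) and CPN-specific.

A command-line layer mirrors the stages:

```bash
tempomod simulate --out sim/ --seed 3
tempomod select-dynamic --modality rna --stats sim/diff_stats.tsv \
    --matrix sim/expression.tsv --conditions sim/conditions.tsv --out dynamic.txt
tempomod cluster --matrix sim/expression.tsv --conditions sim/conditions.tsv \
    --kmin 1 --kmax 6 --out modules
```

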