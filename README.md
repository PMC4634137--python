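# hcregulon

Cell-type-specific transcriptome → transcription-factor inference for
sorted inner-ear cell populations.

## The problem

Auditory and vestibular hair cells (HCs) are rare mechanosensory cells
whose maturation is driven by transcriptional programs that are hard to
see in whole-tissue expression data. Given expression matrices from sorted
cell populations (HCs, epithelial non-hair cells ENHC, non-epithelial
cells NEC, from two organs with replicates), this package answers a
reverse-engineering question: *which transcription factor drives the
HC-enriched transcriptome?* It does so by finding genes whose expression
is confined to or elevated in HCs and then asking which promoter motif is
over-represented in those genes — in practice an RFX-like X-box — and by
validating the inferred regulon against ChIP-derived target lists, a
second species via ortholog mapping, and a rank-based expression-shift
test. It is aimed at genomicists analysing sorted-population or
cell-type-resolved expression data with matching promoter sequence.

## Core statistics

- **Differential expression.** Per gene, a fixed-effects two-way ANOVA
  with interaction on log2(x+1) values over the organ × cell-type design;
  Benjamini–Hochberg FDR per effect; a gene is selected when any effect's
  q < 0.05.
- **Strict marker rule.** Gene g marks cell type c iff mean expression
  over the c samples > 250 (a.u.) and *every* individual non-c sample
  < 120 — favouring specificity over sensitivity.
- **Motif over-representation.** Promoters (−1000..+500 nt around the
  TSS, strand-aware) are scanned with a PWM at a log-odds threshold
  θ·S_max (θ = 0.8, both strands). With N background genes of which K
  carry ≥1 hit, and k of n target genes carrying a hit,

      p = P(X ≥ k),  X ~ Hypergeometric(N, K, n),
      EF = (k/n) / (K/N)        (enrichment factor)

  The hit-position histogram peaks sharply at the TSS, so the test is
  re-run on a narrowed −200..+100 window where it is more significant.
- **Regulon validation.** Per-gene HC-enrichment ratio
  r = mean_HC / mean(mean_HC, mean_ENHC, mean_NEC); a one-sided Wilcoxon
  rank-sum test asks whether log2 r of the inferred targets is shifted
  right of all other genes. ChIP target lists are intersected with the
  candidates under the same hypergeometric test, and the analysis is
  repeated in a second species through a one-to-one ortholog map.

Because the original deposited data are not bundled, a first-class
synthetic-data module generates ground-truthed inputs with the same
statistical structure (planted regulon, planted promoter motif instances
concentrated near the TSS, ChIP lists overlapping the regulon, partially
conserved second species), so every stage is testable offline.

## Worked example

```python
from hcregulon import PipelineConfig, simulate, run_pipeline

cfg = PipelineConfig(out_dir="demo_out", seed=1)
cfg, truth = simulate(cfg)          # writes FASTA/BED/TSV/MEME inputs
report = run_pipeline(cfg)

print(report["n_markers"])                       # {'ENHC': 50, 'HC': 50, 'NEC': 50}
print(report["n_hc_enriched"])                   # 143
print(report["motif_enrichment_full"]["enrichment_factor"])   # 2.844227356
print(report["motif_enrichment_full"]["p"])      # 1.26557823e-20
print(report["top_kmer"])                        # ATGGCAAC
print(report["shift_test"]["p"])                 # 6.460187945e-50
```

At seed 1 the pipeline recovers all 150 planted cell-type markers; 143
genes pass the ≥3-fold HC/ENHC rule (quantile normalization compresses the
planted 4-fold effect, so only the stronger regulon genes clear it); their
promoters carry the planted X-box-like motif at 2.8× the background rate
(hypergeometric p ≈ 1e-20, far more significant in the narrowed TSS
window), de-novo k-mer discovery returns the planted consensus core
`ATGGCAAC/GTTGCCAT`, and the ChIP-defined targets' HC-enrichment ratios
are strongly right-shifted (Wilcoxon p ≈ 6e-50).

The same analysis is scriptable from the shell:

```
hcregulon simulate --seed 1 --out demo_out
hcregulon run --seed 1 --out demo_out
hcregulon report --out demo_out
```

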