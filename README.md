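# charflow

Integrative ATAC-seq + RNA-seq analysis of chromatin accessible regions
(ChARs), built around the question of how chronic antigen exposure remodels
the chromatin of brain-infiltrating CD8+ T cells. The package reimplements,
as a tested pipeline over synthetic data with planted ground truth, the
computational stages used to compare T cells from an autoimmune CNS setting
(groups A_E/A_L, early day 7 / late day 21) against acutely resolved viral
infection (V_E/V_L):

- **Region algebra** — Tn5 insertion-shift correction (+4 bp forward / −5 bp
  reverse reads), pooling of per-sample peak calls, and consensus merging:
  two regions overlapping by ≥ 50% of the width of the larger are replaced by
  their *intersection*; lesser overlaps are kept unchanged. Strict
  promoter > exon > intron > intergenic annotation (≥ 1 bp overlap; promoter =
  −2000/+1000 bp around the merged gene model's TSS) and nearest-gene
  assignment capped at 50 kb.
- **Library QC** — ENCODE complexity ratios NRF = distinct/total insertion
  positions, PBC1 = one-read/distinct, PBC2 = one-read/two-read positions,
  and FRiP.
- **Differential accessibility / expression** — TMM normalization factors and
  a conditional exact negative-binomial test on library-equalized group sums:
  with common dispersion φ and n_g replicates per group, P(S_A = a | S_A + S_B = t)
  is Dirichlet-multinomial with weights r_g = n_g/φ, reducing to an exact
  binomial split test at φ = 0. Benjamini–Hochberg FDR; calls at
  |log₂FC| ≥ 1, q < 0.05 (ATAC) and FC ≥ 1.5, q < 0.05 with a 1-RPKM
  expression filter (RNA).
- **Accessibility modules** — per-ChAR coverage in centre ± 500 bp windows,
  library-normalized, scaled 0–1 across replicates, hierarchically clustered
  and cut into k = 5 modules (silhouette summary over k = 2..20 emitted).
- **Motif enrichment** — HOMER-style: matched background of non-differential
  ChARs (|log₂FC| < 1, p > 0.05) at least 2000 bp from any clustered ChAR;
  log-odds PWM scanning of both strands; hypergeometric upper-tail p per
  module, reported at p < 10⁻³.
- **Preranked GSEA** — weighted Kolmogorov–Smirnov running sum
  (hits add |s|ᵖ/Σ|s|ᵖ, misses subtract 1/(N−|S|)), gene-label permutation
  null, NES = ES / mean |same-sign permuted ES|.
- **ChAR–gene integration** — diamond-plot table (top-50 up/down DEGs with a
  differential ChAR within 15 kb), TCF-1-bound gene flags (binding site
  within 10 kb of the gene span), and per-module 0–1-scaled expression
  summaries.

The synthetic-data module (`charflow.synthetic`) generates the whole input
bundle — genome FASTA, GTF, per-sample narrowPeak and fragment BED files, RNA
counts, MEME motifs, TCF-1 sites, reference peaksets, gene sets — with known
planted effects, so every stage can be scored against ground truth.

## Worked example

```bash
python analysis/01_simulate.py --seed 0        # writes results/fixture/
python analysis/02_run_pipeline.py             # writes results/pipeline/
python analysis/03_evaluate_recovery.py        # scores against ground truth
```

The second step prints, for the default bundle (2 chromosomes × 1 Mb,
300 genes, 400 peaks of which 40 carry planted |log₂FC| = 2 effects):

```
completed stages: qc, merge, diff, cluster, motif, gsea, integrate
consensus ChARs: 395
  A_E_vs_V_E: 22 differential ChARs (|log2FC|>=1, q<0.05)
  A_L_vs_V_L: 29 differential ChARs (|log2FC|>=1, q<0.05)
  V_L_vs_V_E: 0 differential ChARs (|log2FC|>=1, q<0.05)
  A_L_vs_A_E: 19 differential ChARs (|log2FC|>=1, q<0.05)
DEGs A_L vs V_L: 23 up, 23 down
                    set        ES       NES  p_value  n_genes
planted_down_A_L_vs_V_L -1.000000 -2.590537 0.002079       22
  planted_up_A_L_vs_V_L  0.992537  2.536046 0.001923       23
         random_control -0.211828 -0.581651 0.987097       30
```

Reading this: pooling the 8 samples' peak calls yields 395 consensus ChARs;
most planted chromatin remodeling is detected in the autoimmune-vs-viral
comparisons and none in the viral early-vs-late comparison (where nothing was
planted). The planted up/down gene signatures score |NES| ≈ 2.5 with
permutation p ≈ 0.002, while a random control set does not. The third step
then reports recovery of the planted truth — e.g. 97.5% of the 40 planted
differential peaks recalled at q < 0.05, all 30 planted ChAR–gene pairs
assigned to the right gene, module recovery ARI 0.80, planted motif
enrichment p < 10⁻⁶ with all 10 decoy motifs non-significant.

The same pipeline runs on any compliant input bundle via the CLI:

```bash
charflow simulate --seed 0 --out bundle/
charflow run-all --config bundle/run_config.yaml --out run/
```

## Layout

- `src/charflow/` — the library: `genome_annotation`, `region_algebra`,
  `atac_quant`, `differential`, `chromatin_clustering`, `motif_enrichment`,
  `rna_integration`, `synthetic`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and end-to-end round-trip tests.
- `docs/methods.md` — model assumptions, parameter choices, limitations.
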