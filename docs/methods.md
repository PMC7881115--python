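# Methods

## Coordinates and region arithmetic

All intervals are 0-based half-open. GTF input (1-based inclusive) is
converted on read; BED/narrowPeak are used as-is. The unique gene model
merges all exons of all protein-coding isoforms of a gene into disjoint
intervals; the TSS is the span start on the + strand and the span end on the
− strand. Promoter windows are −2000/+1000 bp around the TSS, oriented by
strand by default (a strand-agnostic mode exists because strandedness of the
window is a genuine ambiguity); windows are clipped at position 0 and, when
chromosome lengths are supplied, at the chromosome end. Genes with no
protein-coding transcript are excluded from the gene model.

Consensus ChARs are built by pooling all samples' peak calls, deduplicating,
coordinate-sorting, and sweeping left to right: the running region and the
next peak are replaced by their **intersection** when their overlap is at
least 50% of the width of the larger one; otherwise the running region is
emitted. The sweep is iterated to a fixpoint, which makes the result
deterministic and insensitive to input order. Intersection (rather than the
more common union) is the deliberate default because it is what the merging
rule describes; a `union` mode is available. The rule is defined pairwise
only, so fixpoint sweeping is our documented resolution of overlap chains.
One global consensus set is built across all samples (not per comparison) so
that ChAR identifiers are shared by every comparison — the module-selection
step ("differential in at least one comparison") requires a common region
universe.

Annotation priority is strict: promoter, then exon, then intron (overlap with
the gene span but neither exon nor promoter), then intergenic, each decided
by ≥ 1 bp overlap. Nearest-gene assignment measures the edge-to-edge gap to
the gene span (0 on overlap) with a 50 kb cap; ties break lexicographically
by gene id. TCF-1-bound genes are those with a binding site within 10 kb of
the gene span (the window anchor — span vs TSS — is unstated upstream; span
is used).

## Library QC

Insertion positions are the strand-aware 5′ read coordinates. NRF =
distinct/total, PBC1 = single-read positions/distinct, PBC2 = single-read /
two-read positions (+∞ with a warning when no position is seen exactly
twice), FRiP = reads overlapping any peak / total. The "one read / two
reads" phrasing is read as counts of positions with exactly one vs exactly
two reads (the ENCODE convention).

## Counting and normalization

A fragment increments every region it overlaps by ≥ 1 bp (`multi_overlap =
"all"`), since intersection-merged ChAR sets may sit close together;
a `none` mode discards multi-region fragments. Library sizes are total
fragments, so off-region fragments count toward normalization. CPM =
count/library × 10⁶; logCPM = log₂(CPM + 0.5); RPKM divides CPM by feature
length in kb, with gene length = total merged-exon length. Sample distances
are root-mean-square differences of logCPM over the 500 most variable
regions; the 2-D embedding is classical (Torgerson) metric MDS via
eigendecomposition, which is deterministic (coordinates defined up to
rotation/reflection; distances exact).

## Differential testing

TMM factors: M/A values against the sample whose upper-quartile CPM is
closest to the mean; 30% trim on M, 5% on A; precision-weighted mean of the
surviving M values; factors rescaled to unit geometric mean.

The two-group test is a conditional exact NB test. Counts are scaled to a
common effective library (library size × TMM factor) and rounded — a
pragmatic stand-in for edgeR's quantile adjustment. For common dispersion φ
the group sums are NB with size n_g/φ, and conditionally on the total the
group-A sum is Dirichlet-multinomial; the two-sided p sums all split
probabilities not exceeding the observed one. φ = 0 reduces to an exact
binomial split test. Common dispersion maximizes the conditional
log-likelihood over features; a tagwise mode shrinks per-feature estimates
toward the common value with a fixed prior weight (10 feature-equivalents).
log₂FC uses normalized group-mean CPM with a 0.5 prior. Exact parity with
edgeR is not claimed; the implementation is validated by calibration instead:
on seeded null simulations (2000 features; 2 vs 2 and 3 vs 3; dispersions
0.05 and 0.2) the empirical type-I error sits within two binomial standard
deviations of nominal at α ∈ {0.01, 0.05}, and planted |log₂FC| = 2 effects
on 10% of features (means ≥ 50, dispersions 0.05/0.1) are recovered with
sensitivity ≥ 0.8 at observed FDR ≤ 0.1. At dispersion 0.2 with two
replicates per group this effect size is intrinsically underpowered for any
exact conditional test (sensitivity ≈ 0.4); that regime is asserted for
calibration only. A Fisher-exact mode on pooled group counts is included for
comparison; it ignores within-group dispersion and is not the default.

BH adjustment is delegated to statsmodels and cross-checked against a
brute-force step-up oracle. Calls: ATAC |log₂FC| ≥ 1, RNA |log₂FC| ≥
log₂ 1.5, both at q < 0.05; RNA genes additionally require ≥ 1 RPKM in at
least one sample (the across-sample rule for the filter is our choice).

## Accessibility modules

ChARs differential in at least one of the two group comparisons (|log₂FC| ≥ 1,
q < 0.05) are extended ±500 bp around their centres; mean per-bp coverage per
replicate is normalized by library size (×10⁶) and each row scaled to [0, 1]
(constant rows become zeros and are flagged). Rows are clustered on Euclidean
distances after canonical (lexicographic) row ordering, making the dendrogram
row-order invariant; the tree is cut into exactly k flat modules, labelled by
descending size. k defaults to 5 with a silhouette summary over k = 2..20 to
support the choice (the original choice was made visually and is not
automatable). `hierarchical_modules` defaults to complete linkage (the
classic `hclust` default); the *pipeline* default is Ward, because with two
replicates per group and biological-scale dispersion, complete linkage
merges planted behaviour classes that differ in a single group (measured ARI
0.45–0.72 vs ≥ 0.86 for Ward on identical matrices). Either can be selected
via `clustering_linkage`.

Reference-peakset profiles are per-peak z-scores (ddof = 1) of
library-normalized counts across samples; constant rows are zeroed and
flagged.

## Motif enrichment

Background: ChARs with |log₂FC| < 1 and p > 0.05 **in every clustering
comparison**, at least 2000 bp (edge distance) from every clustered ChAR,
taken as centre ± 500 bp windows. ("abs(FC) < 1" is read on the log₂ scale,
consistent with the surrounding thresholds.) PWMs come from MEME minimal
files; scoring is log-odds against the file's background frequencies with
probabilities floored at 10⁻⁴; N bases contribute 0. The default hit
threshold is 80% of each PWM's maximum achievable score (motif-specific
thresholds are not published); both strands are scanned. Enrichment of
hit-bearing sequences in a module vs background is the hypergeometric upper
tail; reporting keeps p < 10⁻³.

## Preranked GSEA

Genes are ranked by signed log₂FC (the ranking metric is not pinned down
upstream; a q-based alternative exists for DEG ranking). The running sum adds
|score|ᵖ/Σ_set|score|ᵖ at members (p = 1) and subtracts 1/(N−|S|) at
non-members; ES is the extreme deviation. The null permutes gene labels
(standard for preranked input): NES = ES / mean |same-sign permuted ES|, p =
(1 + #{|permuted| ≥ |ES|}) / (#same-sign + 1), bounded below by
1/(n_perm + 1). A set covering the whole list, or disjoint from it, is an
error. Signature construction supports "top n upregulated among significant"
(n = 150 effector-style) and "all with log₂FC ≥ 1, q < 0.05"
(exhaustion-style) rules.

## ChAR–gene integration

Diamond table: within each direction, DEGs are ranked by |log₂FC| (q-ranking
optional) and the top 50 per direction with at least one differential ChAR
(p < 0.05) within 15 kb of the gene span are kept, one row per qualifying
pair, carrying the ChAR's accessibility log₂FC and the gene's expression
log₂FC. Module expression summaries scale each gene's per-condition
expression to 0–1, deduplicate genes hit by several ChARs of one module, and
annotate TCF-1-bound membership. The gene-assignment cap defaults to 50 kb;
a 100 kb override exists because both values appear in upstream descriptions
of this analysis.

## Synthetic data

The generator emulates the study design: 4 groups (V_E, A_E, V_L, A_L) × 2
ATAC replicates and × 3 RNA replicates; 2 chromosomes × 1 Mb, 300
protein-coding genes in regular slots (plus a few non-coding transcripts),
400 peaks. 10% of peaks are differential with |log₂FC| = 2, cycling through
five behaviour classes (early opening, late closing, late opening, closed in
autoimmunity at both time points, early closing); each differential peak sits
inside a host gene and, with probability 0.9, the host gene is planted as a
concordant DEG. Counts are negative-binomial with dispersion 0.1 (per-sample
library scale factors drawn from 0.8–1.2); fragments are placed uniformly in
peak ± 100 bp with 50–120 bp lengths, plus 15% uniform background fragments
so FRiP has a denominator. Base peak means of 100–250 keep effective
consensus-region counts in the ≥ 50 regime the power statements assume. A
10-bp consensus motif is written into 60% of autoimmune-opening peak windows
and 5% of stable-peak windows (10 bp keeps the per-window chance-hit
probability ~2 × 10⁻³, far below the planted rates; an 8-mer would have
chance hits comparable to the background planting rate). TCF-1 sites are
seeded inside 30% of gene spans; the bound-gene truth is recomputed from the
emitted sites with the 10 kb rule, so neighbouring genes within the window
are included. Reference peaksets mimic published exhaustion/effector region
lists: ~90% opening (resp. closing) peaks plus stable fillers, with ±40 bp
jitter to mimic external coordinates.

What the generator does **not** model: Tn5 sequence bias,
fragment-length periodicity, GC-dependent coverage, realistic gene length and
expression distributions, correlated replicates, or multi-peak regulatory
architecture. Passing round-trip tests therefore demonstrates the internal
consistency of the pipeline's inference at realistic noise levels, not
performance on real sequencing data.

Determinism: every draw comes from one seeded generator and all writers use
fixed orderings/formats, so a spec + seed yields a byte-identical bundle, and
a pipeline run at a fixed seed yields byte-identical tables.

## Problem sizes

Defaults are deliberately desk-scale: bundle generation < 2 s, the full
pipeline ≈ 25 s on one CPU, the complete test suite a few minutes. Null
calibration uses 2000 features; GSEA uniformity checks use 200 random sets ×
250 permutations; the merge oracle covers 1000 random peak sets.

## Known limitations

- The NB exact test approximates edgeR (no quantile adjustment, no
  empirical-Bayes trend); agreement is statistical (calibration/power), not
  numerical.
- Intersection merging can shrink consensus regions below biologically
  meaningful sizes when many jittered replicates pool; the union mode avoids
  this at the cost of fidelity to the stated rule.
- Motif hit calling with a single fractional-of-max threshold is cruder than
  curated per-motif thresholds; enrichment p-values are conditional on that
  choice.
- k for module cutting is a parameter, not an inference.
- With two replicates per group, module recovery depends on the linkage
  choice (see above); ARI against planted classes is typically 0.7–1.0
  across seeds at the default noise level.
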