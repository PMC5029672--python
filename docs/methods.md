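# Methods

`lncscape` re-implements, as one tested pipeline, an integrated lncRNA
analysis for a three-group tumor RNA-seq design: matched normal colon (NC),
primary tumor (PC) and liver-metastasis (MC) tissue. Because the analysis
chains seven heterogeneous stages, every stage is exercised end-to-end on
synthetic data whose structure is planted and therefore scoreable. This
note documents the models, the defaults and why they were chosen, what the
generator does and does not emulate, and the numerical conventions.

## Coordinate and distance conventions

All coordinates are 0-based, half-open `[start, end)`; GTF (1-based,
end-inclusive) is converted on I/O, BED is native. The TSS is the 5'-most
transcribed base: `start` on the plus strand, `end - 1` on the minus strand.
Distance from a position to a gene is 0 inside the gene and otherwise the
gap to the nearest boundary (`start - pos` to the left, `pos - end` to the
right, with the half-open `end` as the boundary coordinate). Distances are
strand-blind; genes on different chromosomes are never neighbors.
Nearest-gene ties break on smaller start, then lexicographic gene id, so
queries are deterministic. The cis scan measures the boundary gap between
the lncRNA locus and candidate mRNAs by default; TSS-based distance is a
flag. All interval queries are checked against exhaustive all-gene scans in
the test suite.

## Synthetic data generator

The generator emulates the targeted study design: 3 matched groups ×
`n_per_group` samples (default 18, i.e. 54 samples), ~2,000 single-exon
genes (70% coding, 30% lncRNA) on two chromosomes.

* **Counts.** Gene counts are negative binomial with a common dispersion
  (default 0.1, a typical bulk RNA-seq value) via a gamma–Poisson mixture;
  variance = mu + dispersion·mu². Base means are log-normal (median ≈ 110
  counts for mRNAs, floored at 8 so every gene is testable); lncRNA means
  are scaled by `lnc_expression_scale` (default 0.25) so lncRNAs are
  systematically lower-expressed, as in real tissue. Library-size factors
  are log-uniform in [0.7, 1.3] to exercise normalization.
* **Planted DE.** A fraction `frac_de` (default 0.1) of genes get a
  2^`de_log2fc` multiplier (default log2FC = 2) in either PC or MC, so each
  planted gene is differential in exactly two of the three pairwise
  comparisons. Truth is derived from the *exact* group means (any gene whose
  true |log2FC| ≥ 1 is recorded, with its value), so plantings that interact
  — e.g. module latent factors that shift group means by ~1.1 log2 units —
  are honestly part of the truth rather than hidden.
* **Cis pairs.** Each planted pair is laid out as an isolated block
  (partner mRNA, 500 bp gap, lncRNA) with ≥ 5 kb clearance, making the
  partner the provable nearest coding gene; both members share the same DE
  planting so the pair is co-regulated by construction.
* **Modules.** Members of a planted module share a unit-variance latent
  factor; each member's log2-scale loading is set from its own NB noise
  variance so every member pair correlates at `intra_correlation`
  (default 0.8) regardless of expression level. For trait-linked modules
  the factor mixes a standardized group contrast at 35% of its variance —
  strong enough for clear eigengene–trait correlation (r ≈ 0.5–0.6 at
  n = 54), weak enough that differently trait-linked modules stay
  near-orthogonal in an unsigned network.
* **ChIP windows.** The genome is tiled into 200-bp windows with
  Poisson(10) background. Windows within 1 kb of any gene TSS get a 4-fold
  elevated baseline in both conditions (so the TSS aggregate profile is
  promoter-enriched). For `n_chip_links` lncRNAs that are strongly DE in
  PC-NC (true |log2FC| at least midway between the call threshold and the
  planted effect, so links are recoverable), the TSS windows instead carry
  `chip_fold` (default 8, above the caller's strict >4 cut) in the
  concordant condition: tumor for up-regulated lncRNAs, normal for
  down-regulated.
* **Signature block.** `n_signature_genes` mRNAs and `n_correlated_lnc`
  lncRNAs share a latent factor with loadings set for pairwise correlation
  `target_r` (default 0.8), planted among otherwise-uncorrelated lncRNAs.
* **SNPs.** `n_snp_near` SNPs are placed within 10 kb of lncRNA loci (30%
  inside the locus) and `n_snp_far` in a gene-free desert beyond the last
  gene + 10 kb; placement is verified at generation time. The default 9/74
  panel mirrors an 83-SNP GWAS panel with a ~10.8% near fraction.

What the generator does **not** emulate: multi-exon gene models and
isoform structure, within-patient correlation across the three matched
tissues (off by default; `patient_effect_sd` adds a shared per-patient
log-normal effect), gene-length biases in counting, batch effects, and
read-level artifacts (the pipeline consumes count matrices by design).
Passing tests therefore demonstrate that the *procedures* recover known
structure under a faithful noise model, not that any biological claim about
real tissue is reproduced.

All stages draw from per-stage `numpy` `SeedSequence` streams derived from
one seed; identical configuration gives byte-identical outputs.

## Expression quantification

RPKM = count · 10⁹ / (exon-model length · library size), with library size
the column total of the supplied count matrix (the true mapped-read total is
unavailable downstream of counting; a sidecar vector can override it).
Expression tiers follow the two conventional cutoffs: detectable at
RPKM ≥ 0.3 (inclusive) and active at RPKM > 1 (strict), each in ≥ 1 sample.
Log transforms use a pseudocount of 0.01 RPKM. The lncRNA-vs-mRNA level
contrast is a Wilcoxon rank-sum test on per-gene mean log10 RPKM, normal
approximation with continuity and tie correction (an exact mode exists and
is checked against rank enumeration in the tests). Sample PCA runs on
gene-centered log expression via SVD, with component signs fixed
deterministically.

## Consensus differential expression

The calling rule intersects two independent procedures, keeping the
two-tool-overlap design of the original analysis while replacing the
external tools with internal tests (their exact numerics are a non-goal;
one is cross-checked against pyDESeq2 in the test suite):

1. **NB Wald test.** Median-of-ratios size factors (geometric-mean-1
   rescaled); per-gene method-of-moments dispersion pooled over the two
   groups, shrunk 50/50 toward a `a0 + a1/mean` trend; log2FC with a 0.5
   pseudocount on normalized group means; delta-method standard error from
   the NB variance; two-sided normal p. Null p-values are uniform by KS
   test under simulation.
2. **Permutation test.** Statistic = difference in mean log2 normalized
   counts; two-sided tail over label permutations. Designs with ≤ `n_perm`
   distinct assignments are enumerated exhaustively (p = tail/total; a
   fully separated 3-vs-3 gene gives p = 2/20 = 0.1); larger designs sample
   `n_perm` permutations with the (b+1)/(B+1) correction. The default
   B = 5000 keeps the p floor small enough that BH can resolve sparse
   signal: the smallest achievable FDR is roughly `m/(B·m₁)` for m genes
   with m₁ true positives, so B = 1000 would saturate above 0.05 when only
   ~20 of 2,000 genes carry signal.

A gene is significant per procedure at BH FDR < 0.05 and |log2FC| ≥ 1
(fold change ≥ 2, inclusive at the boundary); the consensus call requires
both procedures to agree in direction. Reported statistics come from the
NB procedure. FDR is Benjamini–Hochberg (the fold-change filter applies to
the point estimate); Benjamini–Yekutieli is a config option. Comparisons
are unpaired — the matched design is not assumed — with a paired mode left
to the patient-effect flag.

## Cis lncRNA–mRNA pairs

For each lncRNA significant in any comparison, the nearest coding gene is
found (boundary distance, deterministic tie-break); the pair is kept when
that mRNA is significant in ≥ 1 comparison and both members have mean
RPKM ≥ 1 in at least one group (the unquantified "expression filtering" of
the source procedure is pinned to the active tier; configurable). One pair
per lncRNA. A pair is *co-regulated* when both members are significant in
≥ 2 of the 3 comparisons; direction concordance is recorded but not
required, since the source analysis does not state it.

## Co-expression network

Transcripts are ranked by log-expression variance and the top k selected
(deterministic tie-break). The network is unsigned, `a_ij = |cor|^power`
(signed mode behind a flag); the soft-threshold power is the smallest
candidate whose binned log–log connectivity regression reaches scale-free
R² ≥ 0.8 with negative slope, else the best-R² power with a warning. Block
plantings with equal loadings are *not* scale-free (their degree
distribution is bimodal), so the fallback is the expected path on such
data; the R² ≥ 0.8 branch engages on hub-like (graded-loading) structure.

Topological overlap is
`TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`, diag 1.
Modules come from average-linkage clustering of 1 − TOM with a **static
absolute cut at height 0.98**. The absolute cut (rather than a fraction of
the maximum merge height) is deliberate: the root merge always exceeds any
relative fraction, so a relative cut can never yield a single module and
misbehaves when all dissimilarities are small; on the bounded 1 − TOM scale
genuine co-expression merges sit well below 0.98 while chance merges
concentrate above it (noise pairs at ~0.999). Clusters under
`min_module_size` (30) are unassigned (label 0). Modules whose eigengenes
correlate above `merge_cutoff` (0.75) are merged iteratively, recomputing
eigengenes after each merge until a fixed point.

The module eigengene is the first PC of the standardized member matrix,
unit variance, sign-oriented so members correlate positively on average.
Module–trait correlation is Pearson r of each eigengene against the one-hot
group indicator, p from the t-distribution with n − 2 df.

## Promoter histone-mark linkage

The TSS aggregate profile resamples library-normalized window signal into
an odd number of bins over TSS ± 3 kb, strand-oriented and averaged over
TSSs. Differential windows use a per-window G-test (likelihood ratio of
equal library-normalized rates) with BH correction; adjacent significant
windows of the same direction merge into regions, called at FDR < 0.05 and
fold change > 4 (strict), with region log2FC computed from summed
normalized counts with a +1 pseudocount. A region links to a DE lncRNA
(PC-NC) when it overlaps the promoter window TSS ± 3 kb (half-open); the
3 kb flank matches the only stated TSS window in the source analysis. The
direction-consistency statistic is the Pearson r between region and lncRNA
log2 fold changes over all links, with every (region, lncRNA) pair counted.

## Prognosis-signature correlation

Classifier gene lists are merged by union, dropping unmeasured genes; a
DE-restricted variant intersects with the PC-MC significant set. The
correlation matrix is Pearson on log10(RPKM + 0.01) between each lncRNA and
each signature gene over **all** samples pooled. Rows and columns are
clustered with Euclidean distance and complete linkage. Extraction takes
every flat row-cluster (default 10 clusters, capped at the row count) whose
mean correlation reaches `min_mean_r` (default 0.3), then keeps rows whose
own mean correlation reaches it — combining the dendrogram-cut and
threshold mechanisms, since the source analysis quantifies neither. The
published 33/46 set sizes are dataset-specific and expressly not targets;
the quantitative claim here is planted-block recovery. In the full
pipeline the matrix rows are DE lncRNAs (the clinical procedure); a config
switch widens rows to all lncRNAs.

## SNP proximity

Each SNP maps to its nearest lncRNA; "near" means distance ≤ 10 kb,
boundary inclusive (a SNP at exactly 10,000 bp counts). SNPs on
chromosomes without lncRNAs stay in the denominator with infinite distance,
so the reported fraction is over all input SNPs. DE status joins from the
PC-NC comparison by default (configurable; the source analysis does not
name the comparison).

## Problem sizes and degenerate inputs

The shipped study conditions are 18 samples/group and 2,000 genes (600
lncRNA) for DE/cis/ChIP stages, 600 transcripts for the module stage and
220 lncRNAs for the signature stage — sizes at which every stage's recovery
statistics are stable across seeds while a full pipeline run takes seconds.
Degenerate inputs are defined rather than fatal where the contract says so:
all-zero genes test at (log2FC 0, p 1); constant transcripts correlate at
0 with a warning; constant eigengenes report r = 0, p = 1; p-values are
floored at 1e-300 to stay in (0, 1]. Zero library sizes, empty biotypes,
mismatched window grids, undersized genomes and out-of-range parameters
raise named errors.

## Known limitations

Single-exon gene models only; the NB test is a Wald approximation, not a
GLM with covariates; the permutation test's resolution is bounded by
`n_perm`; module detection assumes modules are either well-separated or
merge-able by eigengene correlation — overlapping soft modules are out of
scope; the ChIP caller assumes a shared fixed window grid and two
conditions without replicates (replicate-aware calling is a non-goal);
survival analysis and external-database enrichment are out of scope.
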