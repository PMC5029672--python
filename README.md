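# lncscape

Integrated analysis of long non-coding RNAs (lncRNAs) in a three-group
tumor RNA-seq design — matched normal colon (NC), primary tumor (PC) and
liver-metastasis (MC) tissue — for computational biologists who have
gene-level count matrices and want the full downstream chain in one tested,
deterministic package:

1. **Expression** — RPKM (reads per kilobase of exon model per million
   mapped reads), detectable/active expression tiers, the lncRNA-vs-mRNA
   level contrast (Wilcoxon rank-sum), sample PCA.
2. **Consensus differential expression** — a negative-binomial Wald test
   intersected with a label-permutation test; a gene is called only when
   both agree in direction at FDR < 0.05 and fold change ≥ 2.
3. **Cis pairs** — each DE lncRNA paired with its nearest protein-coding
   gene; pairs where both members are DE (and expressed) are candidate
   cis-regulatory partners; co-regulated = both DE in ≥ 2 of the 3
   comparisons.
4. **Co-expression modules** — unsigned weighted network
   (a_ij = |cor|^β), topological overlap
   TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij), average-linkage
   modules, module eigengenes (first PC of the standardized members), and
   Pearson eigengene–trait correlations against the NC/PC/MC indicators.
5. **Promoter H3K4me3 linkage** — TSS ± 3 kb aggregate profiles, per-window
   G-test of tumor vs normal (FDR < 0.05, fold change > 4), region-to-DE-lncRNA
   promoter linkage, and the direction-consistency correlation between
   region and lncRNA log2 fold changes.
6. **Prognosis signature** — merged poor-prognosis classifier gene lists,
   the lncRNA × signature-gene Pearson matrix over all samples, Euclidean /
   complete-linkage clustering, and extraction of the positively correlated
   lncRNA set.
7. **SNP proximity** — index SNPs mapped to their nearest lncRNA locus
   within 10 kb (inclusive), joined with DE status.

A first-class synthetic-data generator plants recoverable truth for every
stage (DE genes, cis neighbor pairs, trait-linked modules, promoter
gain/loss links, signature-correlated lncRNAs, near/far SNPs), so each
stage's output is scored against known ground truth. See
[docs/methods.md](docs/methods.md) for models, defaults and limitations.

## Worked example

Run the numbered analysis scripts in order (each prints what it found and
writes tables under `results/`; bulky matrices go to `scratch/`):

```bash
cd analysis
python 01_simulate.py
python 02_expression_de.py
python 03_cis_pairs.py
# ... through 07_snp_mapping.py
```

Output from a run at seed 1:

```
wrote 2000 genes (600 lncRNA) across 2 chromosomes
counts: 2000 genes x 54 samples (18/group)

lncRNA vs mRNA expression level: Wilcoxon p = 1.2e-39 (lncRNAs systematically lower)
PC-NC: 127 consensus DE (37 lncRNA) | recall 0.62 overall, 0.95 on strong effects
31 DE lncRNA-mRNA nearest-neighbor pairs (28 co-regulated in >= 2 comparisons)
planted pairs recovered: 10/10; 21 additional pairs arise from coincidentally neighboring DE genes
module-label ARI on planted members: 0.875
trait PC: best module 3 (r = 0.514, p = 6.9e-05) | contains 96/100 planted PC-module members
31 differential H3K4me3 regions (16 gained, 15 lost) at FDR < 0.05, FC > 4
direction consistency: r = 0.9898 (p = 5.5e-15)
extracted 20 positively correlated lncRNAs — precision 1.00, recall 1.00
9 of 83 SNPs (10.8%) lie within 10 kb of a lncRNA locus
```

Reading this: the Wilcoxon p confirms the planted lower lncRNA expression;
consensus DE recovers essentially all strong (log2FC 2) plantings while
borderline effects induced by the trait-linked modules (true |log2FC| just
over 1) are harder, as expected; the cis scan finds every planted neighbor
pair plus genuine coincidental DE neighbors; the planted PC- and MC-linked
modules are re-found with the right trait correlations; promoter H3K4me3
gains/losses pair with up/down lncRNAs at r ≈ 0.99; the signature block and
the 9-of-83 (10.8%) near-SNP design are recovered exactly.

The same chain is available as a CLI over a YAML config:

```bash
lncscape validate --config config.yaml
lncscape all --config config.yaml --outdir out --seed 1
```

where `config.yaml` either points at your own inputs (`counts`, `samples`,
`annotation`, optional `chip_tumor`/`chip_normal`/`snps`/`signature_lists`)
or carries a `simulate:` block. Identical config + seed gives
byte-identical outputs, including the run manifest.

## Layout

```
src/lncscape/      library: annotation, simulate, expression, de, cis,
                   network, chip, signature, snp, evaluate, pipeline, cli
analysis/          numbered narrative drivers over the library
tests/             pytest suite (unit, property, oracle-equivalence,
                   end-to-end recovery)
scripts/           acceptance.py
docs/methods.md    models, parameter defaults, numerical conventions
```
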