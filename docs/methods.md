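# Methods

## Overview

`tftargets` infers direct transcription-factor targets by integrating two
evidence streams measured over developmental stages: promoter binding
(ChIP-seq of the tagged factor against a tag-only control) and
genotype-dependent expression (RNA-seq of strains carrying functional vs
non-functional alleles). The pipeline has five analysis stages — peak
calling, promoter scoring, differential expression, rank-product
integration, and transcriptome-similarity profiling — plus a first-class
synthetic-data generator that plants known programs so each stage can be
validated against ground truth.

## Peak calling

Windows of 200 bp with 50% overlap tile each chromosome from position 0;
larger processing regions are irrelevant to window coordinates. Reads
enter by their 5′ position (half-open membership) after deduplication to
at most 5 reads per (chromosome, position, strand), which bounds the
influence of PCR artifacts. The window statistic is the log2 ratio of
library-size-scaled counts with one pseudocount read on each side:
`log2(((c_s+1)/N_s)/((c_c+1)/N_c))`. The pseudocount keeps ratios finite;
it is negligible wherever a peak could plausibly be called.

No parametric null is assumed. The null distribution of window statistics
comes from swapping the sample and control labels on the same two
libraries; p-values are add-one empirical exceedance probabilities and
q-values are Benjamini–Hochberg. Two consequences worth knowing:

- the smallest attainable p is 1/(B+1) with B the number of windows, so
  the smallest attainable q is roughly 1/k where k windows sit at that
  floor. A run with only a handful of true peaks cannot reach q < 0.01;
  at realistic peak counts (tens and above, each spanning ~4–6 windows)
  the floor is far below the threshold.
- under exchangeable null data the q-values are conservative; the
  fraction of windows passing q < 0.01 on label-swapped null data is
  ~0 (checked over 10 seeds in the acceptance suite).

Windows passing fold > 4 and q < 0.01 (both strict) merge when
overlapping or adjacent. Per candidate: the strand shift is the offset
(0–200 bp, 10-bp steps) maximizing the Pearson correlation between
10-bp-binned plus- and minus-strand 5′ profiles; reads are moved toward
each other by half that offset; the summit is the leftmost maximum of the
combined profile (10-bp bins, deterministic tie-break). Candidates need
support > 50 sample reads in the merged region and strand balance
|log2(plus/minus)| < 0.5; enrichment is reported as 2^(max window log
ratio). An externally produced peak list (BED) can be intersected in,
retaining internal peaks with ≥ 1 bp overlap.

## Promoter scoring

The promoter of a gene is the intergenic interval from its transcription
start to the nearest annotated gene boundary upstream (any strand — this
prevents promoters from covering coding sequence of an overlapping
model), or the chromosome edge; an optional maximum length truncates on
the side away from the gene. A peak is assigned to a gene when its summit
lies inside the promoter; a summit in the shared region of two divergent
promoters serves both genes; summits inside any gene body are dropped.

The binding score of a gene at a stage is
`Σ_p log2(fold_p) · exp(−λ d_p)` over assigned peaks, with d_p the
summit-to-gene-start distance as a fraction of the gene's own promoter
length (so d ∈ [0, 1]; zero-length promoters take d = 0) and λ = 5 by
default, making a far-end peak worth e⁻⁵ ≈ 0.7% of a proximal one. The
log2 enrichment weight keeps a single extreme peak from dominating sums.
The functional form (exponential decay in fractional distance, enrichment
weighting) is declared here; only its qualitative shape is fixed by the
approach it follows, so λ is exposed as a parameter. A gene is "bound" at
a stage iff at least one assigned peak has fold strictly greater than 4.

## Differential expression

Normalization is median-of-ratios: the reference is the per-gene
geometric mean over samples (genes detected in every sample), size
factors are the per-sample median ratio to the reference, rescaled to
geometric mean 1 so that re-normalizing normalized data yields factors
of exactly 1.

The DE caller conditions on the total of the two group sums of (rounded)
normalized counts. Under the null of a common mean, each group sum is
negative binomial with size n_g/α; the two-sided p-value sums the
probabilities of all splits no more likely than the observed one
(the classic conditional NB test). Dispersion α is moment-matched from
within-group residuals per gene and floored at the across-gene median,
which is conservative when replicates are few (n = 2 in the emulated
design). For totals above 2×10⁵ the test falls back to a Wald statistic
on log group means with variance 1/K + α/n per group. Calibration and
power are measured, not assumed: on null simulations the fraction of
genes at FDR < 0.05 is ≲ 10⁻³, and planted 8-fold changes at mean 100
with two replicates are detected essentially always (acceptance suite).

DE scores are `log2((mean_a + 1)/(mean_b + 1))` for genes with FDR < 0.05
and exactly 0 otherwise; UP/DOWN/NDE categories follow the same gate with
direction from the group means. "Developmentally regulated" means
significant in at least one consecutive-timepoint comparison within a
genotype; the strain-differential set intersects regulation in all normal
genotypes with normal-vs-aberrant differences at any shared timepoint.
Tables from an external empirical-Bayes DE engine can be ingested
verbatim; rows with posterior likelihood ≤ 0.9 are kept but marked
non-significant.

## Integration

Ranks are descending with average ties: binding rank 1 = highest binding
score, DE rank 1 = largest |DE score|. RP = (rank_b · rank_d)/N² lies in
(0, 1] and is invariant to monotone transforms of either score. Genes
with RP < 0.005 (strict) at any stage are direct targets; per-stage sets
and all Venn sectors are emitted. With N genes and ties concentrated at
score 0 (unbound / non-DE genes share an average rank near N/2), only
genes with genuine evidence on both axes can reach small RP, which is
what makes the statistic precise.

The overlap permutation test redraws both gene sets uniformly without
replacement from the universe in every replicate (vectorized, chunked)
and reports the add-one empirical p — never exactly 0, matching the
"close to zero" reporting convention. The exact distribution of the
overlap is hypergeometric, which the test suite uses as an independent
closed-form check; the implementation deliberately does not sample from
it. Binding-score distributions of UP and DOWN genes are compared with
NDE genes by the two-sample KS test (asymptotic p); ECDF tables are
exportable. Temporal concordance is the Spearman correlation between a
gene's binding-score profile across stages and its expression profile at
the stage-matched timepoints (S→2 h, E→5 h, L→8 h); a gene is concordant
iff |ρ| > 0.5 (strict; with three stages ρ ∈ {0, ±0.5, ±1}), and constant
profiles are flagged `constant_profile` rather than scored.

## Transcriptome profiles

Sample distance is D = 1 − Spearman correlation over genes (average-rank
ties; a constant sample raises an error naming it). Classical MDS double-
centres −D²/2 and eigendecomposes; axes with non-positive eigenvalues are
dropped with a warning, and each retained axis is sign-fixed so its
largest-magnitude coordinate is positive (deterministic plots). Exact
recovery of Euclidean-embeddable distances is machine-precision and is
asserted in the tests. Clustering is complete linkage on the condensed
distance matrix with optimal leaf ordering (the dynamic program over
subtree flips; any order achieving the optimum is acceptable). Dendrograms
export to Newick with branch lengths = parent height − child height. Row
standardization uses the population (÷n) standard deviation; constant rows
become zeros with a warning.

## Synthetic data: what it emulates and what it does not

The generator reproduces the emulated study's design: ChIP at three
stages (S, E, L) with matched controls, and RNA-seq of four genotypes —
WT, CM (null complemented with the tagged factor), KO (null), CS (a
zinc-finger point mutant) — at 0/1/2/5/8 h with two replicates.

Defaults (the study conditions at desk scale): 2,000 genes on one
chromosome, gene lengths uniform 500–2,000 bp, geometric intergenic gaps
with mean 1 kb (a gene-dense genome); 10⁶ reads per library; 10% of genes
planted as targets, bound at all three stages with per-stage enrichments
uniform on 8–24-fold and fragment size 200 bp (matching the caller's
shift allowance); expression induced in WT and CM at the stage-matched
timepoints in proportion to binding enrichment (peak expression folds
6–12), flat in KO and CS; a further 10% of genes developmentally
regulated identically in all genotypes; negative-binomial counts with
shared dispersion 0.05 (replicates as tight as the emulated data's) and
per-sample library factors. A planted event contributes multinomial
weight 2(f−1)·frag_size against the genome-length background weight, so
the 5′-read coverage a window caller measures at the summit is f-fold
over background (each strand's 5′ cluster spans ~frag_size).

Not emulated: sequence content (no FASTQ), mappability bias, PCR
duplicate structure beyond what the dedup cap needs, per-gene dispersion,
batch effects, isoforms, and temporally *selective* binding (default
programs bind targets at all stages with independent enrichments).
Passing tests therefore demonstrate the statistical machinery — not
robustness to alignment artifacts or dispersion heterogeneity. One
visible consequence: because per-stage enrichments are drawn
independently and expression is measured with n = 2 counting noise, the
rank-concordance fraction of called targets that the acceptance script
reports is diluted by near-ties (two similar enrichments flip ranks
easily); real data with sharper temporal binding contrast sits higher.

## Numerical choices

- Log base 2 everywhere a log ratio appears.
- Pseudocounts: 1 read (window ratios), 1 normalized count (DE scores).
- All published cutoffs are strict inequalities: fold > 4, q < 0.01,
  support > 50, |strand log ratio| < 0.5, FDR < 0.05, RP < 0.005,
  |ρ| > 0.5.
- Ties: average ranks (RP, Spearman); leftmost maximum (summits);
  first-seen retention (dedup); lowest-index agglomeration (scipy
  linkage).
- Empirical p-values use the add-one convention, so p ∈ (0, 1].
- Determinism: every stochastic routine takes a seed; fixed seeds give
  bit-identical genomes, reads and counts.

## Problem sizes

The test and acceptance workloads are sized for a single CPU: null
calibration uses 10 seeds of 10⁶ reads on a 1-Mb genome; peak recovery
plants 50 peaks among 500 genes at 10⁶ reads; DE calibration uses 2,000
genes × 10 seeds; the end-to-end study uses 2,000 genes with 10% planted
targets. These are the package's reference conditions; all scale linearly
in reads and windows.

## Known limitations

- The empirical label-swap FDR cannot certify q < 0.01 when fewer than
  ~20 true peaks exist genome-wide (p-floor granularity; see above).
- The binding-score constants (λ = 5, log2 enrichment weight) are a
  declared convention with the stated qualitative shape, not a fitted
  model; sensitivity to λ should be explored on real data.
- The DE stand-in shares one moment-matched dispersion floor across
  genes; strongly gene-specific dispersion will make it conservative for
  noisy genes and slightly liberal for ultra-quiet ones.
- The RP normalization (÷N²) makes the 0.005 threshold dimensionless but
  the threshold's biological meaning still depends on the gene universe
  used for ranking; always rank over the full annotated gene set.
- Bootstrap support values for dendrograms are not computed; merge
  heights are exported so support can be added externally.
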