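# tftargets

Direct transcription-factor target calling from ChIP-seq binding and
RNA-seq expression evidence.

`tftargets` re-implements, as a tested and reusable pipeline, the
computational route used to map the direct targets of a developmentally
regulated GATA-type transcription factor in a social amoeba: window-based
ChIP-seq peak calling against a tag-only control, promoter assignment with
an exponential distance-decay binding score, differential expression
between genotypes, and rank-product integration of the two evidence
streams, together with the supporting statistics (gene-set overlap
permutation tests, Kolmogorov–Smirnov comparisons of binding-score
distributions, temporal binding–expression concordance, and
transcriptome-similarity analytics). It is aimed at regulatory genomicists
who want this style of TF-target inference as a library and CLI rather
than a pile of one-off scripts.

Every stage is exercised end-to-end by a synthetic-data module that plants
known binding and expression programs, so the pipeline's operating
characteristics (calibration, recovery, precision/recall) are measurable
without any external downloads.

## Method

**Peak calling.** Reads are deduplicated to at most 5 per (position,
strand). Each 200-bp window w (50% overlap) is scored by the scaled
coverage log ratio

    LR(w) = log2( ((c_s + 1)/N_s) / ((c_c + 1)/N_c) )

with c the window read count and N the library size for sample (s) and
control (c). Empirical p-values come from the label-swapped null
(p = (#{null LR ≥ LR} + 1)/(B + 1)), with Benjamini–Hochberg q-values.
Significant windows (fold > 4, q < 0.01) merge into candidate peaks;
the +/− strand profile shift (≤ 200 bp) is estimated by correlation scan
and corrected before summit placement; candidates must hold > 50 reads
with strand balance |log2(plus/minus)| < 0.5.

**Binding score.** A gene's promoter runs from its transcription start to
the nearest upstream gene boundary. Peaks whose summits fall in the
promoter (and outside all gene bodies) contribute

    score(g) = Σ_p log2(fold_p) · exp(−λ · d_p),   λ = 5,

where d_p is the summit-to-gene-start distance as a fraction of promoter
length.

**Differential expression.** Counts are normalized by median-of-ratios
size factors. The DE caller is a two-sided negative-binomial conditional
test on summed normalized counts with a moment-matched dispersion
(externally computed DE tables can be ingested instead). For genes with
FDR < 0.05 the DE score is log2 of the ratio of group mean expressions;
all other genes score exactly 0, and genes are categorized UP / DOWN /
NDE per comparison.

**Rank-product integration.** At each stage, genes are ranked by binding
score and by |DE score| (highest first, average ties) and combined as
RP = (rank_b · rank_d)/N². Genes with RP < 0.005 at any stage are called
direct targets.

## Worked example

```python
from tftargets import run_synthetic_study

res = run_synthetic_study(n_genes=500, depth=1_000_000, seed=7)
print(f"planted targets: {len(res.truth)}")
print(f"called targets:  {len(res.targets)}  "
      f"precision={res.precision:.2f}  recall={res.recall:.2f}")
print("peaks per stage: " + ", ".join(f"{s}={len(p)}" for s, p in res.peaks_by_stage.items()))
print(res.rp_by_stage["E"].sort_values("rp").head(3).to_string(index=False))
```

prints

```
planted targets: 50
called targets:  45  precision=1.00  recall=0.90
peaks per stage: S=49, E=49, L=49
  gene_id stage  binding_rank  de_rank       rp
gene00363     E           2.0     10.0 0.000080
gene00399     E           5.0      4.0 0.000080
gene00314     E           1.0     21.0 0.000084
```

The study simulated here has 500 genes, 50 of which were planted as bound
(fold ≥ 8 promoter peaks at three developmental stages) and induced in the
normal genotypes; the pipeline calls ChIP peaks per stage, scores
promoters, tests CM-vs-KO differential expression at the stage-matched
timepoints and ranks genes by RP. The three genes shown are the strongest
joint binding + expression candidates at early aggregation; 45 of the 50
planted targets are recovered with no false calls.

The same flow is available from the shell:

```bash
tftargets simulate --outdir study/ --seed 3
tftargets callpeaks --sample study/chip_E_sample.bed --control study/chip_E_control.bed \
    --gff study/genes.gff3 --out peaks_E.bed --stage E
tftargets score --peaks E peaks_E.bed ... --gff study/genes.gff3 --out scores.tsv
tftargets de --counts study/counts.tsv --meta study/samples.tsv --compare CM:KO@5 --out de_E.tsv
tftargets integrate --binding scores.tsv --de E de_E.tsv ... --out targets/
tftargets profiles --counts study/counts.tsv --meta study/samples.tsv --out profiles/
```

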