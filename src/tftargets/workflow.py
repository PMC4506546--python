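"""End-to-end synthetic study: simulate -> call peaks -> score promoters ->
differential expression -> rank-product target calling, with planted-truth
evaluation helpers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import simulate as sim
from .expression import CountMatrix, call_de, compute_de_score, normalize_counts
from .genome import GenomeSpec
from .integration import call_targets, compute_rank_product
from .peaks import call_peaks_pipeline
from .promoters import binding_score_table, define_promoters


@dataclass
class StudyResult:
    genome: GenomeSpec
    binding_program: sim.BindingProgram
    expression_program: sim.ExpressionProgram
    truth: list[str]
    peaks_by_stage: dict[str, pd.DataFrame]
    binding_scores: pd.DataFrame
    de_by_stage: dict[str, pd.DataFrame]
    rp_by_stage: dict[str, pd.DataFrame]
    targets: set[str]
    targets_by_stage: dict[str, set[str]]
    venn_sectors: dict[str, int]
    counts: CountMatrix

    @property
    def precision(self) -> float:
        if not self.targets:
            return float("nan")
        truth = set(self.truth)
        return len(self.targets & truth) / len(self.targets)

    @property
    def recall(self) -> float:
        truth = set(self.truth)
        if not truth:
            return float("nan")
        return len(self.targets & truth) / len(truth)


def run_synthetic_study(
    n_genes: int = 2_000,
    depth: int = 1_000_000,
    target_fraction: float = 0.10,
    rp_threshold: float = 0.005,
    seed: int = 0,
    n_replicates: int = 2,
) -> StudyResult:
    """Full pipeline on a planted-truth synthetic study.

    Binding evidence at each stage is called from simulated ChIP reads;
    expression evidence comes from CM-vs-KO differential expression at the
    stage-matched timepoint; the two are integrated by rank product.
    """
    genome = sim.generate_genome(
        n_genes, sim.suggested_chrom_length(n_genes), seed=seed
    )
    binding_prog, expr_prog, truth = sim.make_study_programs(
        genome, target_fraction=target_fraction, seed=seed + 10
    )
    chip = sim.simulate_chip_reads(genome, binding_prog, depth=depth, seed=seed + 20)
    counts, meta = sim.simulate_counts(genome, expr_prog, n_replicates=n_replicates, seed=seed + 30)

    peaks_by_stage = {}
    for stage, (sample, control) in chip.items():
        peaks, _ = call_peaks_pipeline(sample, control, genome, stage=stage)
        peaks_by_stage[stage] = peaks

    promoters = define_promoters(genome)
    scores = binding_score_table(peaks_by_stage, promoters, genome)

    cm = normalize_counts(CountMatrix(counts, meta))
    de_by_stage, rp_by_stage = {}, {}
    for stage in peaks_by_stage:
        tp = sim.STAGE_TIMEPOINT[stage]
        de = call_de(
            cm.normalized,
            cm.samples_for("CM", tp),
            cm.samples_for("KO", tp),
            comparison=f"CM-vs-KO@{tp}h",
        )
        de = compute_de_score(de)
        de_by_stage[stage] = de
        rp_by_stage[stage] = compute_rank_product(
            scores[stage], de.set_index("gene_id")["de_score"], stage=stage
        )
    targets, per_stage, sectors = call_targets(rp_by_stage, threshold=rp_threshold)
    return StudyResult(
        genome, binding_prog, expr_prog, truth, peaks_by_stage, scores,
        de_by_stage, rp_by_stage, targets, per_stage, sectors, cm,
    )


def null_window_calibration(
    seed: int = 0,
    depth: int = 1_000_000,
    genome_length: int = 1_000_000,
    fdr_max: float = 0.01,
) -> float:
    """Fraction of windows called at the FDR threshold when sample and
    control are drawn from the same (uniform) distribution — the caller's
    false-positive window rate under the null."""
    genome = GenomeSpec(chromosomes=[("chr1", genome_length)])
    reads = sim.simulate_chip_reads(genome, sim.BindingProgram(), depth=depth,
                                    seed=seed, stages=("S",))["S"]
    sample, control = reads
    from .peaks import compute_window_stats, deduplicate_reads, estimate_window_fdr

    s = deduplicate_reads(sample)
    c = deduplicate_reads(control)
    stats = compute_window_stats(s, c, genome)
    null_stats = compute_window_stats(c, s, genome)
    stats = estimate_window_fdr(stats, null_stats)
    return float((stats["q"] < fdr_max).mean())


def peak_recovery_benchmark(
    seed: int = 0,
    n_genes: int = 500,
    n_planted: int = 50,
    depth: int = 1_000_000,
    enrichment_range: tuple[float, float] = (8.0, 24.0),
) -> dict[str, float]:
    """Recovery of planted promoter peaks (fold >= 8) at default caller
    thresholds, with summit tolerance 100 bp."""
    rng = np.random.default_rng(seed)
    genome = sim.generate_genome(n_genes, sim.suggested_chrom_length(n_genes), seed=seed)
    targets = sorted(rng.choice(genome.genes["gene_id"], size=n_planted, replace=False))
    prog = sim.make_binding_program(genome, targets, seed=seed + 1,
                                    enrichment_range=enrichment_range)
    sample, control = sim.simulate_chip_reads(
        genome, prog, depth=depth, seed=seed + 2, stages=("E",))["E"]
    peaks, _ = call_peaks_pipeline(sample, control, genome, stage="E")
    truth = planted_summits(genome, prog, "E")
    return evaluate_peak_recovery(peaks, truth, summit_tol=100)


def de_null_type1_rate(seed: int = 0, n_genes: int = 2_000, mean: float = 150.0,
                       dispersion: float = 0.05, fdr_max: float = 0.05) -> float:
    """Fraction of genes called DE when the two groups share every mean."""
    rng = np.random.default_rng(seed)
    size = 1.0 / dispersion
    cols = ["a1", "a2", "b1", "b2"]
    norm = pd.DataFrame(
        {c: rng.negative_binomial(size, size / (size + mean), n_genes) for c in cols},
        index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id"),
    ).astype(float)
    de = call_de(norm, ["a1", "a2"], ["b1", "b2"])
    return float((de["fdr"] < fdr_max).mean())


def de_power(seed: int = 0, n_genes: int = 1_000, n_planted: int = 100,
             mean: float = 100.0, fold: float = 8.0, dispersion: float = 0.05,
             fdr_max: float = 0.05) -> float:
    """Detection rate for planted fold changes at mean expression ``mean``
    with two replicates per group."""
    rng = np.random.default_rng(seed)
    size = 1.0 / dispersion
    mu_a = np.full(n_genes, mean)
    mu_b = mu_a.copy()
    planted = rng.choice(n_genes, n_planted, replace=False)
    mu_b[planted] *= fold
    idx = pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id")
    norm = pd.DataFrame({
        "a1": rng.negative_binomial(size, size / (size + mu_a)),
        "a2": rng.negative_binomial(size, size / (size + mu_a)),
        "b1": rng.negative_binomial(size, size / (size + mu_b)),
        "b2": rng.negative_binomial(size, size / (size + mu_b)),
    }, index=idx).astype(float)
    de = call_de(norm, ["a1", "a2"], ["b1", "b2"])
    return float((de.iloc[planted]["fdr"] < fdr_max).mean())


def planted_summits(genome: GenomeSpec, program: sim.BindingProgram, stage: str) -> pd.DataFrame:
    """Genomic summit positions of the planted binding events at a stage."""
    info = sim._tss_and_upstream_gap(genome)
    rows = []
    for ev in program.for_stage(stage).itertuples(index=False):
        g = info.loc[ev.gene_id]
        direction = 1 if g.strand == "+" else -1
        rows.append((ev.gene_id, g.chrom, int(g.tss) - direction * int(ev.summit_offset)))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "summit"])


def evaluate_peak_recovery(
    peaks: pd.DataFrame,
    truth_summits: pd.DataFrame,
    summit_tol: int = 100,
    false_tol: int = 500,
) -> dict[str, float]:
    """Planted-truth peak metrics: recovery fraction (a planted summit is
    recovered when a called summit on its chromosome lies within
    ``summit_tol`` bp) and false-call fraction (called peaks with no planted
    summit within ``false_tol`` bp)."""
    recovered = 0
    for t in truth_summits.itertuples(index=False):
        near = peaks[(peaks["chrom"] == t.chrom)
                     & (np.abs(peaks["summit"] - t.summit) <= summit_tol)]
        if len(near):
            recovered += 1
    false_calls = 0
    for p in peaks.itertuples(index=False):
        near = truth_summits[(truth_summits["chrom"] == p.chrom)
                             & (np.abs(truth_summits["summit"] - p.summit) <= false_tol)]
        if not len(near):
            false_calls += 1
    n_truth = len(truth_summits)
    n_calls = len(peaks)
    return {
        "recovery": recovered / n_truth if n_truth else float("nan"),
        "false_fraction": false_calls / n_calls if n_calls else 0.0,
        "n_called": float(n_calls),
        "n_planted": float(n_truth),
    }
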