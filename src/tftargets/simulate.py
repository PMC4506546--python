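"""Synthetic genomes, ChIP-seq read sets and RNA-seq count matrices.

The generator emulates the study design this pipeline analyses: a
social-amoeba-style gene-dense genome; ChIP of a GATA-type transcription
factor at three developmental stages (S - starvation-sensing, E - early
aggregation, L - late aggregation), each with a matched tag-only control
library; and RNA-seq of four genotypes (WT; CM, null complemented with the
tagged factor; KO, null; CS, a zinc-finger point mutant) at five
developmental timepoints (0, 1, 2, 5, 8 h) with two biological replicates.

Planted truth: a chosen fraction of genes is "target" - bound in the
promoter with known enrichment and responsive in the normal genotypes
(WT, CM) but flat in the aberrant ones (KO, CS) - so downstream callers
can be scored against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .genome import GenomeSpec

STAGES = ("S", "E", "L")
GENOTYPES = ("WT", "CM", "KO", "CS")
TIMEPOINTS = (0, 1, 2, 5, 8)
#: developmental stage sampled by ChIP -> RNA-seq timepoint (hours):
#: starvation-sensing ~2 h, early aggregation ~5 h, late aggregation ~8 h.
STAGE_TIMEPOINT = {"S": 2, "E": 5, "L": 8}

EVENT_COLUMNS = ["gene_id", "stage", "enrichment", "summit_offset", "frag_size"]


@dataclass
class BindingProgram:
    """Planted promoter-binding events per gene and stage.

    ``events`` columns: gene_id, stage, enrichment (fold over background,
    >= 1), summit_offset (bp upstream of the gene's transcription start),
    frag_size (bp, sets the planted strand shift).
    """

    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EVENT_COLUMNS))

    def __post_init__(self) -> None:
        self.events = pd.DataFrame(self.events, columns=EVENT_COLUMNS).reset_index(drop=True)
        if len(self.events):
            if (self.events["enrichment"] < 1).any():
                raise ValueError("enrichment multipliers must be >= 1")
            bad = set(self.events["stage"]) - set(STAGES)
            if bad:
                raise ValueError(f"unknown stages {bad}; expected {STAGES}")

    def for_stage(self, stage: str) -> pd.DataFrame:
        return self.events[self.events["stage"] == stage]

    def bound_genes(self, stage: str) -> set[str]:
        return set(self.for_stage(stage)["gene_id"])


@dataclass
class ExpressionProgram:
    """Per-gene mean expression for every (genotype, timepoint) condition.

    ``means`` is genes x conditions with a (genotype, timepoint) column
    MultiIndex. ``dispersion`` is the shared negative-binomial dispersion
    (variance = mu + dispersion * mu^2). ``lib_factors`` maps sample ids to
    library-size factors (default 1.0 for unlisted samples).
    """

    means: pd.DataFrame
    dispersion: float = 0.05
    lib_factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.means.to_numpy() < 0).any():
            raise ValueError("expression means must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if any(f <= 0 for f in self.lib_factors.values()):
            raise ValueError("library-size factors must be > 0")


def generate_genome(
    n_genes: int,
    chrom_length: int,
    intergenic_mean: float = 1_000,
    seed: int = 0,
    gene_length_range: tuple[int, int] = (500, 2_000),
    chrom_name: str = "chr1",
) -> GenomeSpec:
    """Place ``n_genes`` non-overlapping stranded genes on one chromosome.

    Intergenic gaps are geometric with the given mean; gene lengths are
    uniform over ``gene_length_range``. Deterministic for a fixed seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if chrom_length <= 0 or intergenic_mean <= 0:
        raise ValueError("lengths must be positive")
    rng = np.random.default_rng(seed)
    gaps = rng.geometric(1.0 / intergenic_mean, size=n_genes)
    lengths = rng.integers(gene_length_range[0], gene_length_range[1] + 1, size=n_genes)
    strands = rng.choice(["+", "-"], size=n_genes)
    rows = []
    cursor = 0
    for i in range(n_genes):
        start = cursor + int(gaps[i])
        end = start + int(lengths[i])
        if end > chrom_length:
            raise ValueError(
                f"chromosome of {chrom_length} bp too short to place {n_genes} genes "
                f"(ran out at gene {i})"
            )
        rows.append((f"gene{i:05d}", chrom_name, start, end, strands[i]))
        cursor = end
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return GenomeSpec(chromosomes=[(chrom_name, chrom_length)], genes=genes)


def suggested_chrom_length(n_genes: int, intergenic_mean: float = 1_000,
                           gene_length_range: tuple[int, int] = (500, 2_000)) -> int:
    """Chromosome length that comfortably fits ``n_genes`` under the defaults."""
    mean_len = sum(gene_length_range) / 2
    return int(1.3 * n_genes * (mean_len + intergenic_mean))


def _tss_and_upstream_gap(genome: GenomeSpec) -> pd.DataFrame:
    """Per gene: transcription start, strand sign, and the distance to the
    nearest gene boundary upstream of the TSS (bounded by the chromosome)."""
    out = []
    sizes = genome.chrom_sizes
    for chrom, grp in genome.genes.groupby("chrom"):
        grp = grp.sort_values("start").reset_index(drop=True)
        for i, row in grp.iterrows():
            if row.strand == "+":
                tss = row.start
                bound = grp.loc[i - 1, "end"] if i > 0 else 0
                gap = tss - bound
            else:
                tss = row.end
                bound = grp.loc[i + 1, "start"] if i + 1 < len(grp) else sizes[chrom]
                gap = bound - tss
            out.append((row.gene_id, chrom, int(tss), row.strand, int(gap)))
    return pd.DataFrame(out, columns=["gene_id", "chrom", "tss", "strand", "gap"]).set_index("gene_id")


def make_binding_program(
    genome: GenomeSpec,
    target_genes: list[str],
    seed: int = 0,
    enrichment_range: tuple[float, float] = (8.0, 24.0),
    frag_size: int = 200,
) -> BindingProgram:
    """Bind every target gene at all three stages with independent
    per-stage enrichments, summits inside each gene's own promoter."""
    rng = np.random.default_rng(seed)
    info = _tss_and_upstream_gap(genome)
    rows = []
    for gene in target_genes:
        gap = max(int(info.loc[gene, "gap"]), 2)
        offset = int(rng.integers(1, max(2, min(400, int(0.8 * gap)))))
        for stage in STAGES:
            enr = float(rng.uniform(*enrichment_range))
            rows.append((gene, stage, enr, offset, frag_size))
    return BindingProgram(pd.DataFrame(rows, columns=EVENT_COLUMNS))


def make_expression_program(
    genome: GenomeSpec,
    target_genes: list[str],
    seed: int = 0,
    binding: BindingProgram | None = None,
    base_mean_log: tuple[float, float] = (5.0, 1.0),
    target_fold_range: tuple[float, float] = (6.0, 12.0),
    dev_fraction: float = 0.10,
    dispersion: float = 0.05,
) -> ExpressionProgram:
    """Expression means for every genotype and timepoint.

    Target genes are induced in WT and CM in proportion to their planted
    binding enrichment at the stage-matched timepoints (2, 5, 8 h) and stay
    flat in KO and CS. A further ``dev_fraction`` of non-target genes is
    developmentally regulated identically in all genotypes (factor-
    independent developmental program).
    """
    rng = np.random.default_rng(seed)
    gene_ids = list(genome.genes["gene_id"])
    base = np.exp(rng.normal(base_mean_log[0], base_mean_log[1], size=len(gene_ids)))
    cols = pd.MultiIndex.from_product([GENOTYPES, TIMEPOINTS], names=["genotype", "timepoint"])
    means = pd.DataFrame(
        np.repeat(base[:, None], len(cols), axis=1), index=pd.Index(gene_ids, name="gene_id"),
        columns=cols,
    )
    target_set = set(target_genes)
    # stage-matched induction for targets in the normal genotypes
    for gene in target_genes:
        fold = rng.uniform(*target_fold_range)
        if binding is not None:
            ev = binding.events[binding.events["gene_id"] == gene]
            enr = ev.set_index("stage")["enrichment"]
            weights = {s: enr.get(s, 1.0) for s in STAGES}
            wmax = max(weights.values())
            stage_fold = {s: 1.0 + (fold - 1.0) * weights[s] / wmax for s in STAGES}
        else:
            stage_fold = {s: fold for s in STAGES}
        for geno in ("WT", "CM"):
            for stage, tp in STAGE_TIMEPOINT.items():
                means.loc[gene, (geno, tp)] = means.loc[gene, (geno, tp)] * stage_fold[stage]
    # factor-independent developmental genes: same time course in every genotype
    non_targets = [g for g in gene_ids if g not in target_set]
    n_dev = int(round(dev_fraction * len(gene_ids)))
    dev_genes = list(rng.choice(non_targets, size=min(n_dev, len(non_targets)), replace=False))
    for gene in dev_genes:
        fold = rng.uniform(2.0, 6.0)
        onset = rng.choice(TIMEPOINTS[1:])
        for geno in GENOTYPES:
            for tp in TIMEPOINTS:
                if tp >= onset:
                    means.loc[gene, (geno, tp)] = means.loc[gene, (geno, tp)] * fold
    return ExpressionProgram(means=means, dispersion=dispersion)


def make_study_programs(
    genome: GenomeSpec,
    target_fraction: float = 0.10,
    seed: int = 0,
    **expr_kwargs,
) -> tuple[BindingProgram, ExpressionProgram, list[str]]:
    """Draw the planted target set and both programs; returns the truth list."""
    rng = np.random.default_rng(seed)
    gene_ids = list(genome.genes["gene_id"])
    n_targets = int(round(target_fraction * len(gene_ids)))
    targets = sorted(rng.choice(gene_ids, size=n_targets, replace=False))
    binding = make_binding_program(genome, targets, seed=seed + 1)
    expr = make_expression_program(genome, targets, seed=seed + 2, binding=binding, **expr_kwargs)
    return binding, expr, targets


def _uniform_reads(rng: np.random.Generator, genome: GenomeSpec, n: int) -> pd.DataFrame:
    names = [c for c, _ in genome.chromosomes]
    lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
    chrom_idx = rng.choice(len(names), size=n, p=lengths / lengths.sum())
    pos = (rng.random(n) * lengths[chrom_idx]).astype(int)
    strand = rng.choice(["+", "-"], size=n)
    return pd.DataFrame({"chrom": np.array(names, dtype=object)[chrom_idx], "pos": pos, "strand": strand})


def simulate_chip_reads(
    genome: GenomeSpec,
    program: BindingProgram,
    depth: int = 1_000_000,
    seed: int = 0,
    stages: tuple[str, ...] = STAGES,
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Simulate (sample, control) read sets for each stage.

    Controls are uniform background at the same depth. Sample reads are a
    multinomial mix of uniform background and planted peak reads: a bound
    gene at enrichment ``f`` contributes weight ``2 * (f - 1) * frag_size``
    against the background weight (total genome length), which makes the
    expected 5'-read coverage in a fragment-sized window at the summit
    ``f``-fold over background, as a window caller measures it. Peak
    reads get fragment centres jittered around the summit and 5' ends at
    centre -/+ frag_size/2 on the +/- strand, reproducing the strand-shift
    geometry of real ChIP fragments. Exactly ``depth`` sample reads and
    ``depth`` control reads are emitted per stage.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    unknown = set(program.events["gene_id"]) - set(genome.genes["gene_id"])
    if unknown:
        raise ValueError(f"binding program references unknown genes: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    info = _tss_and_upstream_gap(genome)
    sizes = genome.chrom_sizes
    total_len = genome.total_length
    out: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    for stage in stages:
        events = program.for_stage(stage)
        summits, chroms, frag_sizes, weights = [], [], [], []
        for ev in events.itertuples(index=False):
            g = info.loc[ev.gene_id]
            direction = 1 if g.strand == "+" else -1
            summit = int(g.tss) - direction * int(ev.summit_offset)
            if not (0 <= summit < sizes[g.chrom]):
                raise ValueError(
                    f"summit for {ev.gene_id} at {summit} lies outside {g.chrom}"
                )
            summits.append(summit)
            chroms.append(g.chrom)
            frag_sizes.append(int(ev.frag_size))
            # each strand's 5' cluster spans ~frag_size, so 2*(f-1) excess
            # reads per background read make the summit-window coverage
            # f-fold over background as a window caller measures it
            weights.append(2.0 * (float(ev.enrichment) - 1.0) * float(ev.frag_size))
        w = np.array([float(total_len)] + weights)
        alloc = rng.multinomial(depth, w / w.sum())
        parts = [_uniform_reads(rng, genome, int(alloc[0]))]
        for i, n_i in enumerate(alloc[1:]):
            if n_i == 0:
                continue
            frag = frag_sizes[i]
            centre = summits[i] + np.rint(rng.normal(0, frag / 8, size=n_i)).astype(int)
            minus = rng.random(n_i) < 0.5
            pos = np.where(minus, centre + frag // 2, centre - frag // 2)
            pos = np.clip(pos, 0, sizes[chroms[i]] - 1)
            parts.append(pd.DataFrame({
                "chrom": chroms[i],
                "pos": pos.astype(int),
                "strand": np.where(minus, "-", "+"),
            }))
        sample = pd.concat(parts, ignore_index=True)
        control = _uniform_reads(rng, genome, depth)
        out[stage] = (sample, control)
    return out


def sample_id(genotype: str, timepoint: int, replicate: int) -> str:
    return f"{genotype}_{timepoint}h_r{replicate}"


def simulate_counts(
    genome: GenomeSpec,
    program: ExpressionProgram,
    n_replicates: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial raw counts plus a sample-metadata table.

    Counts for sample s, gene g: NB with mean ``lib_factor_s * mu_{g,cond}``
    and the program's shared dispersion (Poisson in the dispersion -> 0
    limit). Metadata records genotype, timepoint and replicate.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    means = program.means.reindex(genome.genes["gene_id"])
    if means.isna().any().any():
        raise ValueError("expression program does not cover every gene in the genome")
    samples, meta_rows, cols = [], [], []
    for geno, tp in means.columns:
        mu_cond = means[(geno, tp)].to_numpy(dtype=float)
        for rep in range(1, n_replicates + 1):
            sid = sample_id(geno, tp, rep)
            mu = mu_cond * program.lib_factors.get(sid, 1.0)
            if program.dispersion < 1e-12:
                counts = rng.poisson(mu)
            else:
                size = 1.0 / program.dispersion
                p = size / (size + np.where(mu > 0, mu, 1.0))
                counts = np.where(mu > 0, rng.negative_binomial(size, p), 0)
            samples.append(counts.astype(int))
            meta_rows.append((sid, geno, tp, rep))
            cols.append(sid)
    counts = pd.DataFrame(
        np.column_stack(samples), index=pd.Index(means.index, name="gene_id"), columns=cols
    )
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "genotype", "timepoint", "replicate"]
    ).set_index("sample_id")
    return counts, metadata


DEFAULT_CONFIG = {
    "n_genes": 2_000,
    "intergenic_mean": 1_000,
    "chrom_length": None,  # derived from n_genes when absent
    "target_fraction": 0.10,
    "depth": 1_000_000,
    "dispersion": 0.05,
    "n_replicates": 2,
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    merged = dict(DEFAULT_CONFIG)
    unknown = set(cfg) - set(merged)
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    merged.update(cfg)
    return merged
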