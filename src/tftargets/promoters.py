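"""Promoter definition, peak-to-gene assignment and binding scores.

A gene's promoter is the intergenic region 5' of its body, extending to
the nearest annotated gene boundary (any strand) or the chromosome end.
Peaks are assigned to a gene when their summit falls inside its promoter;
summits inside any gene body are discarded (intergenic-only rule). The
per-gene binding score sums, over assigned peaks, the log2 enrichment
weighted by an exponential decay in the summit's fractional distance to
the gene start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeSpec

DEFAULT_DECAY = 5.0
PROMOTER_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


@dataclass
class GeneBindingScore:
    gene_id: str
    stage: str
    score: float
    peak_ids: tuple[str, ...] = ()


def define_promoters(genome: GenomeSpec, max_len: int | None = None) -> pd.DataFrame:
    """One promoter interval per gene (0-based half-open).

    For a '+' gene the promoter ends at the gene start and begins at the
    nearest upstream gene boundary (the largest end of any other gene at or
    left of the start), or 0. Mirrored for '-' genes. ``max_len`` truncates
    on the side away from the gene.
    """
    sizes = genome.chrom_sizes
    rows = []
    for chrom, grp in genome.genes.groupby("chrom", sort=False):
        grp = grp.sort_values("start").reset_index(drop=True)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        for i, row in grp.iterrows():
            if row.strand == "+":
                others = ends[(ends <= row.start) & (np.arange(len(grp)) != i)]
                lo = int(others.max()) if len(others) else 0
                hi = int(row.start)
                if max_len is not None:
                    lo = max(lo, hi - max_len)
            else:
                others = starts[(starts >= row.end) & (np.arange(len(grp)) != i)]
                lo = int(row.end)
                hi = int(others.min()) if len(others) else sizes[chrom]
                if max_len is not None:
                    hi = min(hi, lo + max_len)
            rows.append((row.gene_id, chrom, lo, hi, row.strand))
    return pd.DataFrame(rows, columns=PROMOTER_COLUMNS)


def assign_peaks_to_genes(
    peaks: pd.DataFrame,
    promoters: pd.DataFrame,
    genome: GenomeSpec | None = None,
) -> dict[str, pd.DataFrame]:
    """Map gene_id -> the peaks whose summit lies in the gene's promoter.

    A summit in the shared intergenic region of two divergent genes serves
    both. When ``genome`` is given, peaks whose summit falls inside any gene
    body are dropped first (intergenic-only rule).
    """
    peaks = peaks.copy()
    if genome is not None and len(peaks):
        in_body = np.zeros(len(peaks), dtype=bool)
        for chrom, grp in genome.genes.groupby("chrom", sort=False):
            on_chrom = (peaks["chrom"] == chrom).to_numpy()
            if not on_chrom.any():
                continue
            s = peaks.loc[on_chrom, "summit"].to_numpy()
            hit = np.zeros(len(s), dtype=bool)
            for g in grp.itertuples(index=False):
                hit |= (s >= g.start) & (s < g.end)
            in_body[on_chrom] = hit
        peaks = peaks[~in_body]
    out: dict[str, pd.DataFrame] = {}
    for prom in promoters.itertuples(index=False):
        mask = (
            (peaks["chrom"] == prom.chrom)
            & (peaks["summit"] >= prom.start)
            & (peaks["summit"] < prom.end)
        )
        hit = peaks[mask]
        if len(hit):
            out[prom.gene_id] = hit
    return out


def compute_binding_score(
    gene_peaks: pd.DataFrame,
    promoter,
    decay: float = DEFAULT_DECAY,
    stage: str = "",
) -> GeneBindingScore:
    """score = sum_p log2(fold_p) * exp(-decay * d_p), d_p the summit's
    distance to the gene start as a fraction of promoter length."""
    length = int(promoter.end) - int(promoter.start)
    # the promoter abuts the gene start on its right edge for '+' genes,
    # on its left edge for '-' genes
    tss = int(promoter.end) if promoter.strand == "+" else int(promoter.start)
    score = 0.0
    ids = []
    for p in gene_peaks.itertuples(index=False):
        d = 0.0 if length <= 0 else abs(int(p.summit) - tss) / length
        score += np.log2(p.enrichment) * np.exp(-decay * d)
        ids.append(p.peak_id)
    return GeneBindingScore(promoter.gene_id, stage, float(score), tuple(ids))


def binding_score_table(
    peaks_by_stage: dict[str, pd.DataFrame],
    promoters: pd.DataFrame,
    genome: GenomeSpec | None = None,
    decay: float = DEFAULT_DECAY,
) -> pd.DataFrame:
    """Gene x stage binding-score matrix (0 where no peak was assigned),
    covering every gene with a promoter."""
    idx = pd.Index(promoters["gene_id"], name="gene_id")
    table = pd.DataFrame(0.0, index=idx, columns=list(peaks_by_stage))
    prom_by_gene = {p.gene_id: p for p in promoters.itertuples(index=False)}
    for stage, peaks in peaks_by_stage.items():
        assigned = assign_peaks_to_genes(peaks, promoters, genome)
        for gene_id, gp in assigned.items():
            table.loc[gene_id, stage] = compute_binding_score(
                gp, prom_by_gene[gene_id], decay=decay, stage=stage
            ).score
    return table


def classify_bound_genes(
    peaks_by_stage: dict[str, pd.DataFrame],
    promoters: pd.DataFrame,
    genome: GenomeSpec | None = None,
    fold_min: float = 4.0,
) -> dict[str, set[str]]:
    """Per-stage bound-gene sets: a gene is bound at a stage iff at least
    one assigned promoter peak has fold strictly greater than ``fold_min``.

    Returns the per-stage sets plus ``"union"`` (bound at any stage) and
    ``"<stage>_only"`` single-stage partitions.
    """
    per_stage: dict[str, set[str]] = {}
    for stage, peaks in peaks_by_stage.items():
        assigned = assign_peaks_to_genes(peaks, promoters, genome)
        per_stage[stage] = {
            g for g, gp in assigned.items() if (gp["enrichment"] > fold_min).any()
        }
    stages = list(per_stage)
    result = dict(per_stage)
    result["union"] = set().union(*per_stage.values()) if per_stage else set()
    for stage in stages:
        others = set().union(*(per_stage[s] for s in stages if s != stage)) if len(stages) > 1 else set()
        result[f"{stage}_only"] = per_stage[stage] - others
    return result
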