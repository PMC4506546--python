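"""Integration of binding and expression evidence into direct targets.

A gene's rank product (RP) at a stage is the product of its binding-score
rank (highest score = rank 1) and its |DE score| rank (largest = rank 1),
divided by N^2 so the statistic lies in (0, 1] independently of the gene
universe size; genes with RP below a small threshold at any stage are
called direct targets. Supporting statistics: a gene-set overlap
permutation test against random draws from the genome, Kolmogorov-Smirnov
comparisons of binding-score distributions across expression categories,
and per-gene rank correlation between temporal binding and expression
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_RP_THRESHOLD = 0.005
DEFAULT_CONCORDANCE = 0.5
RP_COLUMNS = ["gene_id", "stage", "binding_rank", "de_rank", "rp"]


@dataclass
class OverlapTestResult:
    n_universe: int
    n_a: int
    n_b: int
    observed: int
    n_permutations: int
    p_value: float
    null_mean: float
    null_sd: float


def compute_rank_product(
    binding: pd.Series,
    de_scores: pd.Series,
    stage: str = "",
) -> pd.DataFrame:
    """RP per gene from a binding-score series and a DE-score series.

    Both series must cover the same gene universe. Ranks are descending
    (rank 1 = highest binding score / largest |DE score|) with average-rank
    ties; RP = (binding rank * DE rank) / N^2.
    """
    if set(binding.index) != set(de_scores.index):
        raise ValueError("binding and DE tables cover different gene universes")
    de_scores = de_scores.reindex(binding.index)
    n = len(binding)
    b_rank = sps.rankdata(-binding.to_numpy(dtype=float), method="average")
    d_rank = sps.rankdata(-np.abs(de_scores.to_numpy(dtype=float)), method="average")
    rp = b_rank * d_rank / n**2
    return pd.DataFrame({
        "gene_id": binding.index, "stage": stage,
        "binding_rank": b_rank, "de_rank": d_rank, "rp": rp,
    })


def call_targets(
    rp_by_stage: dict[str, pd.DataFrame],
    threshold: float = DEFAULT_RP_THRESHOLD,
) -> tuple[set[str], dict[str, set[str]], dict[str, int]]:
    """Direct targets: RP strictly below ``threshold`` at any stage.

    Returns (target set, per-stage target sets, Venn sector counts keyed by
    '+'-joined stage combinations, e.g. ``"S+E"`` for targets at S and E
    but no other stage).
    """
    per_stage = {
        stage: set(df.loc[df["rp"] < threshold, "gene_id"])
        for stage, df in rp_by_stage.items()
    }
    targets = set().union(*per_stage.values()) if per_stage else set()
    stages = list(rp_by_stage)
    sectors: dict[str, int] = {}
    for gene_sets, label in _venn_sectors(per_stage, stages):
        sectors[label] = len(gene_sets)
    return targets, per_stage, sectors


def _venn_sectors(per_stage: dict[str, set[str]], stages: list[str]):
    from itertools import combinations

    universe = set().union(*per_stage.values()) if per_stage else set()
    for r in range(1, len(stages) + 1):
        for combo in combinations(stages, r):
            inside = set(universe)
            for s in combo:
                inside &= per_stage[s]
            for s in stages:
                if s not in combo:
                    inside -= per_stage[s]
            yield inside, "+".join(combo)


def overlap_permutation_test(
    set_a: set[str],
    set_b: set[str],
    universe: list[str],
    n_permutations: int = 1_000_000,
    seed: int = 0,
    chunk: int = 512,
) -> OverlapTestResult:
    """Empirical significance of |A ∩ B| against random gene sets.

    Each replicate draws |A| and |B| genes uniformly without replacement
    from the universe and records the overlap; p = (#{overlap >= observed}
    + 1) / (B + 1).
    """
    universe = list(universe)
    u = len(universe)
    if not set_a <= set(universe) or not set_b <= set(universe):
        raise ValueError("gene sets must be subsets of the universe")
    if len(set_a) > u or len(set_b) > u:
        raise ValueError("gene set larger than the universe")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    observed = len(set_a & set_b)
    rng = np.random.default_rng(seed)
    n_a, n_b = len(set_a), len(set_b)
    exceed = 0
    overlaps_sum = 0.0
    overlaps_sq = 0.0
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        # rank of u iid uniforms = a uniform random permutation; the first
        # n_a (resp. n_b) positions of each row are the drawn sets
        ra = np.argsort(rng.random((m, u)), axis=1)[:, :n_a]
        rb = np.argsort(rng.random((m, u)), axis=1)[:, :n_b]
        mask = np.zeros((m, u), dtype=bool)
        rows = np.repeat(np.arange(m), n_a)
        mask[rows, ra.ravel()] = True
        ov = mask[np.repeat(np.arange(m), n_b), rb.ravel()].reshape(m, n_b).sum(axis=1)
        exceed += int((ov >= observed).sum())
        overlaps_sum += float(ov.sum())
        overlaps_sq += float((ov.astype(float) ** 2).sum())
        done += m
    p = (exceed + 1) / (n_permutations + 1)
    mean = overlaps_sum / n_permutations
    var = max(overlaps_sq / n_permutations - mean**2, 0.0)
    return OverlapTestResult(u, n_a, n_b, observed, n_permutations, p, mean, float(np.sqrt(var)))


def compare_binding_distributions(
    binding: pd.Series,
    categories: pd.Series,
) -> pd.DataFrame:
    """Two-sample KS tests of binding scores: UP vs NDE and DOWN vs NDE.

    Returns one row per comparison with the KS statistic D and asymptotic
    p-value; comparisons against an empty category are skipped with a
    warning row (NaN statistics).
    """
    import warnings

    cats = categories.reindex(binding.index)
    nde = binding[cats == "NDE"].to_numpy(dtype=float)
    rows = []
    for label in ("UP", "DOWN"):
        grp = binding[cats == label].to_numpy(dtype=float)
        if len(grp) == 0 or len(nde) == 0:
            warnings.warn(f"category {label!r} or NDE empty; KS comparison skipped")
            rows.append((f"{label}-vs-NDE", len(grp), len(nde), np.nan, np.nan))
            continue
        res = sps.ks_2samp(grp, nde, method="asymp")
        rows.append((f"{label}-vs-NDE", len(grp), len(nde), float(res.statistic), float(res.pvalue)))
    return pd.DataFrame(rows, columns=["comparison", "n", "n_nde", "ks_D", "p_value"])


def ecdf_table(values: pd.Series) -> pd.DataFrame:
    """Exportable ECDF: sorted values and cumulative proportions."""
    x = np.sort(values.to_numpy(dtype=float))
    return pd.DataFrame({"value": x, "cumulative": np.arange(1, len(x) + 1) / len(x)})


def temporal_concordance(
    binding: pd.DataFrame,
    expression: pd.DataFrame,
    threshold: float = DEFAULT_CONCORDANCE,
) -> pd.DataFrame:
    """Spearman correlation of each gene's binding profile across stages
    with its expression profile at the matched timepoints.

    Both inputs are genes x stages with identical column order. A gene is
    concordant iff |rho| strictly exceeds the threshold; constant profiles
    make rho undefined and are flagged not-concordant with a reason code.
    """
    if list(binding.columns) != list(expression.columns):
        raise ValueError("binding and expression stage columns must match")
    if binding.shape[1] < 3:
        raise ValueError("need at least three matched stages")
    expr = expression.reindex(binding.index)
    rows = []
    for gene in binding.index:
        b = binding.loc[gene].to_numpy(dtype=float)
        e = expr.loc[gene].to_numpy(dtype=float)
        if np.all(b == b[0]) or np.all(e == e[0]):
            rows.append((gene, np.nan, False, "constant_profile"))
            continue
        rho = float(sps.spearmanr(b, e).statistic)
        rows.append((gene, rho, bool(abs(rho) > threshold), ""))
    return pd.DataFrame(rows, columns=["gene_id", "rho", "concordant", "reason"]).set_index("gene_id")
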