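"""Count normalization, differential expression and gene categorisation.

Normalization is median-of-ratios (geometric-mean reference over genes
detected in every sample), the robust standard for negative-binomial
count data. The differential-expression caller is a two-sided negative-
binomial conditional test on summed normalized counts with a moment-
matched dispersion — a self-contained test exposing the same decision
interface (per-gene FDR + direction) as the empirical-Bayes engines used
on real data, whose tables can also be imported verbatim.

DE scores are the log2 ratio of average normalized expression between the
two groups for genes passing the FDR gate, and exactly 0 otherwise; genes
are then categorised UP / DOWN / NDE per comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_FDR = 0.05
DE_COLUMNS = ["gene_id", "comparison", "fdr", "direction", "mean_a", "mean_b", "de_score"]


@dataclass
class CountMatrix:
    """Raw (and optionally normalized) counts with sample metadata.

    ``counts``: genes x samples non-negative integers. ``metadata``: indexed
    by sample id with genotype / timepoint / replicate columns covering every
    count column.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    normalized: pd.DataFrame | None = None
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("raw counts must be non-negative")

    def samples_for(self, genotype: str | None = None, timepoint: int | None = None) -> list[str]:
        m = self.metadata.loc[list(self.counts.columns)]
        mask = pd.Series(True, index=m.index)
        if genotype is not None:
            mask &= m["genotype"] == genotype
        if timepoint is not None:
            mask &= m["timepoint"] == timepoint
        return list(m.index[mask])


def median_of_ratios_factors(raw: pd.DataFrame) -> pd.Series:
    """Size factors via median-of-ratios to a geometric-mean reference,
    rescaled to geometric mean 1 (which makes normalization idempotent)."""
    x = raw.to_numpy(dtype=float)
    if x.sum() == 0:
        raise ValueError("all-zero count matrix cannot be normalized")
    allpos = (x > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene detected in every sample; cannot form reference")
    logx = np.log(x[allpos])
    ref = logx.mean(axis=1)
    factors = np.exp(np.median(logx - ref[:, None], axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=raw.columns, name="size_factor")


def normalize_counts(cm: CountMatrix) -> CountMatrix:
    """Return a copy with ``normalized = raw / size_factor`` filled in."""
    factors = median_of_ratios_factors(cm.counts)
    norm = cm.counts / factors
    return replace(cm, normalized=norm, size_factors=factors)


def _moment_dispersion(norm: pd.DataFrame, groups: list[list[str]]) -> np.ndarray:
    """Per-gene NB dispersion by the method of moments on within-group
    residuals, floored at a pooled (median) estimate for stability."""
    mu_parts, var_parts, dof = [], [], 0
    for g in groups:
        if len(g) < 2:
            continue
        block = norm[g].to_numpy(dtype=float)
        mu_parts.append(block.mean(axis=1) * (len(g) - 1))
        var_parts.append(block.var(axis=1, ddof=1) * (len(g) - 1))
        dof += len(g) - 1
    n_genes = norm.shape[0]
    if dof == 0:
        return np.full(n_genes, 0.1)
    mu = np.sum(mu_parts, axis=0) / dof
    var = np.sum(var_parts, axis=0) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mu > 0, (var - mu) / np.maximum(mu, 1e-12) ** 2, np.nan)
    alpha = np.clip(alpha, 0.0, 10.0)
    valid = alpha[~np.isnan(alpha)]
    common = float(np.median(valid)) if len(valid) else 0.1
    common = max(common, 1e-4)
    alpha = np.where(np.isnan(alpha), common, alpha)
    return np.maximum(alpha, common)


def _nb_conditional_pvalue(k_a: int, k_b: int, n_a: int, n_b: int, alpha: float,
                           max_support: int = 200_000) -> float:
    """Two-sided exact-style p: condition on the total T = k_a + k_b, model
    the group sums as NB with the common mean and summed size, and sum the
    probabilities of outcomes no more likely than the observed split."""
    T = k_a + k_b
    if T == 0:
        return 1.0
    mu = T / (n_a + n_b)
    if T > max_support:  # Wald fallback on log group means
        se2 = 1.0 / max(k_a, 0.5) + alpha / n_a + 1.0 / max(k_b, 0.5) + alpha / n_b
        z = (np.log(max(k_a, 0.5) / n_a) - np.log(max(k_b, 0.5) / n_b)) / np.sqrt(se2)
        return float(2 * sps.norm.sf(abs(z)))
    alpha = max(alpha, 1e-8)
    r_a, r_b = n_a / alpha, n_b / alpha
    p_a = r_a / (r_a + n_a * mu)
    p_b = r_b / (r_b + n_b * mu)
    k = np.arange(T + 1)
    logp = sps.nbinom.logpmf(k, r_a, p_a) + sps.nbinom.logpmf(T - k, r_b, p_b)
    logp -= logp.max()
    probs = np.exp(logp)
    obs = probs[k_a]
    return float(probs[probs <= obs * (1 + 1e-12)].sum() / probs.sum())


def call_de(
    norm: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    comparison: str = "",
    fdr_max: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Per-gene differential-expression results between two sample groups.

    ``norm`` is a normalized genes x samples matrix. Returns a DataFrame
    with gene_id, comparison, fdr (BH-adjusted), direction and group means;
    DE scores are filled by :func:`compute_de_score`.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    a = norm[group_a].to_numpy(dtype=float)
    b = norm[group_b].to_numpy(dtype=float)
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("a group has zero total counts; test is degenerate")
    alpha = _moment_dispersion(norm, [group_a, group_b])
    k_a = np.rint(a.sum(axis=1)).astype(np.int64)
    k_b = np.rint(b.sum(axis=1)).astype(np.int64)
    pvals = np.array([
        _nb_conditional_pvalue(int(ka), int(kb), len(group_a), len(group_b), float(al))
        for ka, kb, al in zip(k_a, k_b, alpha)
    ])
    fdr = multipletests(pvals, method="fdr_bh")[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    direction = np.where(mean_a > mean_b, "greater", np.where(mean_a < mean_b, "lesser", "equal"))
    return pd.DataFrame({
        "gene_id": norm.index, "comparison": comparison, "fdr": fdr,
        "direction": direction, "mean_a": mean_a, "mean_b": mean_b,
        "de_score": 0.0,
    })


def compute_de_score(de: pd.DataFrame, fdr_max: float = DEFAULT_FDR,
                     pseudocount: float = 1.0) -> pd.DataFrame:
    """score = log2((mean_a + eps)/(mean_b + eps)) for genes with FDR below
    the gate, exactly 0 otherwise."""
    out = de.copy()
    sig = out["fdr"] < fdr_max
    score = np.log2((out["mean_a"] + pseudocount) / (out["mean_b"] + pseudocount))
    out["de_score"] = np.where(sig, score, 0.0)
    return out


def categorize_updown(de_scored: pd.DataFrame, fdr_max: float = DEFAULT_FDR) -> pd.Series:
    """UP / DOWN / NDE per gene: UP iff FDR < gate and mean_a > mean_b,
    DOWN iff FDR < gate and mean_a < mean_b, NDE otherwise."""
    sig = de_scored["fdr"] < fdr_max
    cat = np.where(sig & (de_scored["mean_a"] > de_scored["mean_b"]), "UP",
                   np.where(sig & (de_scored["mean_a"] < de_scored["mean_b"]), "DOWN", "NDE"))
    return pd.Series(cat, index=pd.Index(de_scored["gene_id"], name="gene_id"), name="category")


def developmental_regulation(
    cm: CountMatrix,
    genotype: str,
    fdr_max: float = DEFAULT_FDR,
) -> set[str]:
    """Genes significantly changing between any pair of consecutive
    timepoints within one genotype."""
    if cm.normalized is None:
        raise ValueError("normalize the matrix first")
    tps = sorted(cm.metadata.loc[cm.samples_for(genotype), "timepoint"].unique())
    if len(tps) < 2:
        raise ValueError(f"genotype {genotype!r} has fewer than two timepoints")
    regulated: set[str] = set()
    for t0, t1 in zip(tps[:-1], tps[1:]):
        de = call_de(
            cm.normalized,
            cm.samples_for(genotype, t0),
            cm.samples_for(genotype, t1),
            comparison=f"{genotype}:{t0}h-vs-{t1}h",
        )
        regulated |= set(de.loc[de["fdr"] < fdr_max, "gene_id"])
    return regulated


def strain_differential_genes(
    cm: CountMatrix,
    normal: tuple[str, ...] = ("WT", "CM"),
    aberrant: tuple[str, ...] = ("KO", "CS"),
    fdr_max: float = DEFAULT_FDR,
) -> set[str]:
    """Genes developmentally regulated in every normal genotype AND
    differentially expressed between some normal and aberrant genotype at
    some shared timepoint (the strain-differential gene set)."""
    if cm.normalized is None:
        raise ValueError("normalize the matrix first")
    dev = [developmental_regulation(cm, g, fdr_max) for g in normal]
    regulated = set.intersection(*dev)
    differential: set[str] = set()
    for gn in normal:
        for ga in aberrant:
            tps = set(cm.metadata.loc[cm.samples_for(gn), "timepoint"]) & set(
                cm.metadata.loc[cm.samples_for(ga), "timepoint"])
            for tp in sorted(tps):
                de = call_de(cm.normalized, cm.samples_for(gn, tp), cm.samples_for(ga, tp),
                             comparison=f"{gn}-vs-{ga}@{tp}h")
                differential |= set(de.loc[de["fdr"] < fdr_max, "gene_id"])
    return regulated & differential


def read_external_de(path, likelihood_min: float = 0.9) -> pd.DataFrame:
    """Ingest an externally computed DE table (gene, comparison, likelihood,
    fdr, direction). Rows failing the posterior-likelihood cut are retained
    but marked non-significant (fdr set to 1)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "comparison", "fdr", "direction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"external DE table lacks columns: {sorted(missing)}")
    out = df.copy()
    if "likelihood" in out.columns:
        out.loc[out["likelihood"] <= likelihood_min, "fdr"] = 1.0
    for col in ("mean_a", "mean_b", "de_score"):
        if col not in out.columns:
            out[col] = np.nan if col != "de_score" else 0.0
    return out[DE_COLUMNS + [c for c in out.columns if c not in DE_COLUMNS]]
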