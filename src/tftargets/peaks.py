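"""Sliding-window ChIP-seq peak calling against a matched control.

The caller scores 200-bp windows (50% overlap) by the log2 ratio of
sample-to-control coverage scaled by library size, assigns empirical
FDRs from a label-swap null, merges significant windows, corrects the
positive/negative strand-profile shift (up to 200 bp) before placing
summits, and filters candidates on enrichment, FDR, read support and
strand balance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from statsmodels.stats.multitest import multipletests

from .genome import GenomeSpec

WINDOW_COLUMNS = ["chrom", "start", "end", "sample_count", "control_count", "log_ratio"]
PEAK_COLUMNS = [
    "chrom", "start", "end", "peak_id", "enrichment",
    "summit", "support", "balance", "stage",
]

# default thresholds: enrichment > 4-fold, FDR < 0.01, read support > 50,
# strand shift <= 200 bp, |log2 strand ratio| < 0.5 — all strict inequalities
DEFAULT_FOLD_MIN = 4.0
DEFAULT_FDR_MAX = 0.01
DEFAULT_SUPPORT_MIN = 50
DEFAULT_SHIFT_MAX = 200
DEFAULT_BALANCE_MAX = 0.5


def deduplicate_reads(reads: pd.DataFrame, cap: int = 5) -> pd.DataFrame:
    """Retain at most ``cap`` reads per (chromosome, position, strand).

    Retention is first-seen order, so the operation is deterministic and
    idempotent.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    keep = reads.groupby(["chrom", "pos", "strand"], sort=False).cumcount() < cap
    return reads[keep].reset_index(drop=True)


def _chrom_sizes(genome) -> dict[str, int]:
    if isinstance(genome, GenomeSpec):
        return genome.chrom_sizes
    return dict(genome)


def _window_counts(pos: np.ndarray, starts: np.ndarray, window: int) -> np.ndarray:
    pos = np.sort(pos)
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, starts + window, side="left")
    return hi - lo


def compute_window_stats(
    sample: pd.DataFrame,
    control: pd.DataFrame,
    genome,
    window: int = 200,
    step: int = 100,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-window counts and scaled log2 coverage ratios.

    For each window, ``log_ratio = log2(((c_s + pc)/N_s) / ((c_c + pc)/N_c))``
    where c is the window's 5'-position count, N the library size and pc the
    pseudocount keeping ratios finite. Windows tile each chromosome
    identically from position 0 regardless of any larger processing region.
    """
    if window % 2 != 0 or step != window // 2:
        raise ValueError("windows must half-overlap: step = window/2")
    n_s, n_c = len(sample), len(control)
    if n_c == 0:
        raise ValueError("control library is empty; cannot scale coverage")
    if n_s == 0:
        raise ValueError("sample library is empty; cannot scale coverage")
    frames = []
    for chrom, length in _chrom_sizes(genome).items():
        if length < window:
            continue
        starts = np.arange(0, length - window + 1, step, dtype=int)
        c_s = _window_counts(sample.loc[sample["chrom"] == chrom, "pos"].to_numpy(), starts, window)
        c_c = _window_counts(control.loc[control["chrom"] == chrom, "pos"].to_numpy(), starts, window)
        with np.errstate(divide="ignore", invalid="ignore"):
            # +/-inf only reachable with pseudocount = 0
            log_ratio = np.log2(((c_s + pseudocount) / n_s) / ((c_c + pseudocount) / n_c))
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + window,
            "sample_count": c_s, "control_count": c_c, "log_ratio": log_ratio,
        }))
    return pd.concat(frames, ignore_index=True)


def estimate_window_fdr(stats: pd.DataFrame, null_stats: pd.DataFrame) -> pd.DataFrame:
    """Empirical p-values against a label-swap null, BH-adjusted q-values.

    p(w) = (#{null log ratios >= w's log ratio} + 1) / (B + 1); the add-one
    convention keeps p > 0.
    """
    null = np.sort(null_stats["log_ratio"].to_numpy())
    B = len(null)
    if B == 0:
        raise ValueError("null window set is empty; cannot calibrate FDR")
    lr = stats["log_ratio"].to_numpy()
    exceed = B - np.searchsorted(null, lr, side="left")
    p = (exceed + 1) / (B + 1)
    out = stats.copy()
    out["p"] = p
    out["q"] = multipletests(p, method="fdr_bh")[1]
    return out


def _merge_windows(sig: pd.DataFrame) -> list[tuple[str, int, int, float]]:
    """Merge overlapping-or-adjacent significant windows; returns
    (chrom, start, end, max log ratio) per merged candidate."""
    merged = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur = None
        for row in grp.itertuples(index=False):
            if cur is None or row.start > cur[2]:
                if cur is not None:
                    merged.append(cur)
                cur = [chrom, row.start, row.end, row.log_ratio]
            else:
                cur[2] = max(cur[2], row.end)
                cur[3] = max(cur[3], row.log_ratio)
        if cur is not None:
            merged.append(cur)
    return [tuple(m) for m in merged]


def _binned_hist(pos: np.ndarray, lo: int, hi: int, bin_size: int) -> np.ndarray:
    edges = np.arange(lo, hi + bin_size, bin_size)
    return np.histogram(pos, bins=edges)[0].astype(float)


def _estimate_shift(plus: np.ndarray, minus: np.ndarray, lo: int, hi: int,
                    shift_max: int, bin_size: int = 10) -> int:
    """Offset (bp) maximizing the Pearson correlation between the plus
    profile and the minus profile shifted left by the offset."""
    ph = _binned_hist(plus, lo, hi, bin_size)
    mh = _binned_hist(minus, lo, hi, bin_size)
    best_d, best_r = 0, -np.inf
    for k in range(0, shift_max // bin_size + 1):
        a = ph[: len(ph) - k] if k else ph
        b = mh[k:] if k else mh
        if len(a) < 2 or a.std() == 0 or b.std() == 0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        if r > best_r:
            best_r, best_d = r, k * bin_size
    return best_d


def call_peaks(
    stats: pd.DataFrame,
    sample: pd.DataFrame,
    fold_min: float = DEFAULT_FOLD_MIN,
    fdr_max: float = DEFAULT_FDR_MAX,
    support_min: int = DEFAULT_SUPPORT_MIN,
    shift_max: int = DEFAULT_SHIFT_MAX,
    balance_max: float = DEFAULT_BALANCE_MAX,
    stage: str = "",
    summit_bin: int = 10,
) -> pd.DataFrame:
    """Merge significant windows into peaks with shift-corrected summits.

    A window is significant when its linear fold (2**log_ratio) exceeds
    ``fold_min`` and its q-value is below ``fdr_max`` (both strict). Merged
    candidates must hold more than ``support_min`` sample reads and strand
    balance |log2(plus/minus)| strictly below ``balance_max``. The summit is
    the leftmost maximum of the combined strand-shift-corrected 5' profile.
    """
    if "q" not in stats.columns:
        raise ValueError("window stats lack q-values; run estimate_window_fdr first")
    fold = 2.0 ** stats["log_ratio"].to_numpy()
    sig = stats[(fold > fold_min) & (stats["q"] < fdr_max)]
    rows = []
    for chrom, start, end, max_lr in _merge_windows(sig):
        reads = sample[(sample["chrom"] == chrom)
                       & (sample["pos"] >= start) & (sample["pos"] < end)]
        plus = reads.loc[reads["strand"] == "+", "pos"].to_numpy()
        minus = reads.loc[reads["strand"] == "-", "pos"].to_numpy()
        support = len(plus) + len(minus)
        if not support > support_min:
            continue
        if len(plus) == 0 or len(minus) == 0:
            continue  # balance is infinite
        balance = abs(np.log2(len(plus) / len(minus)))
        if not balance < balance_max:
            continue
        lo, hi = max(0, start - shift_max), end + shift_max
        d = _estimate_shift(plus, minus, lo, hi, shift_max)
        combined = np.concatenate([plus + d // 2, minus - d // 2])
        combined = combined[(combined >= start) & (combined < end)]
        if len(combined) == 0:
            combined = np.concatenate([plus, minus])
        hist = _binned_hist(combined, start, end, summit_bin)
        summit = start + int(np.argmax(hist)) * summit_bin + summit_bin // 2
        summit = min(summit, end - 1)
        rows.append((chrom, start, end, "", 2.0 ** max_lr, summit, support, balance, stage))
    peaks = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    prefix = f"{stage}_" if stage else ""
    peaks["peak_id"] = [f"{prefix}peak{i:04d}" for i in range(len(peaks))]
    return peaks


def intersect_peaks(internal: pd.DataFrame, external: pd.DataFrame | None) -> pd.DataFrame:
    """Keep internal peaks overlapping (>= 1 bp) any external BED interval.

    ``external`` needs chrom/start/end columns; ``None`` means no external
    evidence was supplied and the internal peaks pass through unchanged.
    """
    if external is None:
        return internal
    trees: dict[str, IntervalTree] = {}
    for row in external.itertuples(index=False):
        if row.end > row.start:
            trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    keep = [
        bool(trees.get(row.chrom) and trees[row.chrom].overlap(row.start, row.end))
        for row in internal.itertuples(index=False)
    ]
    return internal[np.array(keep, dtype=bool)] if len(internal) else internal


def call_peaks_pipeline(
    sample: pd.DataFrame,
    control: pd.DataFrame,
    genome,
    dedup_cap: int = 5,
    external: pd.DataFrame | None = None,
    stage: str = "",
    **thresholds,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dedup -> window stats -> label-swap FDR -> peak calls (+ optional
    external intersection). Returns (peaks, window stats with p/q)."""
    s = deduplicate_reads(sample, dedup_cap)
    c = deduplicate_reads(control, dedup_cap)
    stats = compute_window_stats(s, c, genome)
    null_stats = compute_window_stats(c, s, genome)
    stats = estimate_window_fdr(stats, null_stats)
    peaks = call_peaks(stats, s, stage=stage, **thresholds)
    return intersect_peaks(peaks, external), stats
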