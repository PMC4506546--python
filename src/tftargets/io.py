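"""Readers and writers for the flat-text formats the pipeline exchanges.

Reads travel as BED6 (one line per mapped read, score column unused,
interval = nominal read footprint, the 5' end recoverable from strand).
Peaks travel as BED6+3 with summit/support/balance extras. Count matrices
are TSV with a sample-metadata sidecar.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
READ_COLUMNS = ["chrom", "pos", "strand"]
PEAK_COLUMNS = [
    "chrom", "start", "end", "peak_id", "enrichment",
    "summit", "support", "balance", "stage",
]


def reads_to_bed(reads: pd.DataFrame, read_length: int = 50) -> pd.DataFrame:
    """Convert internal reads (chrom, pos=5' 0-based, strand) to BED6 rows.

    For '-' strand reads the 5' end is the interval's right-most base, so
    the BED interval is ``[pos - read_length + 1, pos + 1)``.
    """
    pos = reads["pos"].to_numpy()
    minus = (reads["strand"] == "-").to_numpy()
    start = np.where(minus, pos - read_length + 1, pos)
    start = np.maximum(start, 0)
    end = np.where(minus, pos + 1, pos + read_length)
    return pd.DataFrame({
        "chrom": reads["chrom"].to_numpy(),
        "start": start.astype(int),
        "end": end.astype(int),
        "name": [f"read{i}" for i in range(len(reads))],
        "score": 0,
        "strand": reads["strand"].to_numpy(),
    })


def bed_to_reads(bed: pd.DataFrame) -> pd.DataFrame:
    """Recover internal 5'-position reads from BED6 intervals."""
    minus = (bed["strand"] == "-").to_numpy()
    pos = np.where(minus, bed["end"].to_numpy() - 1, bed["start"].to_numpy())
    return pd.DataFrame({
        "chrom": bed["chrom"].to_numpy(),
        "pos": pos.astype(int),
        "strand": bed["strand"].to_numpy(),
    })


def write_bed6(df: pd.DataFrame, path) -> None:
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, n_fields: int | None = None) -> pd.DataFrame:
    """Read a BED file (3+ columns), raising with the line number on bad input."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED at line {lineno}: expected >=3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed BED at line {lineno}: {exc}") from None
            if start < 0 or end < start:
                raise ValueError(f"{path}: malformed BED at line {lineno}: bad interval")
            rows.append(parts[: (n_fields or len(parts))])
    if not rows:
        return pd.DataFrame(columns=BED6_COLUMNS[:3])
    width = max(len(r) for r in rows)
    cols = BED6_COLUMNS[:width] if width <= 6 else BED6_COLUMNS + [f"extra{i}" for i in range(width - 6)]
    df = pd.DataFrame([r + [None] * (width - len(r)) for r in rows], columns=cols)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def read_reads_bed(path) -> pd.DataFrame:
    return bed_to_reads(read_bed(path))


def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    """Write peaks as BED6+3: name=peak id, score=round(100*log2 fold),
    strand='.', extras summit/support/balance."""
    out = pd.DataFrame({
        "chrom": peaks["chrom"],
        "start": peaks["start"],
        "end": peaks["end"],
        "name": peaks["peak_id"],
        "score": np.round(100 * np.log2(peaks["enrichment"])).astype(int),
        "strand": ".",
        "summit": peaks["summit"],
        "support": peaks["support"],
        "balance": peaks["balance"].round(4),
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_peaks_bed(path, stage: str = "") -> pd.DataFrame:
    bed = read_bed(path)
    df = pd.DataFrame({
        "chrom": bed["chrom"],
        "start": bed["start"],
        "end": bed["end"],
        "peak_id": bed["name"],
        "enrichment": 2.0 ** (bed["score"].astype(float) / 100.0),
        "summit": bed["extra0"].astype(int),
        "support": bed["extra1"].astype(int),
        "balance": bed["extra2"].astype(float),
    })
    df["stage"] = stage
    return df


def write_counts(counts: pd.DataFrame, metadata: pd.DataFrame, counts_path, meta_path) -> None:
    counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    metadata.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_counts(counts_path, meta_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    missing = set(counts.columns) - set(meta.index)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
    return counts, meta


def write_bedgraph(stats: pd.DataFrame, path, value: str = "log_ratio") -> None:
    stats[["chrom", "start", "end", value]].to_csv(path, sep="\t", header=False, index=False)
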