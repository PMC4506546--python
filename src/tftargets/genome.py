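"""Genome coordinate backbone: chromosomes and stranded gene models.

Coordinates are 0-based, half-open everywhere inside the package; GFF3
import/export converts to and from the format's 1-based inclusive
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


@dataclass
class GenomeSpec:
    """Chromosome sizes plus stranded gene models.

    Parameters
    ----------
    chromosomes
        List of ``(name, length_bp)`` pairs.
    genes
        DataFrame with columns ``gene_id, chrom, start, end, strand``
        (0-based half-open intervals, strand in ``{+, -}``).
    """

    chromosomes: list[tuple[str, int]]
    genes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=GENE_COLUMNS))

    def __post_init__(self) -> None:
        self.genes = pd.DataFrame(self.genes, columns=GENE_COLUMNS).reset_index(drop=True)
        self.genes["start"] = self.genes["start"].astype(int)
        self.genes["end"] = self.genes["end"].astype(int)
        self.validate()

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return int(sum(length for _, length in self.chromosomes))

    def validate(self) -> None:
        sizes = self.chrom_sizes
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        g = self.genes
        if g["gene_id"].duplicated().any():
            dupes = g.loc[g["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if not g["strand"].isin(["+", "-"]).all():
            raise ValueError("gene strand must be '+' or '-'")
        if (g["start"] >= g["end"]).any():
            raise ValueError("gene intervals require start < end")
        for _, row in g.iterrows():
            if row.chrom not in sizes:
                raise ValueError(f"gene {row.gene_id} on unknown chromosome {row.chrom!r}")
            if row.start < 0 or row.end > sizes[row.chrom]:
                raise ValueError(f"gene {row.gene_id} exceeds chromosome bounds")

    def genes_on(self, chrom: str) -> pd.DataFrame:
        return self.genes[self.genes["chrom"] == chrom].sort_values("start")


def write_gff3(genome: GenomeSpec, path) -> None:
    """Write gene models as GFF3 (1-based, inclusive, per the format)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in genome.chromosomes:
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for row in genome.genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\ttftargets\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


def read_gff3(path) -> GenomeSpec:
    """Read gene models from GFF3 back into the internal 0-based convention.

    Chromosome lengths come from ``##sequence-region`` pragmas when present,
    otherwise from the right-most gene end per chromosome.
    """
    chroms: dict[str, int] = {}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    chroms[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: malformed GFF3 at line {lineno}")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != "gene":
                continue
            gene_id = None
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    gene_id = item[3:]
            if gene_id is None:
                raise ValueError(f"{path}: gene without ID attribute at line {lineno}")
            rows.append((gene_id, chrom, int(start) - 1, int(end), strand))
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    for chrom, grp in genes.groupby("chrom"):
        chroms.setdefault(chrom, int(grp["end"].max()))
    return GenomeSpec(chromosomes=sorted(chroms.items()), genes=genes)
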