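import numpy as np
import pandas as pd
import pytest

from tftargets.genome import GenomeSpec


@pytest.fixture
def two_gene_genome():
    """'+' gene at [10000,12000) with an upstream gene ending at 7000."""
    genes = pd.DataFrame({
        "gene_id": ["up", "focal"],
        "chrom": ["chr1", "chr1"],
        "start": [5000, 10000],
        "end": [7000, 12000],
        "strand": ["+", "+"],
    })
    return GenomeSpec(chromosomes=[("chr1", 20000)], genes=genes)


@pytest.fixture
def divergent_genome():
    """Two divergent genes sharing the intergenic region [3000, 6000)."""
    genes = pd.DataFrame({
        "gene_id": ["left", "right"],
        "chrom": ["chr1", "chr1"],
        "start": [1000, 6000],
        "end": [3000, 8000],
        "strand": ["-", "+"],
    })
    return GenomeSpec(chromosomes=[("chr1", 10000)], genes=genes)


def make_reads(positions, strands=None, chrom="chr1"):
    positions = list(positions)
    if strands is None:
        strands = ["+"] * len(positions)
    return pd.DataFrame({"chrom": chrom, "pos": positions, "strand": list(strands)})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
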