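import numpy as np
import pandas as pd
import pytest

from nucdyn.formats import GenomeIndex


@pytest.fixture
def toy_genome():
    return GenomeIndex({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tags(chrom, positions, strand="+"):
    """Build a dyad-tag frame from raw positions."""
    positions = np.asarray(positions, dtype=np.int64)
    if isinstance(strand, str):
        strand = [strand] * len(positions)
    return pd.DataFrame({"chrom": chrom, "pos": positions, "strand": strand})


def make_genes(rows):
    """rows: (gene_id, chrom, strand, start, end)."""
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end"])
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"])
    df["tts"] = np.where(df["strand"] == "+", df["end"], df["start"])
    return df
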