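"""Read preprocessing: dyad inference and PCR-duplicate capping.

MNase/ChIP tags mark one edge of a nucleosome-protected fragment; shifting
each tag 73 bp (half a nucleosome) in its 3' direction places it on the
inferred nucleosome dyad.  PCR duplicates are then limited by the smallest
per-position cap that still retains a target fraction (default 99%) of all
tags, mirroring library-complexity capping rather than full deduplication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import ConfigError, GenomeIndex

log = logging.getLogger(__name__)

HALF_NUCLEOSOME = 73

TAG_COLUMNS = ["chrom", "pos", "strand"]


@dataclass(frozen=True)
class DuplicateCapResult:
    """Outcome of duplicate capping on one library."""

    cap: int | None
    retained: int
    total: int

    @property
    def retained_fraction(self) -> float:
        return self.retained / self.total if self.total else float("nan")


def shift_to_dyad(
    reads: pd.DataFrame,
    genome: GenomeIndex,
    shift: int = HALF_NUCLEOSOME,
) -> pd.DataFrame:
    """Shift each read *shift* bp in the 3' direction to its dyad position.

    Plus-strand reads move their 5' end (``start``) right; minus-strand reads
    move their 5' end (``end - 1``) left.  Tags shifted off either chromosome
    end are dropped and counted in ``attrs['n_dropped_off_end']``.
    """
    strand = reads["strand"].to_numpy()
    pos = np.where(
        strand == "+",
        reads["start"].to_numpy() + shift,
        reads["end"].to_numpy() - 1 - shift,
    )
    sizes = reads["chrom"].map(genome.chrom_sizes).to_numpy()
    ok = (pos >= 0) & (pos < sizes)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.warning("shift_to_dyad: dropped %d tags shifted off chromosome ends", n_dropped)
    tags = pd.DataFrame(
        {
            "chrom": reads["chrom"].to_numpy()[ok],
            "pos": pos[ok].astype(np.int64),
            "strand": strand[ok],
        }
    )
    tags.attrs["n_dropped_off_end"] = n_dropped
    return tags


def duplicate_cap(multiplicities: np.ndarray, retention: float) -> int:
    """Smallest cap D with sum(min(m, D)) >= retention * sum(m).

    Closed-form scan over the sorted multiplicity spectrum; equivalent to an
    exhaustive search over D in [1, max(m)].
    """
    m = np.sort(np.asarray(multiplicities, dtype=np.int64))
    if m.size == 0:
        raise ValueError("no multiplicities given")
    if not 0 < retention <= 1:
        raise ConfigError(f"retention must be in (0, 1], got {retention}")
    total = int(m.sum())
    need = retention * total
    # retained(D) = sum of m <= D, plus D per group with m > D
    csum = np.concatenate([[0], np.cumsum(m)])
    for d in range(1, int(m[-1]) + 1):
        i = np.searchsorted(m, d, side="right")
        retained = csum[i] + d * (m.size - i)
        if retained >= need:
            return d
    return int(m[-1])


def cap_duplicates(
    tags: pd.DataFrame,
    retention: float = 0.99,
) -> tuple[pd.DataFrame, DuplicateCapResult]:
    """Truncate (chrom, pos, strand) duplicate groups to the retention cap.

    Duplicate groups are defined by identical coordinate and strand.  Because
    the dyad shift is a strand-wise bijection of positions, groups are the
    same whether capping is applied to raw reads or to shifted tags.  Within
    a group the first-encountered tags are kept (deterministic).
    """
    total = len(tags)
    if total == 0:
        log.warning("cap_duplicates: empty input, cap undefined")
        return tags.copy(), DuplicateCapResult(cap=None, retained=0, total=0)
    grouped = tags.groupby(["chrom", "pos", "strand"], sort=False)
    mult = grouped.size().to_numpy()
    cap = duplicate_cap(mult, retention)
    keep = grouped.cumcount().to_numpy() < cap
    filtered = tags[keep].reset_index(drop=True)
    result = DuplicateCapResult(cap=cap, retained=len(filtered), total=total)
    return filtered, result


def write_tags_bed(tags: pd.DataFrame, path) -> None:
    """Write dyad tags as BED6 (1-bp intervals at the dyad)."""
    n = len(tags)
    out = pd.DataFrame(
        {
            "chrom": tags["chrom"].to_numpy(),
            "start": tags["pos"].to_numpy(),
            "end": tags["pos"].to_numpy() + 1,
            "name": [f"t{i}" for i in range(n)],
            "score": np.zeros(n, dtype=int),
            "strand": tags["strand"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_tags_bed(path, genome: GenomeIndex) -> pd.DataFrame:
    from .formats import read_alignments

    reads = read_alignments(path, genome, format="bed")
    return pd.DataFrame(
        {
            "chrom": reads["chrom"],
            "pos": reads["start"].astype(np.int64),
            "strand": reads["strand"],
        }
    )
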