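"""Binned occupancy comparison, replicate correlation and region statistics.

Occupancy changes between two samples are scored per fixed-width bin on
depth-normalized tag counts, with a symmetric fold threshold: a bin is a
*gain* when the query is at least ``fold`` times the reference, a *loss* in
the mirror case, *none_detected* when neither sample has tags there, and
*unchanged* otherwise.  A zero denominator with a nonzero numerator counts
as gain/loss, so the four categories partition every bin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .formats import ConfigError, GenomeIndex

log = logging.getLogger(__name__)

CATEGORIES = ("gain", "loss", "none_detected", "unchanged")


@dataclass
class BinTrack:
    """Per-bin tag counts over a genome tiling, with a normalized value.

    ``mode='fraction'`` divides raw counts by the library size (the scale
    used for fold-change comparison); ``mode='rpkm'`` is reads per kilobase
    of bin per million mapped tags (the scale used for correlation).  The
    trailing partial bin of each chromosome keeps its true width.
    """

    bin_size: int
    mode: str
    total_tags: int
    data: pd.DataFrame  # chrom, start, end, count, value

    def same_grid(self, other: "BinTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and len(self.data) == len(other.data)
            and (self.data["chrom"].to_numpy() == other.data["chrom"].to_numpy()).all()
            and (self.data["start"].to_numpy() == other.data["start"].to_numpy()).all()
        )

    @property
    def values(self) -> np.ndarray:
        return self.data["value"].to_numpy()


@dataclass
class BinComparison:
    """Per-bin occupancy-change categories and their genome fractions."""

    data: pd.DataFrame  # chrom, start, end, category
    fractions: dict[str, float] = field(default_factory=dict)


def bin_counts(
    tags: pd.DataFrame,
    genome: GenomeIndex,
    bin_size: int,
    mode: str = "fraction",
) -> BinTrack:
    """Count dyad tags in fixed-width bins tiling every chromosome."""
    if bin_size <= 0:
        raise ConfigError(f"bin_size must be positive, got {bin_size}")
    if mode not in ("fraction", "rpkm"):
        raise ConfigError(f"mode must be 'fraction' or 'rpkm', got {mode!r}")
    total = len(tags)
    by_chrom = dict(iter(tags.groupby("chrom", sort=False)["pos"])) if total else {}
    frames = []
    for chrom, size in genome.items():
        n_bins = math.ceil(size / bin_size)
        pos = by_chrom.get(chrom)
        if pos is None:
            counts = np.zeros(n_bins, dtype=np.int64)
        else:
            counts = np.bincount(pos.to_numpy() // bin_size, minlength=n_bins)
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, size)
        frames.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "count": counts})
        )
    data = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "start", "end", "count"]
    )
    counts = data["count"].to_numpy(dtype=float)
    if total == 0:
        data["value"] = 0.0
    elif mode == "fraction":
        data["value"] = counts / total
    else:  # rpkm
        widths_kb = (data["end"].to_numpy() - data["start"].to_numpy()) / 1000.0
        data["value"] = counts / widths_kb / (total / 1e6)
    return BinTrack(bin_size=bin_size, mode=mode, total_tags=total, data=data)


def classify_bins(
    reference: BinTrack,
    query: BinTrack,
    fold: float = 1.5,
) -> BinComparison:
    """Categorize each bin of the query relative to the reference."""
    if not reference.same_grid(query):
        raise ConfigError("bin grids of the two tracks do not match")
    a = reference.values
    b = query.values
    cat = np.full(len(a), "unchanged", dtype=object)
    both_zero = (a == 0) & (b == 0)
    tol = 1.0 - 1e-9  # a ratio of exactly `fold` counts as changed
    cat[(~both_zero) & (b >= fold * a * tol)] = "gain"
    cat[(~both_zero) & (a >= fold * b * tol)] = "loss"
    cat[both_zero] = "none_detected"
    data = reference.data[["chrom", "start", "end"]].copy()
    data["category"] = cat
    n = len(cat)
    fractions = {c: float((cat == c).sum()) / n for c in CATEGORIES}
    return BinComparison(data=data, fractions=fractions)


def replicate_correlation(
    track_a: BinTrack,
    track_b: BinTrack,
    log_base: float = 10.0,
    pseudocount: float = 0.01,
) -> float:
    """Pearson r of log-scaled per-bin values between two tracks."""
    if not track_a.same_grid(track_b):
        raise ConfigError("bin grids of the two tracks do not match")
    if len(track_a.data) < 2:
        raise ConfigError("need at least two bins for a correlation")
    la = np.log(track_a.values + pseudocount) / np.log(log_base)
    lb = np.log(track_b.values + pseudocount) / np.log(log_base)
    r, _p = stats.pearsonr(la, lb)
    return float(r)


def _union_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly-overlapping intervals into a disjoint sorted union."""
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    out_s, out_e = [s[0]], [e[0]]
    for i in range(1, s.size):
        if s[i] <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e[i])
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.asarray(out_s), np.asarray(out_e)


def coverage_rate(
    nucleosomes: pd.DataFrame,
    regions: pd.DataFrame,
    min_region_len: int = 150,
) -> pd.DataFrame:
    """Fraction of each region covered by the union of nucleosome footprints.

    Regions shorter than *min_region_len* are excluded.  *nucleosomes* is any
    interval frame (e.g. nucleosome calls with their dyad±73 footprints).
    """
    keep = (regions["end"] - regions["start"]) >= min_region_len
    regions = regions[keep].reset_index(drop=True)
    fracs = np.zeros(len(regions))
    nuc_by_chrom = {
        chrom: _union_intervals(g["start"].to_numpy(), g["end"].to_numpy())
        for chrom, g in nucleosomes.groupby("chrom", sort=False)
    }
    for chrom, g in regions.groupby("chrom", sort=False):
        if chrom not in nuc_by_chrom:
            continue
        us, ue = nuc_by_chrom[chrom]
        for idx, rs, re_ in zip(g.index, g["start"].to_numpy(), g["end"].to_numpy()):
            lo = np.searchsorted(ue, rs, side="right")
            hi = np.searchsorted(us, re_, side="left")
            if hi <= lo:
                continue
            overlap = np.minimum(ue[lo:hi], re_) - np.maximum(us[lo:hi], rs)
            fracs[idx] = overlap.sum() / (re_ - rs)
    out = regions.copy()
    out["covered_fraction"] = fracs
    return out


REGION_CATEGORIES = (
    "tss_upstream",
    "tss_downstream",
    "tts_upstream",
    "tts_downstream",
    "genic_rest",
    "intergenic",
)

_LABEL = {name: i for i, name in enumerate(REGION_CATEGORIES)}


def _paint(arr: np.ndarray, start: int, end: int, label: int) -> None:
    lo = max(0, int(start))
    hi = min(arr.size, int(end))
    if hi > lo:
        arr[lo:hi] = label


def region_labels(genes: pd.DataFrame, genome: GenomeIndex) -> dict[str, np.ndarray]:
    """Per-bp category labels; precedence TSS > TTS > genic rest > intergenic.

    Windows are strand-aware: 300 bp upstream / 600 bp downstream of each
    TSS and 300 bp on either side of each TTS.
    """
    labels = {
        chrom: np.full(size, _LABEL["intergenic"], dtype=np.uint8)
        for chrom, size in genome.items()
    }
    by_chrom = genes.groupby("chrom", sort=False)
    for chrom, g in by_chrom:
        if chrom not in labels:
            log.warning("region_labels: gene chromosome %r not in genome, skipped", chrom)
            continue
        arr = labels[chrom]
        for rec in g.itertuples(index=False):
            _paint(arr, rec.start, rec.end, _LABEL["genic_rest"])
        for rec in g.itertuples(index=False):
            if rec.strand == "+":
                _paint(arr, rec.tts - 300, rec.tts, _LABEL["tts_upstream"])
                _paint(arr, rec.tts, rec.tts + 300, _LABEL["tts_downstream"])
            else:
                _paint(arr, rec.tts, rec.tts + 300, _LABEL["tts_upstream"])
                _paint(arr, rec.tts - 300, rec.tts, _LABEL["tts_downstream"])
        for rec in g.itertuples(index=False):
            if rec.strand == "+":
                _paint(arr, rec.tss - 300, rec.tss, _LABEL["tss_upstream"])
                _paint(arr, rec.tss, rec.tss + 600, _LABEL["tss_downstream"])
            else:
                _paint(arr, rec.tss, rec.tss + 300, _LABEL["tss_upstream"])
                _paint(arr, rec.tss - 600, rec.tss, _LABEL["tss_downstream"])
    return labels


def region_read_fractions(
    tags: pd.DataFrame,
    genes: pd.DataFrame,
    genome: GenomeIndex,
) -> pd.Series:
    """Fraction of dyad tags in each of the six genome categories.

    The result sums to 1; the per-category genome length shares are attached
    as ``result.attrs['length_fractions']``.
    """
    labels = region_labels(genes, genome)
    counts = np.zeros(len(REGION_CATEGORIES), dtype=np.int64)
    lengths = np.zeros(len(REGION_CATEGORIES), dtype=np.int64)
    for chrom, arr in labels.items():
        lengths += np.bincount(arr, minlength=len(REGION_CATEGORIES))
    for chrom, g in tags.groupby("chrom", sort=False):
        if chrom not in labels:
            continue
        counts += np.bincount(
            labels[chrom][g["pos"].to_numpy()], minlength=len(REGION_CATEGORIES)
        )
    total = counts.sum()
    fracs = counts / total if total else counts.astype(float)
    out = pd.Series(fracs, index=list(REGION_CATEGORIES), name="tag_fraction")
    out.attrs["length_fractions"] = pd.Series(
        lengths / lengths.sum(), index=list(REGION_CATEGORIES), name="length_fraction"
    )
    return out
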