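"""TSS-anchored occupancy metaprofiles, heatmap matrices and clustering.

Profiles are strand-aware: the axis of a minus-strand gene is flipped so
that positive relative coordinates always point downstream of the TSS.
Per-bin tag counts summed over genes are normalized to RPKM per gene (tags
per kilobase per million mapped, divided by the number of anchor TSSs) and
smoothed with a centered 5-bin moving average whose window shrinks at the
edges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .formats import ConfigError, GenomeIndex

log = logging.getLogger(__name__)


@dataclass
class MetaProfile:
    """Average occupancy around TSSs: one value per fixed-width bin."""

    window: tuple[int, int]  # relative bp, half-open
    bin_size: int
    counts: np.ndarray  # raw summed tag counts per bin
    values: np.ndarray  # smoothed normalized profile
    n_genes: int
    total_tags: int

    @property
    def positions(self) -> np.ndarray:
        """Bin start positions relative to the TSS."""
        return np.arange(self.window[0], self.window[1], self.bin_size)


@dataclass
class ProfileMatrix:
    """Per-gene occupancy rows over a TSS-relative window, in a fixed order."""

    window: tuple[int, int]
    bin_size: int
    matrix: np.ndarray  # genes x bins
    gene_order: list[str]

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.window[0], self.window[1], self.bin_size)

    def reordered(self, gene_order: list[str]) -> "ProfileMatrix":
        """Reuse an exported gene ordering (e.g. from another condition)."""
        index = {g: i for i, g in enumerate(self.gene_order)}
        missing = [g for g in gene_order if g not in index]
        if missing:
            raise ConfigError(f"{len(missing)} genes of the ordering are absent")
        sel = [index[g] for g in gene_order]
        return ProfileMatrix(self.window, self.bin_size, self.matrix[sel], list(gene_order))


def moving_average(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    return (
        pd.Series(np.asarray(values, dtype=float))
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def _relative_positions(pos: np.ndarray, tss: int, strand: str) -> np.ndarray:
    """Distance from the TSS, positive downstream (strand-aware)."""
    if strand == "+":
        return pos - tss
    return (tss - 1) - pos


def tss_profile(
    tags: pd.DataFrame,
    genes: pd.DataFrame,
    window: tuple[int, int] = (-2000, 2000),
    bin_size: int = 10,
    smooth_bins: int = 5,
) -> MetaProfile:
    """Average dyad-tag occupancy around all TSSs.

    Counts are summed per bin across genes, converted to per-gene RPKM
    (count / bin kb / million mapped tags / n genes) and smoothed.
    """
    if len(genes) == 0:
        raise ConfigError("tss_profile needs at least one gene")
    lo, hi = window
    n_bins = (hi - lo) // bin_size
    counts = np.zeros(n_bins, dtype=np.int64)
    by_chrom = {
        chrom: np.sort(g["pos"].to_numpy())
        for chrom, g in tags.groupby("chrom", sort=False)
    }
    for rec in genes.itertuples(index=False):
        pos = by_chrom.get(rec.chrom)
        if pos is None:
            continue
        # tags possibly in window: genomic span [tss-|hi|-1, tss+|hi|+1]
        span = max(abs(lo), abs(hi)) + 1
        i0 = np.searchsorted(pos, rec.tss - span)
        i1 = np.searchsorted(pos, rec.tss + span, side="right")
        rel = _relative_positions(pos[i0:i1], int(rec.tss), rec.strand)
        in_win = (rel >= lo) & (rel < hi)
        if in_win.any():
            counts += np.bincount((rel[in_win] - lo) // bin_size, minlength=n_bins)
    total = len(tags)
    if total:
        rpkm = counts / (bin_size / 1000.0) / (total / 1e6) / len(genes)
    else:
        rpkm = counts.astype(float)
    values = moving_average(rpkm, smooth_bins)
    return MetaProfile(
        window=window,
        bin_size=bin_size,
        counts=counts,
        values=values,
        n_genes=len(genes),
        total_tags=total,
    )


SILENT_FPKM_FLOOR = 0.5


def gene_group_profiles(
    tags: pd.DataFrame,
    genes: pd.DataFrame,
    fpkm: pd.Series,
    window: tuple[int, int] = (-2000, 2000),
    bin_size: int = 10,
    top_quantile: float = 0.05,
    silent_floor: float = SILENT_FPKM_FLOOR,
) -> dict[str, MetaProfile]:
    """TSS profiles for the top-expressed, silent and remaining genes.

    Silent genes fall below *silent_floor* FPKM; the top group holds the
    ``ceil(top_quantile * n_expressed)`` most expressed genes.  Empty groups
    are omitted with a warning.
    """
    fpkm = fpkm.reindex(genes["gene_id"]).fillna(0.0)
    silent_mask = (fpkm < silent_floor).to_numpy()
    expressed = genes[~silent_mask]
    expr_fpkm = fpkm[~silent_mask]
    n_top = math.ceil(top_quantile * len(expressed))
    top_ids = set(expr_fpkm.sort_values(ascending=False).index[:n_top])
    groups = {
        "top": expressed[expressed["gene_id"].isin(top_ids)],
        "silent": genes[silent_mask],
        "others": expressed[~expressed["gene_id"].isin(top_ids)],
    }
    out = {}
    for name, group in groups.items():
        if len(group) == 0:
            log.warning("gene_group_profiles: group %r is empty, omitted", name)
            continue
        out[name] = tss_profile(tags, group, window=window, bin_size=bin_size)
    return out


def profile_matrix(
    calls: pd.DataFrame,
    genes: pd.DataFrame,
    rank_by: pd.Series,
    window: tuple[int, int] = (-500, 1500),
    bin_size: int = 10,
) -> ProfileMatrix:
    """Per-gene nucleosome-occupancy rows around the TSS, ranked for display.

    Each nucleosome call paints the interval dyad±fuzziness; rows are per-bp
    coverage averaged into *bin_size* bins and sorted by *rank_by*
    descending (genes without a ranking value are dropped with a warning).
    The resulting gene order can be reused on other conditions.
    """
    lo, hi = window
    width = hi - lo
    n_bins = width // bin_size
    have_rank = genes["gene_id"].isin(rank_by.dropna().index)
    if (~have_rank).any():
        log.warning("profile_matrix: dropped %d genes missing rank_by", int((~have_rank).sum()))
    genes = genes[have_rank]
    calls_by_chrom = dict(iter(calls.groupby("chrom", sort=False)))
    rows = np.zeros((len(genes), n_bins))
    for gi, rec in enumerate(genes.itertuples(index=False)):
        g = calls_by_chrom.get(rec.chrom)
        if g is None:
            continue
        row = np.zeros(width)
        dyads = g["dyad"].to_numpy()
        fuzz = g["fuzziness"].to_numpy()
        rel_dyad = _relative_positions(dyads, int(rec.tss), rec.strand)
        half = np.ceil(fuzz).astype(int)
        starts = rel_dyad - half
        ends = rel_dyad + half + 1
        near = (ends > lo) & (starts < hi)
        for s, e in zip(starts[near], ends[near]):
            row[max(s - lo, 0) : min(e - lo, width)] += 1
        rows[gi] = row.reshape(n_bins, bin_size).mean(axis=1)
    order = np.argsort(-rank_by.reindex(genes["gene_id"]).to_numpy(), kind="stable")
    gene_order = list(genes["gene_id"].to_numpy()[order])
    return ProfileMatrix(window=window, bin_size=bin_size, matrix=rows[order], gene_order=gene_order)


def kmeans_profiles(
    matrix: ProfileMatrix,
    subwindow: tuple[int, int] = (-300, 600),
    k: int = 4,
    seed: int = 0,
    n_init: int = 50,
) -> np.ndarray:
    """K-means clustering of per-gene profiles over a TSS subwindow.

    Labels are renumbered by descending cluster mean occupancy so that
    label 0 is always the most-occupied cluster (stable reporting).
    """
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    if k > matrix.matrix.shape[0]:
        raise ConfigError(f"k={k} exceeds the number of genes ({matrix.matrix.shape[0]})")
    pos = matrix.positions
    sel = (pos >= subwindow[0]) & (pos < subwindow[1])
    X = matrix.matrix[:, sel]
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    means = np.array([X[raw == i].mean() if (raw == i).any() else -np.inf for i in range(k)])
    relabel = np.empty(k, dtype=int)
    relabel[np.argsort(-means, kind="stable")] = np.arange(k)
    return relabel[raw]
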