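"""Histone-mark island calling and chromatin-domain classification.

Enriched islands are built SICER-style: the genome is tiled in 1-kb
windows, windows with at least 6 reads are kept, consecutive kept windows
are grouped while tolerating a single sub-threshold gap window, and groups
totalling at least 60 reads become islands.  H3K4me3 and H3K27me3 islands
are then combined into *active*, *repressive* and *bivalent* domains:
bivalent when the two marks' islands overlap by at least half of the
smaller island, otherwise each island keeps its own mark's state.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .formats import GenomeIndex

log = logging.getLogger(__name__)

STATES = ("active", "repressive", "bivalent")
MARK_STATE = {"K4me3": "active", "K27me3": "repressive"}


def window_scan(
    tags: pd.DataFrame,
    genome: GenomeIndex,
    win: int = 1000,
    min_reads: int = 6,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Count tags in non-overlapping windows; report those above threshold.

    Returns ``(above, counts)`` where *above* lists windows with at least
    *min_reads* tags and *counts* holds the full per-window count vector per
    chromosome (needed later so gap windows can contribute their reads).
    """
    counts: dict[str, np.ndarray] = {}
    by_chrom = dict(iter(tags.groupby("chrom", sort=False)["pos"]))
    rows = []
    for chrom, size in genome.items():
        n_win = -(-size // win)
        pos = by_chrom.get(chrom)
        c = (
            np.bincount(pos.to_numpy() // win, minlength=n_win)
            if pos is not None
            else np.zeros(n_win, dtype=np.int64)
        )
        counts[chrom] = c
        for i in np.flatnonzero(c >= min_reads):
            rows.append((chrom, int(i), int(i) * win, min((int(i) + 1) * win, size), int(c[i])))
    above = pd.DataFrame(rows, columns=["chrom", "index", "start", "end", "count"])
    return above, counts


def merge_windows(
    above: pd.DataFrame,
    counts: dict[str, np.ndarray],
    win: int = 1000,
    gap: int = 1,
    include_gap_reads: bool = True,
) -> pd.DataFrame:
    """Group above-threshold windows, allowing up to *gap* sub-threshold
    windows between consecutive members.

    Group reads sum over the whole merged span (gap windows included by
    default); the interval spans the first window start to the last window
    end.
    """
    rows = []
    for chrom, g in above.groupby("chrom", sort=False):
        g = g.sort_values("index", kind="stable")
        idx = g["index"].to_numpy()
        win_end = dict(zip(idx, g["end"].to_numpy()))  # last window of a group is above-threshold
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > gap + 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [idx.size - 1]])
        c = counts[chrom]
        for s, e in zip(starts, ends):
            first, last = int(idx[s]), int(idx[e])
            if include_gap_reads:
                reads = int(c[first : last + 1].sum())
            else:
                reads = int(sum(c[i] for i in idx[s : e + 1]))
            rows.append((chrom, first * win, int(win_end[last]), reads, last - first + 1))
    groups = pd.DataFrame(rows, columns=["chrom", "start", "end", "reads", "n_windows"])
    return groups


def call_islands(
    groups: pd.DataFrame,
    mark: str,
    min_total: int = 60,
) -> pd.DataFrame:
    """Keep merged groups with at least *min_total* reads as mark islands."""
    out = groups[groups["reads"] >= min_total].reset_index(drop=True).copy()
    out["mark"] = mark
    return out


def call_islands_from_tags(
    tags: pd.DataFrame,
    genome: GenomeIndex,
    mark: str,
    win: int = 1000,
    min_reads: int = 6,
    gap: int = 1,
    min_total: int = 60,
) -> pd.DataFrame:
    """window_scan -> merge_windows -> call_islands in one step."""
    above, counts = window_scan(tags, genome, win=win, min_reads=min_reads)
    groups = merge_windows(above, counts, win=win, gap=gap)
    return call_islands(groups, mark, min_total=min_total)


def _merge_same_mark(islands: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping islands of the same mark (warns if any)."""
    rows = []
    merged_any = False
    for chrom, g in islands.groupby("chrom", sort=False):
        g = g.sort_values("start", kind="stable")
        cur = None
        for rec in g.itertuples(index=False):
            if cur is None or rec.start >= cur[2]:
                if cur is not None:
                    rows.append(cur)
                cur = [chrom, rec.start, rec.end, rec.reads]
            else:
                cur[2] = max(cur[2], rec.end)
                cur[3] += rec.reads
                merged_any = True
        if cur is not None:
            rows.append(cur)
    if merged_any:
        log.warning("overlapping same-mark islands merged before classification")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "reads"])


def _interval_overlaps(a: pd.DataFrame, b: pd.DataFrame) -> list[tuple[int, int, int]]:
    """All (i_a, i_b, overlap_bp) pairs with positive overlap."""
    pairs = []
    b_by_chrom = dict(iter(b.groupby("chrom", sort=False)))
    for chrom, ga in a.groupby("chrom", sort=False):
        gb = b_by_chrom.get(chrom)
        if gb is None:
            continue
        for ia, ra in zip(ga.index, ga.itertuples(index=False)):
            for ib, rb in zip(gb.index, gb.itertuples(index=False)):
                inter = min(ra.end, rb.end) - max(ra.start, rb.start)
                if inter > 0:
                    pairs.append((ia, ib, inter))
    return pairs


def classify_domains(
    k4_islands: pd.DataFrame,
    k27_islands: pd.DataFrame,
    min_overlap: float = 0.5,
) -> pd.DataFrame:
    """Combine H3K4me3 and H3K27me3 islands into chromatin domains.

    Overlap fraction uses the smaller island as denominator (the symmetric
    choice).  Pairs at or above *min_overlap* become one bivalent domain
    over the union interval, consuming both islands; partial overlaps below
    the threshold leave each island with its own mark's state but flagged
    ``ambiguous`` (a strict no-overlap reading would leave them stateless).
    """
    k4 = _merge_same_mark(k4_islands).reset_index(drop=True)
    k27 = _merge_same_mark(k27_islands).reset_index(drop=True)
    pairs = _interval_overlaps(k4, k27)
    scored = []
    for ia, ib, inter in pairs:
        min_len = min(
            k4.loc[ia, "end"] - k4.loc[ia, "start"],
            k27.loc[ib, "end"] - k27.loc[ib, "start"],
        )
        scored.append((inter / min_len, ia, ib, inter))
    scored.sort(key=lambda t: (-t[0], k4.loc[t[1], "start"], k27.loc[t[2], "start"]))
    consumed_k4: set[int] = set()
    consumed_k27: set[int] = set()
    partial_k4: set[int] = set()
    partial_k27: set[int] = set()
    rows = []
    for frac, ia, ib, _inter in scored:
        if frac >= min_overlap:
            if ia in consumed_k4 or ib in consumed_k27:
                continue
            consumed_k4.add(ia)
            consumed_k27.add(ib)
            rows.append(
                {
                    "chrom": k4.loc[ia, "chrom"],
                    "start": int(min(k4.loc[ia, "start"], k27.loc[ib, "start"])),
                    "end": int(max(k4.loc[ia, "end"], k27.loc[ib, "end"])),
                    "state": "bivalent",
                    "reads": int(k4.loc[ia, "reads"] + k27.loc[ib, "reads"]),
                    "ambiguous": False,
                }
            )
        else:
            partial_k4.add(ia)
            partial_k27.add(ib)
    for frame, state, consumed, partial in (
        (k4, "active", consumed_k4, partial_k4),
        (k27, "repressive", consumed_k27, partial_k27),
    ):
        for i in frame.index:
            if i in consumed:
                continue
            rows.append(
                {
                    "chrom": frame.loc[i, "chrom"],
                    "start": int(frame.loc[i, "start"]),
                    "end": int(frame.loc[i, "end"]),
                    "state": state,
                    "reads": int(frame.loc[i, "reads"]),
                    "ambiguous": i in partial,
                }
            )
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "state", "reads", "ambiguous"])
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def domain_transitions(
    reference: pd.DataFrame,
    target: pd.DataFrame,
    min_overlap: float = 0.5,
) -> pd.DataFrame:
    """Fate of each reference domain in a target condition.

    A reference domain takes the state of the target domain covering at
    least *min_overlap* of the reference's length (highest overlap wins,
    ties to the lower-coordinate target), else ``none``.  Returns a
    row-normalized matrix (reference state x target state).
    """
    target_states = list(STATES) + ["none"]
    counts = pd.DataFrame(0.0, index=list(STATES), columns=target_states)
    pairs = _interval_overlaps(reference, target)
    best: dict[int, tuple[float, int, int]] = {}
    for ia, ib, inter in pairs:
        frac = inter / (reference.loc[ia, "end"] - reference.loc[ia, "start"])
        key = (-frac, int(target.loc[ib, "start"]), ib)
        if ia not in best or key < best[ia]:
            best[ia] = key
    for ia in reference.index:
        ref_state = reference.loc[ia, "state"]
        if ia in best and -best[ia][0] >= min_overlap:
            tgt_state = target.loc[best[ia][2], "state"]
        else:
            tgt_state = "none"
        counts.loc[ref_state, tgt_state] += 1
    totals = counts.sum(axis=1)
    nonzero = totals > 0
    counts.loc[nonzero] = counts.loc[nonzero].div(totals[nonzero], axis=0)
    counts.attrs["row_counts"] = totals.astype(int).to_dict()
    return counts


def write_domains_bed(domains: pd.DataFrame, path) -> None:
    """Write domains as BED6 (name=state, score=reads)."""
    with open(path, "w") as fh:
        for rec in domains.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.state}\t{rec.reads}\t.\n")
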