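"""Promoter CpG classification and H3K4me3/H3K27me3 state dynamics.

A promoter is the TSS±500 bp window.  Promoters overlapping a CpG island
by at least 1 bp are high-CpG (HCG), the rest low-CpG (LCG).  Each
promoter's chromatin state per condition follows the 1-RPKM rule on its
H3K4me3 and H3K27me3 dyad-tag densities: strictly above 1 RPKM in one mark
gives ``K4`` or ``K27``, in both gives ``K4K27``, otherwise ``None``.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .formats import ConfigError, GenomeIndex

log = logging.getLogger(__name__)

PROMOTER_FLANK = 500
STATE_THRESHOLD = 1.0  # RPKM, strict >
PROMOTER_STATES = ("K4", "K27", "K4K27", "None")
CPG_CLASSES = ("HCG", "LCG")


def promoter_intervals(genes: pd.DataFrame, genome: GenomeIndex, flank: int = PROMOTER_FLANK) -> pd.DataFrame:
    """TSS±flank windows, clipped to chromosome bounds."""
    tss = genes["tss"].to_numpy()
    sizes = genes["chrom"].map(genome.chrom_sizes).to_numpy()
    return pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy(),
            "chrom": genes["chrom"].to_numpy(),
            "start": np.maximum(tss - flank, 0),
            "end": np.minimum(tss + flank, sizes),
        }
    )


def classify_cpg(promoters: pd.DataFrame, cpg_islands: pd.DataFrame) -> pd.Series:
    """HCG if the promoter overlaps any CpG island by >= 1 bp, else LCG."""
    classes = np.full(len(promoters), "LCG", dtype=object)
    cpg_by_chrom = {
        chrom: (np.sort(g["start"].to_numpy()), g["end"].to_numpy()[np.argsort(g["start"].to_numpy())])
        for chrom, g in cpg_islands.groupby("chrom", sort=False)
    }
    for i, rec in enumerate(promoters.itertuples(index=False)):
        isl = cpg_by_chrom.get(rec.chrom)
        if isl is None:
            continue
        starts, ends = isl
        j = np.searchsorted(starts, rec.end, side="left")
        if (ends[:j] > rec.start).any():
            classes[i] = "HCG"
    return pd.Series(classes, index=promoters.index, name="cpg_class")


def promoter_rpkm(tags: pd.DataFrame, promoters: pd.DataFrame, total_tags: int | None = None) -> pd.Series:
    """Dyad-tag RPKM over each promoter interval (length-normalized)."""
    if total_tags is None:
        total_tags = len(tags)
    rpkm = np.zeros(len(promoters))
    if total_tags == 0:
        return pd.Series(rpkm, index=promoters.index)
    pos_by_chrom = {
        chrom: np.sort(g["pos"].to_numpy()) for chrom, g in tags.groupby("chrom", sort=False)
    }
    for i, rec in enumerate(promoters.itertuples(index=False)):
        pos = pos_by_chrom.get(rec.chrom)
        if pos is None:
            continue
        count = np.searchsorted(pos, rec.end) - np.searchsorted(pos, rec.start)
        rpkm[i] = count / ((rec.end - rec.start) / 1000.0) / (total_tags / 1e6)
    return pd.Series(rpkm, index=promoters.index)


def promoter_state(
    k4_rpkm: pd.Series | np.ndarray,
    k27_rpkm: pd.Series | np.ndarray,
    threshold: float = STATE_THRESHOLD,
) -> pd.Series:
    """Four-class chromatin state from mark RPKM levels (strictly > threshold)."""
    k4 = np.asarray(k4_rpkm, dtype=float)
    k27 = np.asarray(k27_rpkm, dtype=float)
    if (k4 < 0).any() or (k27 < 0).any():
        raise ConfigError("negative RPKM value")
    state = np.full(k4.shape, "None", dtype=object)
    state[k4 > threshold] = "K4"
    state[k27 > threshold] = "K27"
    state[(k4 > threshold) & (k27 > threshold)] = "K4K27"
    index = k4_rpkm.index if isinstance(k4_rpkm, pd.Series) else None
    return pd.Series(state, index=index, name="state")


def build_promoter_table(
    genes: pd.DataFrame,
    cpg_islands: pd.DataFrame,
    genome: GenomeIndex,
    mark_tags: dict[str, dict[str, pd.DataFrame]],
    threshold: float = STATE_THRESHOLD,
    flank: int = PROMOTER_FLANK,
) -> pd.DataFrame:
    """One row per TSS: CpG class plus per-condition mark RPKM and state.

    *mark_tags* maps condition -> {"K4me3": tags, "K27me3": tags}.
    """
    promoters = promoter_intervals(genes, genome, flank=flank)
    table = promoters.copy()
    table["cpg_class"] = classify_cpg(promoters, cpg_islands)
    for condition, marks in mark_tags.items():
        k4 = promoter_rpkm(marks["K4me3"], promoters)
        k27 = promoter_rpkm(marks["K27me3"], promoters)
        table[f"k4_rpkm_{condition}"] = k4
        table[f"k27_rpkm_{condition}"] = k27
        table[f"state_{condition}"] = promoter_state(k4, k27, threshold=threshold)
    return table


def state_transitions(
    table: pd.DataFrame,
    reference: str,
    target: str,
) -> dict[str, pd.DataFrame]:
    """Per-CpG-class transition matrices of promoter states.

    Rows are states in the *reference* condition, columns states in the
    *target*; each present row is normalized to sum to 1 and empty starting
    states are omitted (noted in ``attrs['omitted_rows']``).
    """
    for cond in (reference, target):
        if f"state_{cond}" not in table.columns:
            raise ConfigError(f"missing condition {cond!r} in promoter table")
    out = {}
    for cpg_class in CPG_CLASSES:
        sub = table[table["cpg_class"] == cpg_class]
        counts = pd.DataFrame(0.0, index=list(PROMOTER_STATES), columns=list(PROMOTER_STATES))
        for start, tgt in zip(sub[f"state_{reference}"], sub[f"state_{target}"]):
            counts.loc[start, tgt] += 1
        totals = counts.sum(axis=1)
        present = totals > 0
        matrix = counts.loc[present].div(totals[present], axis=0)
        matrix.attrs["omitted_rows"] = list(totals.index[~present])
        matrix.attrs["row_counts"] = totals[present].astype(int).to_dict()
        out[cpg_class] = matrix
    return out


def expression_by_state_change(
    table: pd.DataFrame,
    expression: pd.DataFrame,
    start_state: str,
    reference: str,
    target: str,
    cpg_class: str = "HCG",
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Expression of genes starting in one state, grouped by their target state.

    Returns per-target-state log2(FPKM+1) vectors (expression in the target
    condition) and two-tailed t-tests between every pair of groups with at
    least two members.
    """
    fpkm_col = f"fpkm_{target}"
    if fpkm_col not in expression.columns:
        raise ConfigError(f"expression table lacks column {fpkm_col!r}")
    sub = table[(table["cpg_class"] == cpg_class) & (table[f"state_{reference}"] == start_state)]
    expr = expression.set_index("gene_id")[fpkm_col]
    groups: dict[str, np.ndarray] = {}
    for tgt_state, g in sub.groupby(f"state_{target}", sort=False):
        vals = expr.reindex(g["gene_id"]).dropna().to_numpy(dtype=float)
        if vals.size:
            groups[tgt_state] = np.log2(vals + 1.0)
    rows = []
    for a, b in itertools.combinations(sorted(groups), 2):
        if len(groups[a]) < 2 or len(groups[b]) < 2:
            log.warning("t-test skipped for %s vs %s (group too small)", a, b)
            continue
        t, p = stats.ttest_ind(groups[a], groups[b])
        rows.append({"group_a": a, "group_b": b, "t_statistic": float(t), "p_value": float(p)})
    tests = pd.DataFrame(rows, columns=["group_a", "group_b", "t_statistic", "p_value"])
    return groups, tests
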