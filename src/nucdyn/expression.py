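"""Differential-expression filtering, temporal clustering and correlation.

The DE filter matches the classic pairwise rule: a gene is differentially
expressed when some pairwise comparison shows at least a 2-fold FPKM change
(pseudocount 1, so the ratio is (max+1)/(min+1) and symmetric in condition
order) with an FDR-adjusted q-value below 0.05.  The union over pairwise
comparisons forms the DE set, which is then clustered into six temporal
patterns (C1..C6) by K-means on z-scored log2(FPKM+1) trajectories.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .formats import ConfigError

log = logging.getLogger(__name__)

DEFAULT_CONDITIONS = ("MEF", "preiPSC", "iPSC")


def pairwise_comparisons(conditions: tuple[str, ...] | list[str]) -> list[tuple[str, str]]:
    return list(itertools.combinations(conditions, 2))


def q_column(a: str, b: str) -> str:
    return f"q_{a}_vs_{b}"


def fold_change(fpkm_a: np.ndarray, fpkm_b: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Symmetric fold change (max+pc)/(min+pc) on FPKM."""
    hi = np.maximum(fpkm_a, fpkm_b) + pseudocount
    lo = np.minimum(fpkm_a, fpkm_b) + pseudocount
    return hi / lo


def de_genes(
    table: pd.DataFrame,
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS,
    fold: float = 2.0,
    q_max: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Genes differentially expressed in at least one pairwise comparison.

    Requires columns ``fpkm_<cond>`` and ``q_<a>_vs_<b>`` for every pair.
    Genes with a missing q-value are skipped with a warning.
    """
    de_mask = np.zeros(len(table), dtype=bool)
    skipped = np.zeros(len(table), dtype=bool)
    for a, b in pairwise_comparisons(conditions):
        qcol = q_column(a, b)
        if qcol not in table.columns:
            raise ConfigError(f"expression table lacks column {qcol!r}")
        fa = table[f"fpkm_{a}"].to_numpy(dtype=float)
        fb = table[f"fpkm_{b}"].to_numpy(dtype=float)
        q = table[qcol].to_numpy(dtype=float)
        missing = np.isnan(q)
        skipped |= missing
        fc = fold_change(fa, fb, pseudocount)
        de_mask |= (~missing) & (fc >= fold) & (q < q_max)
    if skipped.any():
        log.warning("de_genes: %d genes had a missing q-value in some comparison",
                    int(skipped.sum()))
    return table[de_mask].reset_index(drop=True)


def _trajectory_features(
    table: pd.DataFrame,
    conditions: tuple[str, ...],
    zscore: bool,
) -> np.ndarray:
    X = np.log2(table[[f"fpkm_{c}" for c in conditions]].to_numpy(dtype=float) + 1.0)
    if zscore:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        X = X - mu
        nonflat = sd[:, 0] > 0
        X[nonflat] = X[nonflat] / sd[nonflat]  # zero-variance rows stay centered only
    return X


def canonical_cluster_names(centroids: np.ndarray) -> list[str]:
    """Name k=6 temporal clusters C1..C6 by trajectory shape.

    C1 is the most-decreasing mean trajectory (first-to-last slope) and C3
    the most-increasing.  Of the remaining four, C4 is the strongest
    transient-up (highest interior mean), C6 the strongest transient-down,
    and the last two become C2/C5 by ascending slope.
    """
    k = centroids.shape[0]
    if k != 6:
        return [f"C{i + 1}" for i in range(k)]
    slope = centroids[:, -1] - centroids[:, 0]
    mid = centroids[:, 1:-1].mean(axis=1)
    names = [""] * k
    order = np.argsort(slope, kind="stable")
    c1, c3 = order[0], order[-1]
    names[c1], names[c3] = "C1", "C3"
    rest = [i for i in range(k) if i not in (c1, c3)]
    c4 = max(rest, key=lambda i: (mid[i], -i))
    rest.remove(c4)
    c6 = min(rest, key=lambda i: (mid[i], i))
    rest.remove(c6)
    names[c4], names[c6] = "C4", "C6"
    rest.sort(key=lambda i: slope[i])
    names[rest[0]], names[rest[1]] = "C2", "C5"
    return names


def cluster_de(
    de_table: pd.DataFrame,
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS,
    k: int = 6,
    seed: int = 0,
    n_init: int = 50,
    zscore: bool = True,
) -> pd.Series:
    """K-means clustering of DE-gene temporal trajectories into C1..Ck.

    Features are per-gene z-scored log2(FPKM+1) across conditions (rows with
    zero variance are centered only).  Cluster labels are renamed
    canonically so the naming is reproducible across seeds.
    """
    n = len(de_table)
    if k > n:
        raise ConfigError(f"k={k} exceeds the number of DE genes ({n})")
    X = _trajectory_features(de_table, conditions, zscore)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    names = canonical_cluster_names(km.cluster_centers_)
    labels = pd.Series(
        [names[i] for i in raw], index=de_table["gene_id"].to_numpy(), name="cluster"
    )
    return labels


def condition_correlation(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Pearson correlation matrix of log2(FPKM+pc) across condition columns.

    Zero-variance columns yield NaN entries (reported as missing).
    """
    if columns is None:
        columns = [c for c in table.columns if c.startswith("fpkm_")]
    if len(columns) < 2:
        raise ConfigError("need at least two expression columns")
    X = np.log2(table[columns].to_numpy(dtype=float) + pseudocount)
    frame = pd.DataFrame(X, columns=columns)
    return frame.corr(method="pearson")
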