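"""Nucleosome calling, per-nucleosome fuzziness, and cross-sample matching.

Calling follows the classic smoothed-tag-density approach: dyad tags are
convolved with a Gaussian kernel, candidate positions are accepted greedily
by descending signal, and an accepted dyad suppresses all positions closer
than one exclusion zone (default 147 bp, one nucleosome footprint), so no
two accepted dyads can be closer than the exclusion distance.  Fuzziness is
the RMS deviation of a nucleosome's assigned tag positions about its dyad:
a low value means a well-phased nucleosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .formats import ConfigError, GenomeIndex
from .preprocess import HALF_NUCLEOSOME

log = logging.getLogger(__name__)

CALL_COLUMNS = ["chrom", "dyad", "n_tags", "fuzziness", "start", "end"]


@dataclass(frozen=True)
class FuzzinessComparison:
    """Paired fuzziness summary for matched nucleosomes of two samples."""

    mean_a: float
    mean_b: float
    mean_difference: float
    t_statistic: float
    p_value: float
    n_pairs: int


def fuzziness(positions: np.ndarray, dyad: float) -> float:
    """RMS deviation of tag positions about the dyad.

    Coincides with the standard deviation when the dyad equals the tag mean.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("fuzziness needs at least one tag")
    return float(np.sqrt(np.mean((positions - dyad) ** 2)))


def _local_maxima(signal: np.ndarray) -> np.ndarray:
    """Positions of positive local maxima (leftmost point of any plateau)."""
    left = np.empty_like(signal)
    left[0] = -np.inf
    left[1:] = signal[:-1]
    right = np.empty_like(signal)
    right[-1] = -np.inf
    right[:-1] = signal[1:]
    return np.flatnonzero((signal > left) & (signal >= right) & (signal > 0))


def _greedy_peaks(signal: np.ndarray, exclusion: int) -> np.ndarray:
    """Greedy selection of smoothed-signal peaks with an exclusion zone.

    Candidates are local maxima; ties in signal are broken toward the lower
    coordinate.  Returns accepted dyads in ascending coordinate order.
    """
    candidates = _local_maxima(signal)
    if candidates.size == 0:
        return candidates
    # lexsort: primary key last -> sort by -signal, ties by position ascending
    order = candidates[np.lexsort((candidates, -signal[candidates]))]
    suppressed = np.zeros(signal.size, dtype=bool)
    accepted = []
    for p in order:
        if suppressed[p]:
            continue
        accepted.append(p)
        lo = max(0, p - exclusion + 1)
        suppressed[lo : p + exclusion] = True
    return np.sort(np.asarray(accepted, dtype=np.int64))


def assign_tags(
    positions: np.ndarray,
    dyads: np.ndarray,
    max_dist: int | None = HALF_NUCLEOSOME,
) -> np.ndarray:
    """Index of the nearest dyad for each tag, or -1 beyond *max_dist*.

    *dyads* must be sorted ascending.  ``max_dist=None`` assigns every tag to
    its nearest dyad regardless of distance.
    """
    if dyads.size == 0:
        return np.full(positions.shape, -1, dtype=np.int64)
    right = np.searchsorted(dyads, positions)
    left = np.clip(right - 1, 0, dyads.size - 1)
    right = np.clip(right, 0, dyads.size - 1)
    d_left = np.abs(positions - dyads[left])
    d_right = np.abs(positions - dyads[right])
    idx = np.where(d_left <= d_right, left, right)
    dist = np.minimum(d_left, d_right)
    if max_dist is not None:
        idx = np.where(dist <= max_dist, idx, -1)
    return idx.astype(np.int64)


def call_nucleosomes(
    tags: pd.DataFrame,
    genome: GenomeIndex,
    sigma: float = 20.0,
    exclusion: int = 147,
    min_tags: int = 3,
    max_assign_dist: int | None = HALF_NUCLEOSOME,
) -> pd.DataFrame:
    """Call nucleosomes from dyad tags, one chromosome at a time.

    Returns a frame with columns ``chrom, dyad, n_tags, fuzziness, start,
    end`` where ``[start, end)`` is the dyad±73 footprint clipped to the
    chromosome.  Calls with fewer than *min_tags* assigned tags are dropped.
    """
    if sigma <= 0:
        raise ConfigError(f"sigma must be positive, got {sigma}")
    if exclusion <= 0:
        raise ConfigError(f"exclusion must be positive, got {exclusion}")
    frames = []
    for chrom, g in tags.groupby("chrom", sort=False):
        size = genome[chrom]
        pos = g["pos"].to_numpy()
        density = np.bincount(pos, minlength=size).astype(float)
        signal = gaussian_filter1d(density, sigma, truncate=4.0, mode="constant")
        dyads = _greedy_peaks(signal, exclusion)
        if dyads.size == 0:
            continue
        idx = assign_tags(pos, dyads, max_assign_dist)
        assigned = idx >= 0
        n_tags = np.bincount(idx[assigned], minlength=dyads.size)
        sq = np.zeros(dyads.size)
        np.add.at(sq, idx[assigned], (pos[assigned] - dyads[idx[assigned]]) ** 2.0)
        with np.errstate(invalid="ignore"):
            fuzz = np.sqrt(sq / np.where(n_tags > 0, n_tags, 1))
        keep = n_tags >= min_tags
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "dyad": dyads[keep],
                    "n_tags": n_tags[keep],
                    "fuzziness": fuzz[keep],
                    "start": np.maximum(dyads[keep] - HALF_NUCLEOSOME, 0),
                    "end": np.minimum(dyads[keep] + HALF_NUCLEOSOME + 1, size),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=CALL_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def match_common(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    max_dist: int = HALF_NUCLEOSOME,
) -> pd.DataFrame:
    """Greedy one-to-one matching of nucleosome calls between two samples.

    Candidate pairs with dyad distance < *max_dist* (strictly less than half
    a nucleosome by default) are taken in order of increasing distance; each
    call joins at most one pair.
    """
    rows = []
    b_by_chrom = dict(iter(calls_b.groupby("chrom", sort=False)))
    for chrom, ga in calls_a.groupby("chrom", sort=False):
        gb = b_by_chrom.get(chrom)
        if gb is None:
            continue
        ga = ga.sort_values("dyad", kind="stable").reset_index(drop=True)
        gb = gb.sort_values("dyad", kind="stable").reset_index(drop=True)
        da = ga["dyad"].to_numpy()
        db = gb["dyad"].to_numpy()
        cand = []
        for ia, d in enumerate(da):
            lo = np.searchsorted(db, d - max_dist + 1)
            hi = np.searchsorted(db, d + max_dist, side="right")
            for ib in range(lo, hi):
                dist = abs(int(d) - int(db[ib]))
                if dist < max_dist:
                    cand.append((dist, int(d), ia, ib))
        cand.sort()
        used_a: set[int] = set()
        used_b: set[int] = set()
        for dist, _d, ia, ib in cand:
            if ia in used_a or ib in used_b:
                continue
            used_a.add(ia)
            used_b.add(ib)
            rows.append(
                {
                    "chrom": chrom,
                    "dyad_a": int(da[ia]),
                    "dyad_b": int(db[ib]),
                    "distance": dist,
                    "fuzziness_a": float(ga["fuzziness"].iloc[ia]),
                    "fuzziness_b": float(gb["fuzziness"].iloc[ib]),
                    "n_tags_a": int(ga["n_tags"].iloc[ia]),
                    "n_tags_b": int(gb["n_tags"].iloc[ib]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "dyad_a", "dyad_b", "distance",
            "fuzziness_a", "fuzziness_b", "n_tags_a", "n_tags_b",
        ],
    )


def compare_fuzziness(pairs: pd.DataFrame) -> FuzzinessComparison:
    """Mean fuzziness per sample over matched pairs, with a paired t-test."""
    if len(pairs) < 2:
        raise ValueError("need at least two matched pairs for a paired t-test")
    a = pairs["fuzziness_a"].to_numpy(dtype=float)
    b = pairs["fuzziness_b"].to_numpy(dtype=float)
    diff = b - a
    if np.allclose(diff, diff[0]):
        # degenerate case (constant difference): scipy would warn; report directly
        t = 0.0 if diff[0] == 0 else float("inf") * np.sign(diff[0])
        p = 1.0 if diff[0] == 0 else 0.0
    else:
        t, p = stats.ttest_rel(b, a)
    return FuzzinessComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        mean_difference=float(diff.mean()),
        t_statistic=float(t),
        p_value=float(p),
        n_pairs=len(pairs),
    )


def write_calls_bed(calls: pd.DataFrame, path) -> None:
    """Write calls as BED6+2 (name=id, score=n_tags, extra: dyad, fuzziness)."""
    with open(path, "w") as fh:
        for i, rec in enumerate(calls.itertuples(index=False)):
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\tnuc{i}\t{rec.n_tags}\t."
                f"\t{rec.dyad}\t{rec.fuzziness:.3f}\n"
            )


def read_calls_bed(path) -> pd.DataFrame:
    raw = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "n_tags", "strand", "dyad", "fuzziness"],
        dtype={"chrom": str},
    )
    return raw[["chrom", "dyad", "n_tags", "fuzziness", "start", "end"]].copy()
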