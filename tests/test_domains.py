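import re

import numpy as np
import pandas as pd
import pytest

from conftest import make_tags
from nucdyn.domains import (
    call_islands,
    call_islands_from_tags,
    classify_domains,
    domain_transitions,
    merge_windows,
    window_scan,
)
from nucdyn.formats import GenomeIndex


def oracle_islands(counts, win=1000, min_reads=6, min_total=60):
    """Independent regex-based oracle for the window->island pipeline.

    Above-threshold windows are 'A', others 'b'; an island is a maximal run
    matching A(b?A)* (at most one sub-threshold window between members),
    with total reads over the whole merged span and a 60-read floor.
    """
    pattern = "".join("A" if c >= min_reads else "b" for c in counts)
    islands = []
    for m in re.finditer(r"A(?:b?A)+|A", pattern):
        first, last = m.start(), m.end() - 1
        reads = int(sum(counts[first : last + 1]))
        if reads >= min_total:
            islands.append((first * win, (last + 1) * win, reads))
    return islands


def counts_to_tags(counts, win=1000):
    positions = []
    for i, c in enumerate(counts):
        positions.extend([i * win + 5] * int(c))
    return make_tags("chr1", positions)


class TestWindowScan:
    def test_threshold_selection(self):
        genome = GenomeIndex({"chr1": 6000})
        above, counts = window_scan(counts_to_tags([7, 3, 8, 2, 2, 9]), genome)
        assert list(above["index"]) == [0, 2, 5]
        assert list(counts["chr1"]) == [7, 3, 8, 2, 2, 9]

    def test_boundary_six_reads_included(self):
        genome = GenomeIndex({"chr1": 1000})
        above, _ = window_scan(counts_to_tags([6]), genome)
        assert len(above) == 1

    def test_empty_chromosome(self):
        genome = GenomeIndex({"chr1": 5000})
        above, _ = window_scan(make_tags("chr1", []), genome)
        assert len(above) == 0


class TestMergeWindows:
    def test_single_gap_merged_with_gap_reads(self):
        genome = GenomeIndex({"chr1": 3000})
        above, counts = window_scan(counts_to_tags([7, 3, 8]), genome)
        groups = merge_windows(above, counts)
        assert len(groups) == 1
        assert groups.loc[0, "reads"] == 18  # 7 + 3 + 8, gap included
        assert (groups.loc[0, "start"], groups.loc[0, "end"]) == (0, 3000)

    def test_two_gap_windows_split(self):
        genome = GenomeIndex({"chr1": 4000})
        above, counts = window_scan(counts_to_tags([7, 1, 1, 8]), genome)
        groups = merge_windows(above, counts)
        assert len(groups) == 2

    def test_single_window_group(self):
        genome = GenomeIndex({"chr1": 1000})
        above, counts = window_scan(counts_to_tags([9]), genome)
        groups = merge_windows(above, counts)
        assert len(groups) == 1
        assert groups.loc[0, "reads"] == 9

    def test_exclude_gap_reads_flag(self):
        genome = GenomeIndex({"chr1": 3000})
        above, counts = window_scan(counts_to_tags([7, 3, 8]), genome)
        groups = merge_windows(above, counts, include_gap_reads=False)
        assert groups.loc[0, "reads"] == 15


class TestCallIslands:
    @pytest.mark.parametrize("reads,expected", [(75, 1), (60, 1), (59, 0)])
    def test_total_read_floor(self, reads, expected):
        groups = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [1000], "reads": [reads], "n_windows": [1]}
        )
        assert len(call_islands(groups, "K4me3")) == expected

    def test_gap_merge_worked_example(self):
        genome = GenomeIndex({"chr1": 3000})
        islands = call_islands_from_tags(counts_to_tags([40, 5, 30]), genome, "K4me3")
        assert len(islands) == 1
        assert islands.loc[0, "reads"] == 75
        assert islands.loc[0, "end"] - islands.loc[0, "start"] == 3000

    def test_matches_enumeration_oracle_on_random_chromosomes(self, rng):
        for _ in range(100):
            n_win = int(rng.integers(1, 50))
            counts = rng.integers(0, 15, size=n_win)
            # sprinkle high-count windows so some islands pass the 60-read floor
            hot = rng.random(n_win) < 0.15
            counts[hot] += rng.integers(40, 80, size=int(hot.sum()))
            genome = GenomeIndex({"chr1": n_win * 1000})
            islands = call_islands_from_tags(counts_to_tags(counts), genome, "K4me3")
            got = [
                (int(r.start), int(r.end), int(r.reads)) for r in islands.itertuples()
            ]
            assert got == oracle_islands(counts)


class TestClassifyDomains:
    @staticmethod
    def _islands(rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "reads"])

    def test_bivalency_worked_example(self):
        k4 = self._islands([("chr1", 0, 3000, 100)])
        k27 = self._islands([("chr1", 1000, 4000, 100)])
        domains = classify_domains(k4, k27)
        assert len(domains) == 1
        rec = domains.iloc[0]
        assert rec["state"] == "bivalent"
        assert (rec["start"], rec["end"]) == (0, 4000)

    def test_isolated_k4_is_active(self):
        domains = classify_domains(
            self._islands([("chr1", 0, 3000, 80)]), self._islands([])
        )
        assert list(domains["state"]) == ["active"]

    def test_identical_islands_bivalent(self):
        k4 = self._islands([("chr1", 0, 2000, 70)])
        k27 = self._islands([("chr1", 0, 2000, 90)])
        domains = classify_domains(k4, k27)
        assert list(domains["state"]) == ["bivalent"]

    def test_partial_overlap_keeps_own_mark_flagged(self):
        k4 = self._islands([("chr1", 0, 10_000, 100)])
        k27 = self._islands([("chr1", 9_000, 12_000, 100)])  # 1000/3000 = 0.33
        domains = classify_domains(k4, k27)
        assert set(domains["state"]) == {"active", "repressive"}
        assert domains["ambiguous"].all()

    def test_states_partition_domains(self, rng):
        k4 = self._islands(
            [("chr1", int(s), int(s) + 2000, 80) for s in rng.integers(0, 90_000, 10) * 10]
        )
        k27 = self._islands(
            [("chr1", int(s), int(s) + 2000, 80) for s in rng.integers(0, 90_000, 10) * 10]
        )
        domains = classify_domains(k4, k27)
        assert set(domains["state"]) <= {"active", "repressive", "bivalent"}


class TestDomainTransitions:
    @staticmethod
    def _domains(rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])

    def test_identical_sets_identity_matrix(self):
        d = self._domains(
            [("chr1", 0, 2000, "active"), ("chr1", 5000, 8000, "repressive"),
             ("chr1", 10_000, 14_000, "bivalent")]
        )
        m = domain_transitions(d, d)
        for state in ("active", "repressive", "bivalent"):
            assert m.loc[state, state] == 1.0

    def test_no_overlap_goes_to_none(self):
        ref = self._domains([("chr1", 0, 2000, "bivalent")])
        tgt = self._domains([("chr1", 50_000, 52_000, "active")])
        m = domain_transitions(ref, tgt)
        assert m.loc["bivalent", "none"] == 1.0

    def test_fraction_worked_example(self):
        # 10 repressive reference domains, 2 still repressive in the target
        ref = self._domains([("chr1", i * 10_000, i * 10_000 + 2000, "repressive")
                             for i in range(10)])
        tgt = self._domains(
            [("chr1", 0, 2000, "repressive"), ("chr1", 10_000, 12_000, "repressive")]
            + [("chr1", i * 10_000, i * 10_000 + 2000, "active") for i in range(2, 10)]
        )
        m = domain_transitions(ref, tgt)
        assert m.loc["repressive", "repressive"] == pytest.approx(0.2)
        assert m.loc["repressive", "active"] == pytest.approx(0.8)

    def test_rows_sum_to_one(self):
        ref = self._domains([("chr1", 0, 2000, "active"), ("chr1", 9000, 9500, "bivalent")])
        tgt = self._domains([("chr1", 500, 2500, "repressive")])
        m = domain_transitions(ref, tgt)
        present = m.sum(axis=1) > 0
        assert np.allclose(m[present.to_numpy()].sum(axis=1), 1.0)

    def test_common_domain_counts_symmetric(self, rng):
        """With the min-size denominator, common-domain pairs are symmetric."""
        def rand_domains(seed):
            r = np.random.default_rng(seed)
            starts = np.sort(r.choice(np.arange(100) * 3000, size=12, replace=False))
            lengths = r.integers(1000, 3000, size=12)
            return pd.DataFrame(
                {"chrom": "chr1", "start": starts, "end": starts + lengths,
                 "state": r.choice(["active", "repressive", "bivalent"], size=12)}
            )

        a, b = rand_domains(1), rand_domains(2)

        def common_pairs(x, y):
            n = 0
            for rx in x.itertuples():
                for ry in y.itertuples():
                    inter = min(rx.end, ry.end) - max(rx.start, ry.start)
                    if inter <= 0:
                        continue
                    if inter / min(rx.end - rx.start, ry.end - ry.start) >= 0.5:
                        n += 1
            return n

        assert common_pairs(a, b) == common_pairs(b, a)
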