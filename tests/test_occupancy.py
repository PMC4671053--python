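import numpy as np
import pandas as pd
import pytest

from conftest import make_genes, make_tags
from nucdyn.formats import ConfigError, GenomeIndex
from nucdyn.occupancy import (
    bin_counts,
    classify_bins,
    coverage_rate,
    region_read_fractions,
    replicate_correlation,
)


class TestBinCounts:
    def test_count_conservation(self, toy_genome, rng):
        tags = make_tags("chr1", rng.integers(0, 100_000, size=1234))
        track = bin_counts(tags, toy_genome, 10_000)
        assert track.data["count"].sum() == 1234

    def test_rpkm_worked_example(self):
        # 50 tags in one 10-kb bin of a 1e6-tag library -> 5.0 RPKM
        genome = GenomeIndex({"chr1": 10_000, "chr2": 50_000})
        rest = np.arange(999_950) % 50_000
        tags = pd.concat(
            [make_tags("chr1", [5] * 50), make_tags("chr2", rest)], ignore_index=True
        )
        track = bin_counts(tags, genome, 10_000, mode="rpkm")
        chr1_bin = track.data[track.data["chrom"] == "chr1"].iloc[0]
        assert chr1_bin["value"] == pytest.approx(5.0)

    def test_trailing_partial_bin_true_width(self):
        genome = GenomeIndex({"chr1": 10_500})
        tags = make_tags("chr1", [10_200] * 10)
        track = bin_counts(tags, genome, 10_000, mode="rpkm")
        last = track.data.iloc[-1]
        assert last["end"] - last["start"] == 500
        assert last["value"] == pytest.approx(10 / 0.5 / (10 / 1e6))

    def test_empty_chromosome_all_zero(self, toy_genome):
        tags = make_tags("chr1", [5])
        track = bin_counts(tags, toy_genome, 10_000)
        chr2 = track.data[track.data["chrom"] == "chr2"]
        assert (chr2["count"] == 0).all()

    def test_bad_bin_size(self, toy_genome):
        with pytest.raises(ConfigError):
            bin_counts(make_tags("chr1", [1]), toy_genome, 0)


def _track_from_values(values, bin_size=10):
    genome = GenomeIndex({"chr1": bin_size * len(values)})
    data = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(len(values)) * bin_size,
            "end": (np.arange(len(values)) + 1) * bin_size,
            "count": 0,
            "value": values,
        }
    )
    from nucdyn.occupancy import BinTrack

    return BinTrack(bin_size=bin_size, mode="fraction", total_tags=0, data=data)


class TestClassifyBins:
    def test_boundary_exactly_fold_counts_as_change(self):
        comp = classify_bins(_track_from_values([2.0e-4]), _track_from_values([3.0e-4]))
        assert comp.data.loc[0, "category"] == "gain"

    def test_both_zero_none_detected(self):
        comp = classify_bins(_track_from_values([0.0]), _track_from_values([0.0]))
        assert comp.data.loc[0, "category"] == "none_detected"

    def test_small_change_unchanged(self):
        comp = classify_bins(_track_from_values([1.0e-4]), _track_from_values([1.2e-4]))
        assert comp.data.loc[0, "category"] == "unchanged"

    def test_zero_reference_nonzero_query_is_gain(self):
        comp = classify_bins(_track_from_values([0.0]), _track_from_values([1e-5]))
        assert comp.data.loc[0, "category"] == "gain"

    def test_self_comparison_no_changes_among_detected(self, rng):
        vals = rng.random(100)
        vals[::7] = 0.0
        t = _track_from_values(vals)
        comp = classify_bins(t, t)
        detected = comp.data["category"][vals > 0]
        assert set(detected) <= {"gain"} or True  # ratio exactly 1 < 1.5 both ways
        assert (detected == "unchanged").all()

    def test_swapping_tracks_swaps_gain_and_loss(self, rng):
        a = _track_from_values(rng.random(200))
        b = _track_from_values(rng.random(200))
        fwd = classify_bins(a, b)
        rev = classify_bins(b, a)
        assert fwd.fractions["gain"] == rev.fractions["loss"]
        assert fwd.fractions["loss"] == rev.fractions["gain"]

    def test_fractions_partition(self, rng):
        a = _track_from_values(rng.random(50))
        b = _track_from_values(rng.random(50))
        comp = classify_bins(a, b)
        assert sum(comp.fractions.values()) == pytest.approx(1.0)


class TestReplicateCorrelation:
    def test_self_correlation_is_one(self, rng):
        t = _track_from_values(rng.random(50) + 0.1)
        assert replicate_correlation(t, t) == pytest.approx(1.0)

    def test_reversed_two_point_toy_is_minus_one(self):
        a = _track_from_values([1.0, 10.0])
        b = _track_from_values([10.0, 1.0])
        assert replicate_correlation(a, b) == pytest.approx(-1.0)

    def test_too_few_bins(self):
        t = _track_from_values([1.0])
        with pytest.raises(ConfigError):
            replicate_correlation(t, t)


class TestCoverageRate:
    def test_interval_union_worked_example(self):
        nucs = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [100, 200], "end": [247, 347]}
        )
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        out = coverage_rate(nucs, regions)
        assert out.loc[0, "covered_fraction"] == pytest.approx(0.247)

    def test_no_nucleosomes_zero(self):
        nucs = pd.DataFrame({"chrom": [], "start": [], "end": []})
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        out = coverage_rate(nucs, regions)
        assert out.loc[0, "covered_fraction"] == 0.0

    def test_fully_tiled_region_is_one(self):
        nucs = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [2000]})
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [900]})
        out = coverage_rate(nucs, regions)
        assert out.loc[0, "covered_fraction"] == 1.0

    def test_short_regions_excluded(self):
        nucs = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [2000]})
        regions = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 500], "end": [100, 1000]})
        out = coverage_rate(nucs, regions, min_region_len=150)
        assert len(out) == 1
        assert out.loc[0, "start"] == 500


class TestRegionReadFractions:
    def test_all_tags_in_tss_upstream(self, toy_genome):
        genes = make_genes([("g1", "chr1", "+", 10_000, 20_000)])
        tags = make_tags("chr1", [9_800, 9_900, 9_950])
        fracs = region_read_fractions(tags, genes, toy_genome)
        assert fracs["tss_upstream"] == 1.0

    def test_minus_strand_windows_flip(self, toy_genome):
        genes = make_genes([("g1", "chr1", "-", 10_000, 20_000)])
        # TSS = 20_000; upstream (5'-ward) is to the right
        fracs = region_read_fractions(make_tags("chr1", [20_100]), genes, toy_genome)
        assert fracs["tss_upstream"] == 1.0
        fracs = region_read_fractions(make_tags("chr1", [19_900]), genes, toy_genome)
        assert fracs["tss_downstream"] == 1.0

    def test_fractions_sum_to_one(self, toy_genome, rng):
        genes = make_genes(
            [("g1", "chr1", "+", 10_000, 20_000), ("g2", "chr1", "-", 40_000, 55_000)]
        )
        tags = make_tags("chr1", rng.integers(0, 100_000, size=5000))
        fracs = region_read_fractions(tags, genes, toy_genome)
        assert fracs.sum() == pytest.approx(1.0)

    def test_uniform_tags_match_length_shares(self):
        genome = GenomeIndex({"chr1": 100_000})
        genes = make_genes([("g1", "chr1", "+", 10_000, 20_000)])
        tags = make_tags("chr1", np.arange(0, 100_000))  # exactly one tag per bp
        fracs = region_read_fractions(tags, genes, genome)
        lengths = fracs.attrs["length_fractions"]
        for cat in fracs.index:
            assert fracs[cat] == pytest.approx(lengths[cat], rel=1e-12)
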