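import numpy as np
import pandas as pd
import pytest

from nucdyn.formats import ConfigError
from nucdyn.preprocess import shift_to_dyad
from nucdyn.simulate import (
    ConditionParams,
    SimConfig,
    default_cluster_spec,
    default_condition_params,
    simulate_expression,
    simulate_genome,
    simulate_nucleosome_map,
    simulate_reads,
)

CFG = SimConfig(seed=11, n_chroms=1, chrom_length=300_000, n_genes=15)


@pytest.fixture
def small_world():
    genome, genes, cpg = simulate_genome(CFG)
    return genome, genes, cpg


class TestSimulateGenome:
    def test_deterministic_under_seed(self):
        g1, genes1, cpg1 = simulate_genome(CFG)
        g2, genes2, cpg2 = simulate_genome(CFG)
        assert g1.chrom_sizes == g2.chrom_sizes
        pd.testing.assert_frame_equal(genes1, genes2)
        pd.testing.assert_frame_equal(cpg1, cpg2)

    def test_genes_non_overlapping(self, small_world):
        _, genes, _ = small_world
        g = genes.sort_values("start")
        assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()

    def test_hcg_fraction_one_every_promoter_overlaps(self):
        cfg = SimConfig(seed=3, n_chroms=1, chrom_length=300_000, n_genes=10, hcg_fraction=1.0)
        genome, genes, cpg = simulate_genome(cfg)
        from nucdyn.promoters import classify_cpg, promoter_intervals

        classes = classify_cpg(promoter_intervals(genes, genome), cpg)
        assert (classes == "HCG").all()

    def test_no_genes_valid_genome(self):
        cfg = SimConfig(seed=1, n_chroms=1, chrom_length=300_000, n_genes=0)
        genome, genes, cpg = simulate_genome(cfg)
        assert len(genes) == 0
        assert len(cpg) == 0
        assert genome["chr1"] == 300_000

    def test_impossible_placement_raises(self):
        cfg = SimConfig(seed=1, n_chroms=1, chrom_length=80_000, n_genes=12,
                        gene_length_range=(6000, 8000))
        with pytest.raises(ConfigError, match="longer chromosome"):
            simulate_genome(cfg)


class TestNucleosomeMap:
    def test_ndr_depletion_strand_aware(self, small_world):
        genome, genes, _ = small_world
        active = frozenset(genes["gene_id"])
        params = {"A": ConditionParams(depleted_genes=active)}
        nucs = simulate_nucleosome_map(genome, genes, params, CFG)["A"]
        for rec in genes.itertuples(index=False):
            d = nucs.loc[nucs["chrom"] == rec.chrom, "dyad"].to_numpy()
            rel = d - rec.tss if rec.strand == "+" else (rec.tss - 1) - d
            assert not ((rel >= -150) & (rel <= 50)).any()

    def test_intergenic_multiplier_scales_mean_weight(self, small_world):
        genome, genes, _ = small_world
        params = {
            "A": ConditionParams(intergenic_multiplier=1.0),
            "B": ConditionParams(intergenic_multiplier=0.5),
        }
        maps = simulate_nucleosome_map(genome, genes, params, CFG)
        inter_a = maps["A"].loc[maps["A"]["region"] == "intergenic", "occupancy_weight"]
        inter_b = maps["B"].loc[maps["B"]["region"] == "intergenic", "occupancy_weight"]
        assert inter_b.mean() / inter_a.mean() == pytest.approx(0.5, rel=1e-9)

    def test_shared_lattice_across_conditions(self, small_world):
        genome, genes, _ = small_world
        params = {"A": ConditionParams(), "B": ConditionParams(fuzziness_sd=10.0)}
        maps = simulate_nucleosome_map(genome, genes, params, CFG)
        np.testing.assert_array_equal(maps["A"]["dyad"], maps["B"]["dyad"])

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ConfigError):
            ConditionParams(intergenic_multiplier=-1.0)

    def test_mark_labels_follow_gene_sets(self, small_world):
        genome, genes, _ = small_world
        k4 = frozenset(genes["gene_id"][:5])
        params = {"A": ConditionParams(k4_genes=k4)}
        nucs = simulate_nucleosome_map(genome, genes, params, CFG)["A"]
        assert nucs["H3"].all()
        assert set(nucs.loc[nucs["K4me3"], "gene_id"]) <= k4


class TestSimulateReads:
    @pytest.fixture
    def flat_map(self, small_world):
        genome, genes, _ = small_world
        params = {"A": ConditionParams(fuzziness_sd=0.0)}
        return genome, simulate_nucleosome_map(genome, genes, params, CFG)["A"]

    def test_zero_fuzziness_shift_recovers_dyads_exactly(self, flat_map, rng):
        genome, nucs = flat_map
        reads = simulate_reads(nucs, genome, mean_tags_per_weight=5, rng=rng)
        tags = shift_to_dyad(reads, genome)
        assert len(tags) == len(reads)
        np.testing.assert_array_equal(tags["pos"].to_numpy(), reads["true_dyad"].to_numpy())
        # zero SD: every read of one nucleosome shares the planted dyad
        planted = nucs["dyad"].to_numpy()[reads["nuc_index"].to_numpy()]
        np.testing.assert_array_equal(reads["true_dyad"].to_numpy(), planted)

    def test_empirical_sd_matches_planted_fuzziness(self, small_world):
        genome, genes, _ = small_world
        params = {"A": ConditionParams(fuzziness_sd=8.0)}
        nucs = simulate_nucleosome_map(genome, genes, params, CFG)["A"].iloc[:1]
        reads = simulate_reads(nucs, genome, mean_tags_per_weight=2000 / nucs["occupancy_weight"].iloc[0],
                               seed=99)
        tags = shift_to_dyad(reads, genome)
        sd = np.std(tags["pos"].to_numpy() - nucs["dyad"].iloc[0])
        assert sd == pytest.approx(8.0, abs=0.5)

    def test_duplicate_rate_zero_adds_nothing(self, flat_map, rng):
        genome, nucs = flat_map
        r0 = simulate_reads(nucs, genome, duplicate_rate=0.0, seed=5)
        r1 = simulate_reads(nucs, genome, duplicate_rate=0.0, seed=5)
        pd.testing.assert_frame_equal(r0, r1)

    def test_duplicates_are_copies_of_existing_reads(self, flat_map):
        genome, nucs = flat_map
        plain = simulate_reads(nucs, genome, duplicate_rate=0.0, seed=5)
        duped = simulate_reads(nucs, genome, duplicate_rate=0.3, seed=5)
        assert len(duped) > len(plain)
        extra = duped.iloc[len(plain):]
        merged = extra.merge(plain, on=["chrom", "start", "end", "strand"], how="left",
                             indicator=True)
        assert (merged["_merge"] == "both").all()

    def test_mark_reads_only_from_labeled_nucleosomes(self, small_world, rng):
        genome, genes, _ = small_world
        k4 = frozenset(genes["gene_id"][:3])
        params = {"A": ConditionParams(k4_genes=k4)}
        nucs = simulate_nucleosome_map(genome, genes, params, CFG)["A"]
        reads = simulate_reads(nucs, genome, mark="K4me3", rng=rng)
        assert nucs.loc[reads["nuc_index"].unique(), "K4me3"].all()


class TestSimulateExpression:
    def test_planted_non_de_fails_filter_everywhere(self, rng):
        genes = pd.DataFrame({"gene_id": [f"g{i}" for i in range(300)]})
        table = simulate_expression(genes, default_cluster_spec(10), rng=rng)
        from nucdyn.expression import de_genes

        de_ids = set(de_genes(table)["gene_id"])
        null_ids = set(table.loc[table["planted_cluster"] == "null", "gene_id"])
        assert not (de_ids & null_ids)

    def test_total_de_is_sum_of_cluster_counts(self, rng):
        genes = pd.DataFrame({"gene_id": [f"g{i}" for i in range(200)]})
        spec = default_cluster_spec(12)
        table = simulate_expression(genes, spec, rng=rng)
        n_planted = (table["planted_cluster"] != "null").sum()
        assert n_planted == sum(s.n_genes for s in spec.values())

    def test_monotone_down_archetype(self, rng):
        genes = pd.DataFrame({"gene_id": [f"g{i}" for i in range(100)]})
        table = simulate_expression(genes, default_cluster_spec(5), noise_sd=0.01, rng=rng)
        c1 = table[table["planted_cluster"] == "C1"]
        f = c1[["fpkm_MEF", "fpkm_preiPSC", "fpkm_iPSC"]].to_numpy()
        assert ((f[:, 0] > f[:, 1]) & (f[:, 1] > f[:, 2])).all()

    def test_zero_fold_cluster_spec_rejected(self, rng):
        from nucdyn.simulate import ClusterSpec

        genes = pd.DataFrame({"gene_id": [f"g{i}" for i in range(50)]})
        with pytest.raises(ConfigError, match="fold"):
            simulate_expression(genes, {"C1": ClusterSpec(5, (3.0, 3.0, 3.0))}, rng=rng)

    def test_default_condition_params_encode_study_conditions(self):
        params = default_condition_params()
        assert params["preiPSC"].fuzziness_sd < params["MEF"].fuzziness_sd
        assert params["preiPSC"].intergenic_multiplier < params["MEF"].intergenic_multiplier
        assert params["iPSC"].fuzziness_sd == 32.0
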