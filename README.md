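# nucdyn

Nucleosome positioning, fuzziness and chromatin-state dynamics for
MNase/ChIP-seq time courses.

When somatic cells are reprogrammed to pluripotency (mouse embryonic
fibroblasts → partially reprogrammed pre-iPSCs → iPSCs), the chromatin
landscape is rebuilt: nucleosome occupancy shifts between genic and
intergenic space, nucleosomes become more or less sharply positioned, and
H3K4me3/H3K27me3 domains and promoter states turn over together with gene
expression. `nucdyn` packages that whole analysis as a tested, reusable
Python library and CLI for anyone with aligned MNase-ChIP-seq tags
(H3, H3K4me3, H3K27me3, H3K9me3), a gene annotation, a CpG-island file and
an FPKM/q-value expression table — or with nothing at all, because a
ground-truthed synthetic-data generator is included and drives the entire
test suite.

## What it computes

* **Dyad tags** — each aligned tag shifted 73 bp 3′-ward to the nucleosome
  dyad, and a duplicate cap `D = min{D : Σ min(mᵢ, D) ≥ 0.99 Σ mᵢ}` over
  per-(position, strand) multiplicities mᵢ.
* **Occupancy change per 10-kb bin** — with depth-normalized values a, b:
  *gain* if b ≥ 1.5a, *loss* if a ≥ 1.5b, *none detected* if a = b = 0,
  else *unchanged*; plus 100-kb log₁₀-RPKM Pearson replicate correlation,
  nucleosome coverage rates and genome-region tag fractions.
* **Nucleosome calls** — Gaussian-smoothed tag density (σ = 20 bp), greedy
  peak selection with a 147-bp exclusion zone; per-nucleosome **fuzziness**
  = √(mean((pos − dyad)²)), the RMS spread of a nucleosome's tags about its
  dyad; one-to-one matching of common nucleosomes (< 73 bp apart) between
  samples with a paired t-test on fuzziness.
* **TSS metaprofiles and heatmaps** — strand-aware ±2-kb profiles in 10-bp
  bins with 5-bin moving-average smoothing; per-gene occupancy matrices
  over −500..+1500 with reusable row ordering; K-means profile clusters.
* **Chromatin domains** — H3K4me3/H3K27me3 islands (1-kb windows, ≥6 reads,
  one-gap merging, ≥60 reads total), classified into active / repressive /
  bivalent (≥50% overlap of the smaller island) with transition matrices
  across conditions.
* **Promoter states** — TSS±500 promoters classed HCG/LCG by CpG-island
  overlap, with the four-state K4 / K27 / K4K27 / None rule (strictly
  > 1 RPKM per mark), state-transition matrices and expression coupling.
* **Differential expression** — fold ≥ 2 (pseudocount 1) and q < 0.05 in
  any pairwise comparison; six-cluster temporal K-means on z-scored
  log₂(FPKM+1) with canonical C1..C6 naming; condition correlation
  matrices.

See `docs/methods.md` for the full model description, parameter defaults
and limitations.

## Worked example

Simulate a three-condition dataset with the default study conditions
(pre-iPS chromatin loses intergenic nucleosomes and is better phased), then
run the core comparisons:

```python
from nucdyn.simulate import (SimConfig, default_condition_params,
                             simulate_genome, simulate_nucleosome_map,
                             simulate_reads)
from nucdyn.preprocess import shift_to_dyad, cap_duplicates
from nucdyn.positioning import call_nucleosomes, match_common, compare_fuzziness
from nucdyn.occupancy import bin_counts, classify_bins

cfg = SimConfig(seed=7, n_chroms=2, chrom_length=1_000_000, n_genes=100)
rng = cfg.rng()
genome, genes, cpg = simulate_genome(cfg, rng)
maps = simulate_nucleosome_map(genome, genes, default_condition_params(), cfg, rng)

tags = {}
for cond in cfg.conditions:
    reads = simulate_reads(maps[cond], genome, mean_tags_per_weight=8.0,
                           duplicate_rate=0.02, rng=rng)
    t, cap = cap_duplicates(shift_to_dyad(reads, genome), retention=0.99)
    tags[cond] = t
    print(f"{cond}: {cap.total} tags, cap {cap.cap}, retained {cap.retained}")

comp = classify_bins(bin_counts(tags["MEF"], genome, 10_000),
                     bin_counts(tags["preiPSC"], genome, 10_000))
print("MEF -> pre-iPSC bin fractions:",
      {k: round(v, 3) for k, v in comp.fractions.items()})

calls = {c: call_nucleosomes(tags[c], genome) for c in ("MEF", "preiPSC")}
res = compare_fuzziness(match_common(calls["MEF"], calls["preiPSC"]))
print(f"common nucleosomes: {res.n_pairs}; mean fuzziness "
      f"MEF {res.mean_a:.1f} bp vs pre-iPSC {res.mean_b:.1f} bp "
      f"(paired t = {res.t_statistic:.1f}, p = {res.p_value:.2g})")
```

Output:

```
MEF: 86788 tags, cap 2, retained 86664
preiPSC: 57860 tags, cap 2, retained 57779
iPSC: 71376 tags, cap 2, retained 71294
MEF -> pre-iPSC bin fractions: {'gain': 0.01, 'loss': 0.025, 'none_detected': 0.0, 'unchanged': 0.965}
common nucleosomes: 7251; mean fuzziness MEF 26.7 bp vs pre-iPSC 22.6 bp (paired t = -32.3, p = 1.3e-213)
```

Reading the numbers: the duplicate cap of 2 retains ≥99% of tags in every
library; pre-iPSC tag totals drop because intergenic occupancy is halved,
and the bins that change are mostly losses; matched nucleosomes are clearly
better phased in pre-iPSCs (lower fuzziness, strongly significant paired
t-test). At this modest depth (~8 tags per nucleosome) the windowed
fuzziness estimates sit below the planted spreads of 31/26 bp — the
truncation bias discussed in `docs/methods.md` — while the between-condition
ordering is recovered cleanly; the deeper simulations in the acceptance
script recover the planted values to within 0.1 bp.

The same workflow is available from the shell:

```bash
nucdyn demo --seed 7 --out demo_run      # simulate + full pipeline + summary JSON
nucdyn simulate --seed 1 --out data      # just write a synthetic dataset
nucdyn preprocess --reads data/reads_MEF_H3.bed --genome data/genome.sizes --out tags.bed
nucdyn positions call --tags tags.bed --genome data/genome.sizes --out calls.bed
nucdyn run-all --config data/config.yaml --out results
```

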