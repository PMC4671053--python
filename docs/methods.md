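# Methods

`nucdyn` reimplements, as a tested library, a standard MNase/ChIP-seq
analysis of nucleosome dynamics across cell-state transitions (fibroblast →
partially reprogrammed intermediate → induced pluripotent stem cell, called
MEF / pre-iPSC / iPSC throughout). This note records the models, the
parameters that matter, the synthetic-data generator's assumptions, and the
numerical choices made where the design was genuinely open.

## Dyad inference and duplicate capping

Single-end tags mark one edge of a nucleosome-protected ~147-bp fragment.
Each tag is shifted **73 bp** (half a nucleosome) in its 3′ direction to the
inferred dyad: plus-strand tags move their 5′ end (`start`) right; for
minus-strand tags the 5′ end is `end − 1` and moves left. This is the only
reading of "3′-ward by half a nucleosome" under which a simulated read built
from a known dyad round-trips exactly, and the round-trip is asserted in the
tests.

PCR duplicates are not removed outright. Instead the per-(coordinate,
strand) multiplicity is capped at the smallest integer *D* such that
`Σ min(multiplicity, D) ≥ retention × total`, with retention defaulting to
**0.99** — keep at least 99% of uniquely aligned tags. The cap is computed
per library (marks and conditions have library-specific PCR behaviour) and
is verified against an exhaustive search over all candidate caps. Within a
capped group the first-encountered tags are kept, making the operation
deterministic. Because the dyad shift is a strand-wise bijection, duplicate
groups are identical before and after shifting, so capping is applied to
shifted tags.

## Binned occupancy comparison

Tag counts are binned (default **10 kb**) and divided by library size; two
samples are compared bin by bin with a symmetric **1.5-fold** rule: query ≥
1.5× reference → *gain*; reference ≥ 1.5× query → *loss*; both zero →
*none detected*; else *unchanged*. A zero denominator with a nonzero
numerator counts as a change (the four categories must partition all bins).
A ratio of exactly 1.5 counts as changed; the comparison carries a 1e-9
relative tolerance so the boundary is not lost to floating-point noise.
Replicate consistency uses **100-kb** bins, RPKM normalization (partial
trailing bins keep their true width), and Pearson correlation of
log10(RPKM + 0.01); the 0.01 pseudocount keeps empty bins finite.

Region statistics: the nucleosome coverage rate of a region is the length
of the union of call footprints (dyad ± 73 bp) inside it divided by its
length, for regions ≥ 150 bp. Tag fractions are reported over six
strand-aware categories that partition the genome with precedence
TSS windows (−300/+600) > TTS windows (±300) > remaining genic >
intergenic; "genic" is the full TSS–TTS span (no exon resolution).

## Nucleosome calling and fuzziness

Dyad tags are convolved with a Gaussian kernel (**σ = 20 bp**, truncated at
4σ). Candidate dyads are the positive local maxima of the smoothed signal;
they are accepted greedily by descending signal (ties to the lower
coordinate), and each accepted dyad suppresses all candidates closer than
the **exclusion zone of 147 bp** (one footprint), so accepted dyads are
always ≥ 147 bp apart. Tags are then assigned to the nearest accepted dyad
within 73 bp, and calls with fewer than **3** tags are dropped. σ and the
exclusion width are exposed because different MNase depths favour different
smoothing; the defaults reflect common nucleosome-calling practice. The
greedy selection is tested against an independent O(n²) enumeration oracle
on random toy chromosomes.

**Fuzziness** is the RMS deviation of a nucleosome's assigned tag positions
about its dyad — low fuzziness means a well-phased nucleosome. It is
computed about the called dyad, which coincides with the standard deviation
when the dyad equals the tag mean. One estimation caveat is deliberate:
when tags are assigned through the ±73-bp window, a nucleosome with true
spread ≳ 26 bp has its tails truncated and RMS biased low by several
percent. The simulation-based estimator checks therefore group tags by
their true nucleosome and re-estimate the dyad as the rounded tag mean
(`max_assign_dist=None` exposes the same unbounded assignment in the
caller); the windowed assignment remains the default for real data, where
truth grouping does not exist.

Common nucleosomes between two samples are matched greedily one-to-one by
increasing dyad distance, keeping pairs with distance **strictly < 73 bp**;
paired fuzziness is compared with a two-tailed paired t-test.

## TSS profiles, heatmaps and clustering

Metaprofiles count dyad tags by distance from each TSS (window ±2 kb,
**10-bp** bins), strand-aware so positive distances always point
downstream. Counts summed over genes are converted to RPKM and divided by
the number of anchor TSSs — a per-gene average, so groups of different size
(the **top 5%** expressed, *silent* genes below **0.5 FPKM**, and the rest)
are directly comparable. Profiles are smoothed with a centered 5-bin moving
average whose window shrinks at the edges (no padding), which preserves the
interior mean. Heatmap rows paint each call over dyad ± fuzziness in a
−500/+1500 window, ranked by a per-gene scalar (typically H3K4me3 RPKM at
−300..+600); the row order is exported so other conditions can be displayed
in the identical order. Per-gene profiles over −300..+600 are clustered
with K-means (**k = 4**, k-means++, 50 restarts, fixed seed), and labels
are renumbered by descending cluster mean occupancy for stable reporting.

## Histone-mark islands and chromatin domains

Islands are called SICER-style: **1-kb** windows, keep windows with ≥ **6**
reads, group consecutive kept windows tolerating a **single** sub-threshold
gap window, and keep groups with ≥ **60** reads. Gap-window reads lie
inside the merged span and count toward the total (a flag excludes them).
The full pipeline is tested against a brute-force regex enumeration of all
valid gap-tolerant groupings, including both boundary values.

H3K4me3/H3K27me3 island pairs overlapping by ≥ **50% of the smaller
island** (the symmetric denominator; the threshold's denominator is not
uniquely determined by the 50%-overlap phrasing) merge into one *bivalent*
domain over the union interval, consuming both islands. Islands with no
cross-mark overlap are *active* (K4) or *repressive* (K27). Islands with a
partial (0 < overlap < 50%) cross-mark overlap keep their own mark's state
but are flagged `ambiguous` — a strict "no overlap" reading would leave
them stateless, which discards information. Domain fates across conditions
assign each reference domain the state of the target domain covering ≥ 50%
of the *reference* length (highest overlap wins, ties to the lower
coordinate), else "none"; rows of the transition matrix sum to 1.

## Promoter states and expression coupling

A promoter is TSS ± **500 bp**. Any ≥ 1-bp overlap with a CpG island makes
it HCG, else LCG (CpG islands are a file input; island prediction is out of
scope). Mark levels are dyad-tag RPKM over the 1-kb window; the state rule
is strict: K4 and/or K27 require the level to be **strictly above 1 RPKM**,
so exactly 1.0 is "None". State-transition matrices are reported per CpG
class with empty starting states omitted. Expression coupling groups genes
that start in a given state by their target state and compares
log2(FPKM + 1) between groups with two-tailed t-tests (groups smaller than
two are reported without a test). With several transcripts per gene each
TSS is a row; gene-level summaries take the TSS with the highest reference
K4 signal.

## Differential expression

A gene is DE when any pairwise comparison shows fold ≥ **2** and q <
**0.05**. Fold is (max + 1)/(min + 1) on FPKM — the pseudocount avoids
division by zero and makes the filter symmetric in condition order.
q-values are consumed from the input table (the upstream quantifier's
statistics are not reimplemented). DE trajectories — log2(FPKM + 1) per
condition, z-scored per gene (zero-variance rows centered only; z-scoring
makes the clustering shape-based rather than level-based, disable with
`zscore=False`) — are clustered with K-means (**k = 6**, 50 restarts,
seeded). Cluster names are canonical: C1 = most-decreasing slope, C3 =
most-increasing, C4 = strongest transient-up (highest interior mean), C6 =
strongest transient-down, and the remaining two become C2/C5 by ascending
slope. This makes C1..C6 reproducible across seeds and matches the six
temporal patterns the analysis expects (down, early-down, up, up-then-down,
late-up, down-then-up).

## The synthetic-data generator

The generator produces the structures the analyses assume, with full
determinism from one seeded generator:

* **Genome**: configurable chromosomes; genes placed one per slot of an
  even partition (guaranteeing non-overlap); a configurable fraction of
  promoters (default 0.6) receives an overlapping CpG island.
* **Nucleosome map**: a lattice with spacing = nucleosome size + linker
  (147 + 53 = 200 bp) and ±10-bp jitter, shared across conditions so
  nucleosomes can be matched between them. Occupancy weights carry broad
  regional variation (lognormal, σ = 0.4, 20-kb blocks, shared across
  conditions) — this is what makes 100-kb bins heterogeneous enough for a
  meaningful replicate correlation — times per-condition genic/intergenic
  multipliers. Active genes get a nucleosome-depleted region at
  [−150, +50] around the TSS and a phased −1..+4 array (dyads near −223,
  +123, +323, +523, +723). Histone marks label nucleosomes near the TSSs of
  designated gene sets (H3 labels everything).
* **Condition defaults encode the study conditions**: pre-iPS chromatin
  loses intergenic nucleosomes (multiplier 0.5 vs MEF, 0.75 in iPSC, with
  a mild genic gain) and is better phased — per-condition fuzziness
  defaults are 31 bp (MEF), 26 bp (pre-iPSC) and 32 bp (iPSC).
* **Reads**: per nucleosome, tag count ~ Poisson(weight × depth scale) —
  the simplest shot-noise model; tag dyads ~ Normal(dyad, fuzziness SD)
  rounded to integers, strand fair-coin, and the read laid out so the 73-bp
  shift recovers the sampled dyad exactly. Tags whose footprint cannot fit
  on the chromosome are resampled (bounded retries, then dropped). PCR
  duplicates resample existing reads with a given probability. Mark reads
  come only from mark-labeled nucleosomes.
* **Expression**: six planted temporal archetypes (50 genes each in the
  recovery checks) with multiplicative log-normal noise (σ = 0.1 log2
  units); q-values are drawn below 0.05 exactly in comparisons where the
  planted fold reaches 2, so the DE filter recovers the planted set
  exactly; null genes get flat trajectories and non-significant q-values.

What the generator does **not** emulate: sequence content and mappability,
MNase sequence bias, fragment-length variation, chromatin heterogeneity
between cells, and realistic mark breadth (marks are promoter-anchored
boxes). Passing recovery tests therefore demonstrates the correctness of
the analysis logic under the stated statistical assumptions, not robustness
to the full messiness of real libraries.

## Problem sizes in the standard checks

The bundled recovery checks are sized for a desk run, chosen as the
smallest scales at which the planted effects are statistically unambiguous:
dyad round-trip on ~1.1 × 10⁵ reads; bin-classifier recovery on a 3-Mb
genome at ≈800 tags per intergenic 10-kb bin (gene-dense chromosomes,
~50% genic bp at 2.2× genic occupancy — with library-size normalization a
mostly-intergenic genome would push unchanged genic bins past the 1.5-fold
threshold, so genome composition is part of the planted scenario); fuzziness
recovery on 500 nucleosomes × 1000 tags per condition; caller
recall/precision on 500 well-separated nucleosomes at ~80 tags each; 500
random ≤50-window chromosomes for the island oracle; 400-gene expression
tables; and two 10⁶-tag replicates for the 100-kb correlation. The whole
suite runs in well under a minute on one core.

## Known limitations

* The greedy caller is not a global optimizer; on adversarial signal
  landscapes a non-greedy exclusion-respecting selection could score higher
  total signal. It matches standard practice and the enumeration oracle for
  the greedy rule.
* Fuzziness from windowed assignment is biased low for very fuzzy
  nucleosomes (see above).
* Island calling uses fixed windows with no local background model; very
  deep libraries would need a significance-based threshold instead of the
  fixed 6/60 read counts.
* The transition matrices are per-domain, not per-base; a long reference
  domain straddling two target domains contributes its single best overlap.
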