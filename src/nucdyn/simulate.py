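"""Ground-truthed synthetic genomes, nucleosome maps, reads and expression.

The generator emulates the statistical structure the downstream analyses
assume, for three cell states (MEF, pre-iPSC, iPSC by default):

* a toy genome with non-overlapping genes, a configurable fraction of whose
  promoters overlap a CpG island (these become HCG promoters);
* a shared base nucleosome lattice (spacing = nucleosome size + linker with
  jitter) whose per-nucleosome occupancy weights carry broad regional
  variation (lognormal, 20-kb blocks) shared across conditions, plus
  per-condition genic/intergenic multipliers and per-condition fuzziness;
  active genes get a nucleosome-depleted region [-150, +50] around the TSS
  with phased -1..+3 nucleosomes;
* single-end reads whose dyads are Normal(nucleosome dyad, fuzziness SD),
  emitted so that a 73-bp 3' shift recovers the sampled dyad exactly, with
  optional PCR-duplicate resampling; histone-mark reads are drawn only from
  nucleosomes carrying that mark;
* an FPKM + q-value expression table with DE genes planted in six temporal
  patterns that pass the fold>=2 & q<0.05 filter by construction.

All randomness flows from one seeded generator, so a fixed seed gives a
fully deterministic dataset.

Default condition parameters encode the study conditions: pre-iPS chromatin
is depleted of intergenic nucleosomes relative to MEFs (iPSCs intermediate)
and pre-iPS nucleosomes are better phased (fuzziness 26 bp vs 31 in MEFs
and 32 in iPSCs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import DEFAULT_CONDITIONS, fold_change, pairwise_comparisons, q_column
from .formats import ConfigError, GenomeIndex
from .preprocess import HALF_NUCLEOSOME

log = logging.getLogger(__name__)

MARKS = ("H3", "K4me3", "K27me3", "K9me3")

NUCLEOSOME_COLUMNS = [
    "chrom", "dyad", "fuzziness_sd", "occupancy_weight", "region", "gene_id",
    *MARKS,
]


@dataclass(frozen=True)
class SimConfig:
    """Global layout of the synthetic dataset."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 100
    read_length: int = 36
    nucleosome_size: int = 147
    linker: int = 53
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    hcg_fraction: float = 0.6
    gene_length_range: tuple[int, int] = (2000, 6000)
    regional_lognorm_sd: float = 0.4  # broad occupancy variation, 20-kb blocks
    regional_block: int = 20_000

    def __post_init__(self) -> None:
        if self.read_length >= self.nucleosome_size:
            raise ConfigError("read_length must be smaller than nucleosome_size")
        if self.n_genes and self.chrom_length < 10 * self.gene_length_range[1]:
            raise ConfigError("chrom_length must be at least 10x the maximum gene span")

    @property
    def spacing(self) -> int:
        return self.nucleosome_size + self.linker

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class ConditionParams:
    """Per-condition knobs of the nucleosome map."""

    intergenic_multiplier: float = 1.0
    genic_multiplier: float = 1.0
    fuzziness_sd: float = 30.0
    depleted_genes: frozenset[str] = frozenset()  # genes with a TSS NDR + phased array
    k4_genes: frozenset[str] = frozenset()
    k27_genes: frozenset[str] = frozenset()
    k9_intergenic: bool = False

    def __post_init__(self) -> None:
        if self.intergenic_multiplier < 0 or self.genic_multiplier < 0:
            raise ConfigError("occupancy multipliers must be non-negative")


def default_condition_params(
    active_genes: frozenset[str] = frozenset(),
    k4_genes: frozenset[str] = frozenset(),
    k27_genes: frozenset[str] = frozenset(),
) -> dict[str, ConditionParams]:
    """Study-condition defaults: intergenic loss and tighter phasing in
    pre-iPSCs, partial recovery in iPSCs."""
    base = dict(depleted_genes=active_genes, k4_genes=k4_genes, k27_genes=k27_genes)
    return {
        "MEF": ConditionParams(1.0, 1.0, 31.0, **base),
        "preiPSC": ConditionParams(0.5, 1.3, 26.0, **base),
        "iPSC": ConditionParams(0.75, 1.1, 32.0, **base),
    }


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenomeIndex, pd.DataFrame, pd.DataFrame]:
    """Toy genome: chromosomes, non-overlapping genes and CpG islands.

    Genes are placed one per slot of an even chromosome partition (with end
    margins), which guarantees non-overlap; a ``hcg_fraction`` of promoters
    receive an overlapping CpG island.
    """
    rng = config.rng() if rng is None else rng
    genome = GenomeIndex(
        {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    )
    margin = 5000
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    rows = []
    gi = 0
    for ci, (chrom, size) in enumerate(genome.items()):
        n = per_chrom[ci]
        if n == 0:
            continue
        slot = (size - 2 * margin) // n
        if slot < config.gene_length_range[1] + 2000:
            raise ConfigError(
                "genes cannot be placed without overlap; use a longer chromosome"
            )
        for j in range(n):
            length = int(rng.integers(*config.gene_length_range))
            lo = margin + j * slot + 1000
            hi = margin + (j + 1) * slot - 1000 - length
            start = int(rng.integers(lo, hi))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append(
                {
                    "gene_id": f"g{gi:04d}",
                    "chrom": chrom,
                    "strand": strand,
                    "start": start,
                    "end": start + length,
                }
            )
            gi += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end"])
    if len(genes):
        genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"])
        genes["tts"] = np.where(genes["strand"] == "+", genes["end"], genes["start"])
    else:
        genes["tss"] = pd.Series(dtype=np.int64)
        genes["tts"] = pd.Series(dtype=np.int64)

    n_hcg = int(round(config.hcg_fraction * len(genes)))
    hcg_idx = rng.choice(len(genes), size=n_hcg, replace=False) if n_hcg else np.array([], int)
    cpg_rows = []
    for i in sorted(hcg_idx):
        rec = genes.iloc[i]
        if rec["strand"] == "+":
            s, e = rec["tss"] - 200, rec["tss"] + 300
        else:
            s, e = rec["tss"] - 300, rec["tss"] + 200
        cpg_rows.append({"chrom": rec["chrom"], "start": int(max(s, 0)), "end": int(e)})
    cpg = pd.DataFrame(cpg_rows, columns=["chrom", "start", "end"])
    genes.attrs["hcg_gene_ids"] = list(genes["gene_id"].iloc[sorted(hcg_idx)]) if len(genes) else []
    return genome, genes, cpg


# ---------------------------------------------------------------------------
# nucleosome map
# ---------------------------------------------------------------------------

NDR_WINDOW = (-150, 50)  # relative to the TSS, depleted for active genes
PHASED_OFFSETS = (-223, 123, 323, 523, 723)  # -1 and +1..+4 nucleosome dyads
MARK_PROMOTER_SPAN = 1000  # marks label nucleosomes within TSS±span


def _rel_to_genomic(rel: np.ndarray, tss: int, strand: str) -> np.ndarray:
    return tss + rel if strand == "+" else (tss - 1) - rel


def simulate_nucleosome_map(
    genome: GenomeIndex,
    genes: pd.DataFrame,
    condition_params: dict[str, ConditionParams],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """True nucleosome maps per condition over a shared base lattice.

    The lattice (same dyads in every condition, so nucleosomes can be
    matched across conditions), the per-nucleosome base weights and the
    regional lognormal variation are drawn once; each condition then applies
    its genic/intergenic multipliers, fuzziness SD, TSS depletion for its
    active genes, and histone-mark labels around marked genes' TSSs.
    """
    rng = config.rng() if rng is None else rng
    genes_by_chrom = dict(iter(genes.groupby("chrom", sort=False))) if len(genes) else {}

    base = {}
    for chrom, size in genome.items():
        lattice = np.arange(config.spacing, size - config.spacing, config.spacing)
        jitter = rng.integers(-10, 11, size=lattice.size)
        dyads = lattice + jitter
        genic = np.zeros(dyads.size, dtype=bool)
        gene_id = np.full(dyads.size, "", dtype=object)
        g = genes_by_chrom.get(chrom)
        if g is not None:
            for rec in g.itertuples(index=False):
                inside = (dyads >= rec.start) & (dyads < rec.end)
                genic |= inside
                near_tss = np.abs(dyads - rec.tss) <= MARK_PROMOTER_SPAN
                gene_id[near_tss | inside] = rec.gene_id
        regional = np.exp(
            rng.normal(0.0, config.regional_lognorm_sd, size=size // config.regional_block + 1)
        )
        weight = regional[dyads // config.regional_block]
        base[chrom] = (dyads, genic, gene_id, weight)

    out = {}
    for condition, params in condition_params.items():
        frames = []
        for chrom, (dyads, genic, gene_id, weight) in base.items():
            dyads = dyads.copy()
            w = weight * np.where(genic, params.genic_multiplier, params.intergenic_multiplier)
            keep = np.ones(dyads.size, dtype=bool)
            extra_rows = []
            g = genes_by_chrom.get(chrom)
            if g is not None:
                for rec in g.itertuples(index=False):
                    if rec.gene_id not in params.depleted_genes:
                        continue
                    rel = np.where(
                        rec.strand == "+", dyads - rec.tss, (rec.tss - 1) - dyads
                    )
                    # clear the lattice across the NDR and the phased zone
                    keep &= ~((rel >= -320) & (rel <= 820))
                    for off in PHASED_OFFSETS:
                        d = int(_rel_to_genomic(np.array([off]), int(rec.tss), rec.strand)[0])
                        d += int(rng.integers(-5, 6))
                        if 0 <= d < genome[chrom]:
                            extra_rows.append((d, params.genic_multiplier * 1.5, rec.gene_id))
            rows = pd.DataFrame(
                {
                    "chrom": chrom,
                    "dyad": dyads[keep],
                    "fuzziness_sd": params.fuzziness_sd,
                    "occupancy_weight": w[keep],
                    "region": np.where(genic[keep], "genic", "intergenic"),
                    "gene_id": gene_id[keep],
                }
            )
            if extra_rows:
                extra = pd.DataFrame(
                    {
                        "chrom": chrom,
                        "dyad": [r[0] for r in extra_rows],
                        "fuzziness_sd": params.fuzziness_sd,
                        "occupancy_weight": [r[1] for r in extra_rows],
                        "region": "genic",
                        "gene_id": [r[2] for r in extra_rows],
                    }
                )
                rows = pd.concat([rows, extra], ignore_index=True)
            frames.append(rows)
        nucs = pd.concat(frames, ignore_index=True)
        nucs["H3"] = True
        nucs["K4me3"] = nucs["gene_id"].isin(params.k4_genes)
        nucs["K27me3"] = nucs["gene_id"].isin(params.k27_genes)
        nucs["K9me3"] = params.k9_intergenic & (nucs["region"] == "intergenic")
        nucs = nucs.sort_values(["chrom", "dyad"], kind="stable").reset_index(drop=True)
        out[condition] = nucs
    return out


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(
    nucleosomes: pd.DataFrame,
    genome: GenomeIndex,
    mark: str = "H3",
    mean_tags_per_weight: float = 10.0,
    duplicate_rate: float = 0.0,
    read_length: int = 36,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sample aligned reads for one mark from a true nucleosome map.

    Per nucleosome the tag count is Poisson(occupancy_weight x
    mean_tags_per_weight); each tag's dyad is Normal(nucleosome dyad,
    fuzziness SD) rounded to an integer, with strand Bernoulli(0.5).  Reads
    are laid out so the standard 73-bp 3' shift recovers the sampled dyad
    exactly; tags whose dyad±73 leaves the chromosome are resampled.  PCR
    duplicates are appended by resampling existing reads with probability
    *duplicate_rate*.  Columns ``true_dyad`` (the nucleosome dyad) and
    ``nuc_index`` (row in *nucleosomes*) carry the ground truth.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if mark not in nucleosomes.columns:
        raise ConfigError(f"unknown mark {mark!r}")
    sel = nucleosomes[nucleosomes[mark]]
    counts = rng.poisson(sel["occupancy_weight"].to_numpy() * mean_tags_per_weight)
    nuc_index = np.repeat(sel.index.to_numpy(), counts)
    dyad0 = np.repeat(sel["dyad"].to_numpy(), counts).astype(float)
    sd = np.repeat(sel["fuzziness_sd"].to_numpy(), counts).astype(float)
    chrom = np.repeat(sel["chrom"].to_numpy(), counts)
    sizes = np.array([genome[c] for c in chrom], dtype=np.int64)

    dyads = np.rint(rng.normal(dyad0, sd)).astype(np.int64)
    bad = (dyads - HALF_NUCLEOSOME < 0) | (dyads + HALF_NUCLEOSOME >= sizes)
    for _ in range(100):  # resample out-of-range tags; give up on hopeless ones
        if not bad.any():
            break
        dyads[bad] = np.rint(rng.normal(dyad0[bad], sd[bad])).astype(np.int64)
        bad = (dyads - HALF_NUCLEOSOME < 0) | (dyads + HALF_NUCLEOSOME >= sizes)
    if bad.any():
        log.warning("simulate_reads: dropped %d tags that cannot fit on the chromosome",
                    int(bad.sum()))
        keep = ~bad
        dyads, chrom, sizes = dyads[keep], chrom[keep], sizes[keep]
        nuc_index, dyad0, sd = nuc_index[keep], dyad0[keep], sd[keep]

    plus = rng.random(dyads.size) < 0.5
    start = np.where(plus, dyads - HALF_NUCLEOSOME, dyads + HALF_NUCLEOSOME + 1 - read_length)
    end = start + read_length
    reads = pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": end,
            "strand": np.where(plus, "+", "-"),
            "true_dyad": dyads,
            "nuc_index": nuc_index,
        }
    )
    if duplicate_rate > 0 and len(reads):
        n_dup = rng.binomial(len(reads), duplicate_rate)
        dup = reads.iloc[rng.integers(0, len(reads), size=n_dup)]
        reads = pd.concat([reads, dup], ignore_index=True)
    reads.attrs["n_duplicates_added"] = int(duplicate_rate > 0) and int(
        len(reads) - int(counts.sum())
    )
    return reads


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterSpec:
    """One planted temporal pattern: gene count and base FPKM trajectory."""

    n_genes: int
    fpkm: tuple[float, ...]


def default_cluster_spec(n_per_cluster: int = 20) -> dict[str, ClusterSpec]:
    """Six temporal archetypes over (MEF, pre-iPSC, iPSC).

    C1 monotone down, C2 early down, C3 monotone up, C4 transient up,
    C5 late up, C6 transient down (down-then-up).
    """
    return {
        "C1": ClusterSpec(n_per_cluster, (64.0, 8.0, 1.0)),
        "C2": ClusterSpec(n_per_cluster, (16.0, 1.0, 1.0)),
        "C3": ClusterSpec(n_per_cluster, (1.0, 8.0, 64.0)),
        "C4": ClusterSpec(n_per_cluster, (2.0, 32.0, 2.0)),
        "C5": ClusterSpec(n_per_cluster, (1.0, 1.0, 16.0)),
        "C6": ClusterSpec(n_per_cluster, (16.0, 1.0, 16.0)),
    }


def simulate_expression(
    genes: pd.DataFrame,
    cluster_spec: dict[str, ClusterSpec] | None = None,
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS,
    noise_sd: float = 0.1,  # lognormal noise on the log2 scale
    null_fpkm_range: tuple[float, float] = (0.0, 20.0),
    de_fold: float = 2.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """FPKM + q-value table with DE genes planted in temporal clusters.

    Planted genes follow their cluster's base trajectory with multiplicative
    noise; q-values are below 0.05 exactly in the comparisons where the
    planted fold reaches the DE threshold, and above it elsewhere, so the
    standard filter recovers the planted DE set exactly.  Remaining genes
    get flat trajectories and non-significant q-values.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    cluster_spec = default_cluster_spec() if cluster_spec is None else cluster_spec
    n_cond = len(conditions)
    for name, spec in cluster_spec.items():
        if len(spec.fpkm) != n_cond:
            raise ConfigError(f"cluster {name}: trajectory length != number of conditions")
        base = np.asarray(spec.fpkm)
        if fold_change(base.max(), base.min()) < de_fold:
            raise ConfigError(f"cluster {name}: planted trajectory has fold change < {de_fold}")

    n_planted = sum(s.n_genes for s in cluster_spec.values())
    if n_planted > len(genes):
        raise ConfigError(
            f"cluster spec plants {n_planted} DE genes but only {len(genes)} genes exist"
        )
    gene_ids = genes["gene_id"].to_numpy()
    planted = np.concatenate(
        [[name] * spec.n_genes for name, spec in cluster_spec.items()]
    ) if n_planted else np.array([], dtype=object)
    labels = np.full(len(gene_ids), "null", dtype=object)
    planted_idx = rng.choice(len(gene_ids), size=n_planted, replace=False)
    labels[planted_idx] = planted

    fpkm = np.empty((len(gene_ids), n_cond))
    null_mask = labels == "null"
    base_null = rng.uniform(*null_fpkm_range, size=int(null_mask.sum()))
    fpkm[null_mask] = base_null[:, None] * 2.0 ** rng.normal(
        0.0, noise_sd, size=(int(null_mask.sum()), n_cond)
    )
    for name, spec in cluster_spec.items():
        mask = labels == name
        base = np.asarray(spec.fpkm)
        fpkm[mask] = base[None, :] * 2.0 ** rng.normal(
            0.0, noise_sd, size=(int(mask.sum()), n_cond)
        )

    table = pd.DataFrame({"gene_id": gene_ids})
    for j, cond in enumerate(conditions):
        table[f"fpkm_{cond}"] = fpkm[:, j]
    for a, b in pairwise_comparisons(conditions):
        ia, ib = conditions.index(a), conditions.index(b)
        fc = fold_change(fpkm[:, ia], fpkm[:, ib])
        significant = (labels != "null") & (fc >= de_fold)
        q = np.where(
            significant,
            rng.uniform(1e-6, 0.01, size=len(gene_ids)),
            rng.uniform(0.2, 0.95, size=len(gene_ids)),
        )
        table[q_column(a, b)] = q
    table["planted_cluster"] = labels
    return table
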