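"""End-to-end workflow: preprocess -> occupancy -> positioning -> profiles ->
domains -> promoters -> expression.

`run_all` drives the pipeline from files on disk via a config mapping;
`demo` first writes a fully synthetic dataset and then runs the pipeline on
it, reporting recovered-vs-planted metrics.  Outputs are deterministic
given identical config and inputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import domains as dom
from . import expression as expr
from . import formats, occupancy, positioning, preprocess, profiles, promoters, simulate

log = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "shift": 73,
    "retention": 0.99,
    "compare_bin_size": 10_000,
    "correlate_bin_size": 100_000,
    "fold": 1.5,
    "sigma": 20.0,
    "exclusion": 147,
    "min_tags": 3,
    "match_max_dist": 73,
    "island_window": 1000,
    "island_min_reads": 6,
    "island_min_total": 60,
    "domain_overlap": 0.5,
    "promoter_flank": 500,
    "promoter_threshold": 1.0,
    "de_fold": 2.0,
    "de_q_max": 0.05,
    "k_profiles": 4,
    "k_expression": 6,
    "seed": 0,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _load_tag_inputs(config: dict, genome: formats.GenomeIndex, params: dict):
    """Read and preprocess every reads file in config['reads'][condition][mark]."""
    tags: dict[str, dict[str, pd.DataFrame]] = {}
    caps = {}
    for condition, marks in config["reads"].items():
        tags[condition] = {}
        for mark, path in marks.items():
            reads = formats.read_alignments(path, genome)
            t = preprocess.shift_to_dyad(reads, genome, shift=params["shift"])
            t, cap = preprocess.cap_duplicates(t, retention=params["retention"])
            tags[condition][mark] = t
            caps[f"{condition}/{mark}"] = {
                "cap": cap.cap, "retained": cap.retained, "total": cap.total,
            }
    return tags, caps


def run_all(config: dict, outdir: str | Path) -> dict:
    """Run the full pipeline from a config mapping; returns the summary dict.

    Config keys: ``genome`` (chrom sizes TSV), ``genes`` (BED12/GTF),
    ``reads`` (condition -> mark -> BED/SAM path), optional ``cpg_islands``
    (BED) and ``expression`` (TSV), optional ``params`` overriding
    `DEFAULT_PARAMS`, ``conditions`` (ordered names).  The promoters stage
    is skipped, and the run marked partial, when no CpG file is given.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    summary: dict = {"params": params, "stages": {}, "partial": False}

    try:
        genome = formats.GenomeIndex.from_file(config["genome"])
        genes = formats.read_gene_annotation(config["genes"])
    except Exception as exc:
        raise PipelineError("inputs", str(exc)) from exc
    conditions = list(config.get("conditions") or config["reads"].keys())

    # --- preprocess -------------------------------------------------------
    try:
        tags, caps = _load_tag_inputs(config, genome, params)
        summary["stages"]["preprocess"] = caps
    except Exception as exc:
        raise PipelineError("preprocess", str(exc)) from exc

    h3 = {c: tags[c]["H3"] for c in conditions if "H3" in tags.get(c, {})}

    # --- occupancy --------------------------------------------------------
    try:
        occ = {}
        tracks = {
            c: occupancy.bin_counts(t, genome, params["compare_bin_size"], mode="fraction")
            for c, t in h3.items()
        }
        for a, b in zip(conditions, conditions[1:]):
            comp = occupancy.classify_bins(tracks[a], tracks[b], fold=params["fold"])
            occ[f"{a}_to_{b}"] = comp.fractions
            comp.data.to_csv(outdir / f"bins_{a}_to_{b}.tsv", sep="\t", index=False)
        summary["stages"]["occupancy"] = occ
    except Exception as exc:
        raise PipelineError("occupancy", str(exc)) from exc

    # --- positioning ------------------------------------------------------
    try:
        calls = {}
        for c, t in h3.items():
            calls[c] = positioning.call_nucleosomes(
                t, genome, sigma=params["sigma"], exclusion=params["exclusion"],
                min_tags=params["min_tags"],
            )
            positioning.write_calls_bed(calls[c], outdir / f"nucleosomes_{c}.bed")
        pos_summary = {c: {"n_calls": int(len(v)),
                           "mean_fuzziness": float(v["fuzziness"].mean()) if len(v) else None}
                       for c, v in calls.items()}
        for a, b in zip(conditions, conditions[1:]):
            pairs = positioning.match_common(calls[a], calls[b], max_dist=params["match_max_dist"])
            if len(pairs) >= 2:
                cmp_ = positioning.compare_fuzziness(pairs)
                pos_summary[f"{a}_vs_{b}"] = {
                    "n_pairs": cmp_.n_pairs,
                    "mean_fuzziness_a": cmp_.mean_a,
                    "mean_fuzziness_b": cmp_.mean_b,
                    "paired_t": cmp_.t_statistic,
                    "p_value": cmp_.p_value,
                }
        summary["stages"]["positioning"] = pos_summary
    except Exception as exc:
        raise PipelineError("positioning", str(exc)) from exc

    # --- profiles ---------------------------------------------------------
    try:
        prof_summary = {}
        for c, t in h3.items():
            prof = profiles.tss_profile(t, genes)
            pd.DataFrame({"position": prof.positions, "value": prof.values}).to_csv(
                outdir / f"tss_profile_{c}.tsv", sep="\t", index=False
            )
            prof_summary[c] = {"n_genes": prof.n_genes, "total_tags": prof.total_tags}
        summary["stages"]["profiles"] = prof_summary
    except Exception as exc:
        raise PipelineError("profiles", str(exc)) from exc

    # --- domains ----------------------------------------------------------
    try:
        dom_summary = {}
        domain_sets = {}
        for c in conditions:
            marks = tags.get(c, {})
            if "K4me3" not in marks or "K27me3" not in marks:
                continue
            k4 = dom.call_islands_from_tags(
                marks["K4me3"], genome, "K4me3", win=params["island_window"],
                min_reads=params["island_min_reads"], min_total=params["island_min_total"],
            )
            k27 = dom.call_islands_from_tags(
                marks["K27me3"], genome, "K27me3", win=params["island_window"],
                min_reads=params["island_min_reads"], min_total=params["island_min_total"],
            )
            d = dom.classify_domains(k4, k27, min_overlap=params["domain_overlap"])
            domain_sets[c] = d
            dom.write_domains_bed(d, outdir / f"domains_{c}.bed")
            dom_summary[c] = d["state"].value_counts().to_dict()
        for a, b in zip(conditions, conditions[1:]):
            if a in domain_sets and b in domain_sets:
                m = dom.domain_transitions(domain_sets[a], domain_sets[b],
                                           min_overlap=params["domain_overlap"])
                m.to_csv(outdir / f"domain_transitions_{a}_to_{b}.tsv", sep="\t")
                dom_summary[f"{a}_to_{b}"] = {
                    f"{r}->{c2}": float(m.loc[r, c2]) for r in m.index for c2 in m.columns
                }
        summary["stages"]["domains"] = dom_summary
    except Exception as exc:
        raise PipelineError("domains", str(exc)) from exc

    # --- promoters --------------------------------------------------------
    if config.get("cpg_islands"):
        try:
            cpg = formats.read_intervals(config["cpg_islands"])
            mark_tags = {
                c: {"K4me3": tags[c]["K4me3"], "K27me3": tags[c]["K27me3"]}
                for c in conditions
                if "K4me3" in tags.get(c, {}) and "K27me3" in tags.get(c, {})
            }
            table = promoters.build_promoter_table(
                genes, cpg, genome, mark_tags,
                threshold=params["promoter_threshold"], flank=params["promoter_flank"],
            )
            table.to_csv(outdir / "promoters.tsv", sep="\t", index=False)
            prom_summary = {}
            for c in mark_tags:
                vc = table.groupby("cpg_class")[f"state_{c}"].value_counts()
                prom_summary[c] = {f"{cls}/{state}": int(n) for (cls, state), n in vc.items()}
            summary["stages"]["promoters"] = prom_summary
        except Exception as exc:
            raise PipelineError("promoters", str(exc)) from exc
    else:
        log.warning("no CpG island file given: promoters stage skipped")
        summary["partial"] = True

    # --- expression -------------------------------------------------------
    if config.get("expression"):
        try:
            table = formats.read_expression_table(config["expression"])
            de = expr.de_genes(table, tuple(conditions),
                               fold=params["de_fold"], q_max=params["de_q_max"])
            exp_summary = {"n_de": int(len(de))}
            if len(de) >= params["k_expression"]:
                labels = expr.cluster_de(de, tuple(conditions),
                                         k=params["k_expression"], seed=params["seed"])
                labels.rename_axis("gene_id").to_frame().to_csv(
                    outdir / "de_clusters.tsv", sep="\t"
                )
                exp_summary["cluster_sizes"] = labels.value_counts().sort_index().to_dict()
            corr = expr.condition_correlation(table)
            corr.to_csv(outdir / "expression_correlation.tsv", sep="\t")
            summary["stages"]["expression"] = exp_summary
        except Exception as exc:
            raise PipelineError("expression", str(exc)) from exc
    else:
        summary["partial"] = True

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary


# ---------------------------------------------------------------------------
# synthetic demo
# ---------------------------------------------------------------------------

def write_synthetic_dataset(
    outdir: str | Path,
    config: simulate.SimConfig,
    mean_tags_per_weight: float = 6.0,
    duplicate_rate: float = 0.02,
) -> dict:
    """Simulate a full dataset and write it in the pipeline's input formats.

    Returns a `run_all`-ready config dict (with a ``truth`` key carrying the
    planted ground truth in memory).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = config.rng()
    genome, genes, cpg = simulate.simulate_genome(config, rng)

    n_per_cluster = max(2, len(genes) // 10)  # plant ~60% non-DE genes
    expr_table = simulate.simulate_expression(
        genes, cluster_spec=simulate.default_cluster_spec(n_per_cluster), rng=rng
    )
    fpkm_ref = expr_table.set_index("gene_id")[f"fpkm_{config.conditions[0]}"]
    active = frozenset(fpkm_ref[fpkm_ref >= 8.0].index)
    k4 = active
    silent = frozenset(fpkm_ref[fpkm_ref < 2.0].index)
    params = simulate.default_condition_params(
        active_genes=active, k4_genes=k4, k27_genes=silent
    )
    params = {c: params[c] for c in config.conditions}
    maps = simulate.simulate_nucleosome_map(genome, genes, params, config, rng)

    genome.to_file(outdir / "genome.sizes")
    formats.write_genes_bed12(genes, outdir / "genes.bed")
    formats.write_intervals(cpg, outdir / "cpg_islands.bed")
    formats.write_expression_table(
        expr_table.drop(columns=["planted_cluster"]), outdir / "expression.tsv"
    )
    expr_table.to_csv(outdir / "truth_expression.tsv", sep="\t", index=False)

    reads_cfg: dict[str, dict[str, str]] = {}
    truth_reads = {}
    for condition in config.conditions:
        reads_cfg[condition] = {}
        for mark in ("H3", "K4me3", "K27me3"):
            reads = simulate.simulate_reads(
                maps[condition], genome, mark=mark,
                mean_tags_per_weight=mean_tags_per_weight,
                duplicate_rate=duplicate_rate,
                read_length=config.read_length, rng=rng,
            )
            path = outdir / f"reads_{condition}_{mark}.bed"
            formats.write_reads_bed(reads, path)
            reads_cfg[condition][mark] = str(path)
            truth_reads[(condition, mark)] = reads
        maps[condition].to_csv(outdir / f"truth_nucleosomes_{condition}.tsv",
                               sep="\t", index=False)

    return {
        "genome": str(outdir / "genome.sizes"),
        "genes": str(outdir / "genes.bed"),
        "cpg_islands": str(outdir / "cpg_islands.bed"),
        "expression": str(outdir / "expression.tsv"),
        "reads": reads_cfg,
        "conditions": list(config.conditions),
        "truth": {"maps": maps, "expression": expr_table, "reads": truth_reads,
                  "genes": genes, "genome": genome},
    }


def demo(seed: int, outdir: str | Path, sim_config: simulate.SimConfig | None = None) -> dict:
    """One-command synthetic run: simulate, run the pipeline, report
    recovered-vs-planted metrics in the summary."""
    outdir = Path(outdir)
    config = sim_config or simulate.SimConfig(seed=seed)
    inputs = write_synthetic_dataset(outdir / "inputs", config)
    truth = inputs.pop("truth")
    inputs["params"] = {"seed": seed}
    summary = run_all(inputs, outdir / "results")

    # recovered-vs-planted checks
    genome = truth["genome"]
    cond0 = config.conditions[0]
    calls = positioning.read_calls_bed(outdir / "results" / f"nucleosomes_{cond0}.bed")
    planted = truth["maps"][cond0]
    recovered = 0
    for chrom, g in calls.groupby("chrom", sort=False):
        p = np.sort(planted.loc[planted["chrom"] == chrom, "dyad"].to_numpy())
        if p.size == 0:
            continue
        idx = positioning.assign_tags(g["dyad"].to_numpy(), p, max_dist=10)
        recovered += int((idx >= 0).sum())
    table = formats.read_expression_table(inputs["expression"])
    de = expr.de_genes(table, tuple(config.conditions))
    planted_de = set(truth["expression"].loc[
        truth["expression"]["planted_cluster"] != "null", "gene_id"
    ])
    summary["recovery"] = {
        "n_calls": int(len(calls)),
        "n_planted_nucleosomes": int(len(planted)),
        "calls_within_10bp_of_planted": recovered,
        "de_planted": len(planted_de),
        "de_recovered": int(len(de)),
        "de_exact": set(de["gene_id"]) == planted_de,
    }
    with open(outdir / "results" / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary
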