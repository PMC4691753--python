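"""End-to-end orchestration: simulate -> map -> tails -> quantify -> catalog
-> targets -> enrich, with a single structured configuration and a JSON
report bundle.

Every stage writes plain-text artifacts under the output directory and the
final report collects the headline quantities: per-library tailing
proportions, absolute microRNA estimates under both references and mismatch
settings, flagged clearance microRNA candidates, the top word-enrichment
motifs, and — when ground truth is available — a recovery-versus-truth
table. All randomness flows from the seeds in the configuration.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mirmzt import __version__, io
from mirmzt.catalog import cluster_loci, seed_families
from mirmzt.enrichment import (
    classify_genes,
    enrichment_table,
    intersect_classes,
    rank_mirnas,
    word_enrich,
)
from mirmzt.mapping import build_count_matrix, quantify_library, rpm
from mirmzt.quantify import (
    absolute_quantify,
    check_spikes_absent,
    combine_spike_estimates,
    count_spike_reads,
    stage_correlation,
)
from mirmzt.simulate import COMPARISONS, STAGES, default_config, generate_dataset
from mirmzt.tails import call_library, summarize_tails
from mirmzt.targets import pairs_by_mirna, predict_targets

logger = logging.getLogger("mirmzt")


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for the exit diagnostic."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All pipeline parameters, with defaults matching the analysis design."""

    outdir: str = "mirmzt_run"
    rng_seed: int = 0
    max_mismatches: int = 1
    mismatch_variants: tuple[int, ...] = (1, 2)  # absolute-quantification variants
    max_loci: int = 5
    min_prefix: int = 16
    anchor_tolerance: int = 3
    max_gap: int = 10_000
    seed_k: int = 6
    min_class: str = "7mer-A1"
    fold_threshold: float = 2.0
    alpha: float = 0.05
    n_perm: int = 1000
    p_threshold: float = 1e-3
    word_k: int = 6
    spiked_library: str = "oocyte"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "mismatch_variants" in payload:
            payload["mismatch_variants"] = tuple(payload["mismatch_variants"])
        return cls(**payload)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["mismatch_variants"] = list(self.mismatch_variants)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def run_all(config: PipelineConfig) -> dict:
    """Run the whole pipeline on a synthetic dataset; return the report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report: dict = {"version": __version__, "parameters": dataclasses.asdict(config)}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - contract: name the stage
                raise PipelineError(name, exc) from exc

        return wrap

    dataset = stage("simulate")(_stage_simulate, config, out)
    matrix, normalised = stage("map")(_stage_map, config, out, dataset, report)
    stage("tails")(_stage_tails, config, out, dataset, report)
    stage("quantify")(_stage_quantify, config, out, dataset, matrix, report)
    stage("catalog")(_stage_catalog, config, out, dataset, report)
    pairs = stage("targets")(_stage_targets, config, out, dataset, report)
    stage("enrich")(_stage_enrich, config, out, dataset, normalised, pairs, report)
    _recovery_table(dataset, report)
    io.write_json(report, out / "report.json")
    return report


# ---------------------------------------------------------------------------


def _stage_simulate(config: PipelineConfig, out: Path):
    simdir = out / "sim"
    simdir.mkdir(exist_ok=True)
    dataset = generate_dataset(default_config(config.rng_seed))
    io.write_genome_fasta(dataset.genome, simdir / "genome.fa")
    io.write_loci_gff3(dataset.loci, simdir / "loci.gff3")
    for stage_name, reads in dataset.libraries.items():
        io.write_collapsed_fasta(reads, simdir / f"reads_{stage_name}.fa")
    io.write_spikes_tsv(dataset.spikes, simdir / "spikes.tsv")
    io.write_utr_fasta(dataset.utrs, simdir / "utrs.fa")
    for comparison, table in dataset.de_tables.items():
        io.write_de_table(table, simdir / f"de_{comparison}.tsv")
    dataset.truth.to_json(simdir / "truth.json")
    return dataset


def _stage_map(config: PipelineConfig, out: Path, dataset, report):
    per_library = {}
    summaries = []
    for stage_name in STAGES:
        lm = quantify_library(
            dataset.libraries[stage_name], dataset.genome, dataset.loci,
            max_loci=config.max_loci, max_mismatches=config.max_mismatches,
        )
        per_library[stage_name] = lm
        summaries.append(
            {"library": stage_name, "mapped": lm.mapped_total,
             "discarded_multimapper": lm.discarded_multimapper, "unmapped": lm.unmapped}
        )
    matrix = build_count_matrix(per_library)
    normalised = rpm(matrix)
    io.write_count_matrix(matrix, out / "counts.tsv")
    io.write_count_matrix(normalised, out / "rpm.tsv")
    pd.DataFrame(summaries).to_csv(out / "mapping_summary.tsv", sep="\t", index=False)
    report["mapping"] = {s["library"]: s for s in summaries}
    return matrix, normalised


def _stage_tails(config: PipelineConfig, out: Path, dataset, report):
    taildir = out / "tails"
    taildir.mkdir(exist_ok=True)
    tail_report = {}
    for stage_name in STAGES:
        calls = call_library(
            dataset.genome, dataset.libraries[stage_name], dataset.loci,
            min_prefix=config.min_prefix, anchor_tolerance=config.anchor_tolerance,
        )
        summary = summarize_tails(calls, dataset.loci, config.anchor_tolerance)
        rows = [
            {"read": c.read_id, "prefix_len": c.prefix_len, "tail": c.tail,
             "mature": ",".join(c.matures), "count": c.count}
            for c in calls.tailed
        ]
        pd.DataFrame(
            rows, columns=["read", "prefix_len", "tail", "mature", "count"]
        ).to_csv(taildir / f"tail_calls_{stage_name}.tsv", sep="\t", index=False)
        summary.per_mature.to_csv(taildir / f"tail_per_mature_{stage_name}.tsv", sep="\t")
        summary.composition.to_csv(taildir / f"tail_composition_{stage_name}.tsv", sep="\t")
        tail_report[stage_name] = {
            "modified_proportion": summary.modified_proportion,
            "length_histogram": {str(k): v for k, v in summary.length_histogram.items()},
            "position1_A_fraction": float(summary.composition.loc[1, "A"]),
        }
    io.write_json(tail_report, taildir / "tail_summary.json")
    report["tails"] = tail_report


def _stage_quantify(config: PipelineConfig, out: Path, dataset, matrix, report):
    qdir = out / "quantify"
    qdir.mkdir(exist_ok=True)
    check_spikes_absent(dataset.genome, dataset.spikes)
    lib = config.spiked_library
    reads = dataset.libraries[lib]
    estimates = {}
    for mm in config.mismatch_variants:
        lm = quantify_library(
            reads, dataset.genome, dataset.loci,
            max_loci=config.max_loci, max_mismatches=mm,
        )
        total = lm.mapped_total
        spikes = [
            dataclasses.replace(sp, observed_count=count_spike_reads(reads, sp))
            for sp in dataset.spikes
        ]
        spike_est, spike_table = combine_spike_estimates(total, spikes)
        entry = {
            "total_mirna_reads": total,
            "spike": {
                "fmol_per_egg": spike_est.fmol_per_egg,
                "per_spike": spike_table.to_dict(orient="records"),
            },
        }
        truth = dataset.truth
        if truth.reference_mature and truth.reference_fmol:
            ref_reads = float(lm.column[truth.reference_mature])
            endo = absolute_quantify(
                total, ref_reads, truth.reference_fmol, reference="endogenous"
            )
            entry["endogenous"] = {
                "reference": truth.reference_mature,
                "reference_fmol": truth.reference_fmol,
                "fmol_per_egg": endo.fmol_per_egg,
            }
        estimates[f"mm{mm}"] = entry
    io.write_json(estimates, qdir / "absolute_estimates.json")
    corr = stage_correlation(matrix)
    corr.to_csv(qdir / "stage_correlation.tsv", sep="\t")
    report["absolute_quantification"] = estimates
    report["stage_correlation"] = {
        "min_offdiagonal": float(np.nanmin(corr.values[~np.eye(len(corr), dtype=bool)]))
        if len(corr) > 1 else None,
    }


def _stage_catalog(config: PipelineConfig, out: Path, dataset, report):
    cdir = out / "catalog"
    cdir.mkdir(exist_ok=True)
    clusters = cluster_loci(dataset.loci, max_gap=config.max_gap)
    io.write_clusters_bed(clusters, cdir / "clusters.bed")
    families = seed_families(dataset.matures, k=config.seed_k)
    pd.DataFrame(
        [{"seed": f.seed, "n_members": len(f.members), "members": ",".join(f.members)}
         for f in families]
    ).to_csv(cdir / "seed_families.tsv", sep="\t", index=False)
    report["catalog"] = {
        "n_clusters": len(clusters),
        "n_multi_member_clusters": sum(1 for c in clusters if len(c) > 1),
        "n_seed_families": len(families),
        "n_multi_member_families": sum(1 for f in families if len(f.members) > 1),
    }


def _stage_targets(config: PipelineConfig, out: Path, dataset, report):
    from mirmzt.targets import find_sites

    tdir = out / "targets"
    tdir.mkdir(exist_ok=True)
    site_rows = [
        {"gene": s.gene, "mirna": s.mirna, "class": s.site_class, "offset": s.offset}
        for mature in dataset.matures
        for utr in dataset.utrs
        for s in find_sites(mature, utr)
    ]
    pd.DataFrame(site_rows, columns=["gene", "mirna", "class", "offset"]).to_csv(
        tdir / "sites.tsv", sep="\t", index=False
    )
    pairs = predict_targets(dataset.matures, dataset.utrs, min_class=config.min_class)
    with (tdir / "pairs.tsv").open("w") as fh:
        fh.write(f"# min_class={config.min_class}\n")
        pairs.to_csv(fh, sep="\t", index=False)
    report["targets"] = {
        "min_class": config.min_class,
        "n_pairs": int(len(pairs)),
        "n_target_genes": int(pairs["gene"].nunique()) if len(pairs) else 0,
    }
    return pairs


def _stage_enrich(config: PipelineConfig, out: Path, dataset, normalised, pairs, report):
    edir = out / "enrich"
    edir.mkdir(exist_ok=True)
    classified = {
        c: classify_genes(dataset.de_tables[c], config.fold_threshold, config.alpha)
        for c in COMPARISONS
    }
    utr_genes = {u.gene for u in dataset.utrs}
    universe = utr_genes & set(classified[COMPARISONS[0]]["gene"])
    gene_sets: dict[str, set[str]] = {}
    for comparison, table in classified.items():
        for cls in ("down", "up", "none"):
            gene_sets[f"{comparison}:{cls}"] = (
                set(table.loc[table["class"] == cls, "gene"]) & universe
            )
    inters = intersect_classes(classified)
    gene_sets["inters:down"] = inters["down"] & universe
    gene_sets["inters:up"] = inters["up"] & universe

    targets = pairs_by_mirna(pairs)
    table = enrichment_table(
        targets, gene_sets, universe, n_perm=config.n_perm,
        rng_seed=config.rng_seed + 1,
    )
    table.to_csv(edir / "enrichment.tsv", sep="\t", index=False)

    focus = COMPARISONS[0]  # the interval right after zygotic genome activation
    expression = normalised.counts[focus]
    ranking = rank_mirnas(
        table, expression,
        down_label=f"{focus}:down", up_label=f"{focus}:up",
        p_threshold=config.p_threshold,
    )
    ranking.to_csv(edir / "clearance_ranking.tsv", sep="\t", index=False)
    flagged = sorted(ranking.loc[ranking["flagged"], "mirna"])

    words = word_enrich(dataset.utrs, gene_sets[f"{focus}:down"], universe, k=config.word_k)
    words.head(200).to_csv(edir / "word_enrichment.tsv", sep="\t", index=False)

    report["enrichment"] = {
        "universe_size": len(universe),
        "gene_set_sizes": {k: len(v) for k, v in sorted(gene_sets.items())},
        "correction_family_size": table.attrs["correction_family_size"],
        "flagged_clearance_mirnas": flagged,
        "top_words": words.head(10)[["word", "p_hyper", "p_bonferroni"]].to_dict(
            orient="records"
        ),
    }


def _recovery_table(dataset, report) -> None:
    """Planted-versus-recovered checks, written into the report."""
    truth = dataset.truth
    recovery = {}
    flagged = set(report["enrichment"]["flagged_clearance_mirnas"])
    recovery["clearance_flagging"] = {
        "planted": truth.clearance_matures,
        "flagged": sorted(flagged),
        "exact_match": sorted(flagged) == truth.clearance_matures,
    }
    top_words = [w["word"] for w in report["enrichment"]["top_words"]]
    from mirmzt.sequtils import revcomp

    seed_words = {seed: revcomp(seed) for seed in truth.family_seeds}
    recovery["seed_words_in_top10"] = {
        seed: (word in top_words) for seed, word in seed_words.items()
    }
    tail_truth = {}
    for stage_name, per_mature in truth.per_mature_tails.items():
        total = sum(v["total"] for v in per_mature.values())
        recoverable = sum(v["recoverable_modified"] for v in per_mature.values())
        observed = report["tails"][stage_name]["modified_proportion"]
        expected = recoverable / total if total else float("nan")
        tail_truth[stage_name] = {
            "recovered": observed,
            "planted_recoverable": expected,
            "abs_error": abs(observed - expected),
        }
    recovery["tail_proportions"] = tail_truth
    first_variant = next(iter(report["absolute_quantification"]))
    spike = report["absolute_quantification"][first_variant]["spike"]["fmol_per_egg"]
    recovery["absolute_quantification"] = {
        "planted_fmol": truth.total_mirna_fmol,
        "spike_estimate": spike,
        "relative_error": abs(spike - truth.total_mirna_fmol) / truth.total_mirna_fmol,
    }
    report["recovery"] = recovery
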