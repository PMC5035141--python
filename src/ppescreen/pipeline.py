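"""End-to-end orchestration of the target screen from a structured config.

The pipeline runs, in order: optional simulation (or loading of a real
expression table), optional annotation condensing, the transcriptome
expression floor, per-group induction contrasts with the DE filter
cascade, Venn partitioning and co-regulation classification with summary
fractions and top-fraction overlap tests, merged-replicate significance
testing, optional gene-set enrichment, candidate prioritisation and
optional qPCR cross-validation. Every stage writes a TSV under the output
directory and records its row counts in a JSON manifest; identical config
and seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .contrasts import DEFilterCriteria, compute_contrast, contrast_report
from .coregulation import (classify_coregulation, class_counts,
                           coregulation_summary, partition_de_sets,
                           top_fraction_overlap_test)
from .enrichment import enrich_terms, read_cluster_table, read_gmt, score_clusters
from .io import (ExpressionMatrix, condense_annotations, filter_low_expression,
                 read_blast_tabular, read_expression_table,
                 write_expression_table)
from .merged import MERGED_SCHEMES, merge_replicates, test_merged
from .prioritization import select_candidates, well_supported_list
from .qpcr import read_qpcr_table, relative_quantification
from .synthetic import SimulationConfig, simulate_experiment, write_truth_table

logger = logging.getLogger("ppescreen")

GROUPS = ("six1", "eya1", "six1_eya1")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Structured configuration of one screen run."""

    outdir: Path = Path("ppescreen_out")
    seed: int = 0
    simulate: SimulationConfig | None = None
    inputs: dict[str, Path] = field(default_factory=dict)
    criteria: DEFilterCriteria = field(default_factory=DEFilterCriteria)
    pseudocount: float = 1.0
    fpkm_floor: float = 1.0
    condense_rule: str = "max"
    blast_evalue_cutoff: float = 1e-5
    merged_schemes: tuple[str, ...] = tuple(MERGED_SCHEMES)
    alpha: float = 0.05
    top_fraction: float = 0.1
    fc_min_log2_candidates: float = 1.0
    qpcr_efficiency: float = 2.0

    def __post_init__(self) -> None:
        has_matrix = "matrix" in self.inputs
        if (self.simulate is None) == (not has_matrix):
            raise PipelineError(
                "config must provide exactly one of a simulate section or "
                "an input expression matrix")

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        seed = int(raw.get("seed", 0))
        sim = None
        if "simulate" in raw:
            sim_kwargs = dict(raw["simulate"] or {})
            sim_kwargs.setdefault("seed", seed)
            sim = SimulationConfig(**sim_kwargs)
        criteria = DEFilterCriteria(**(raw.get("filters") or {}))
        inputs = {k: Path(v) for k, v in (raw.get("inputs") or {}).items()}
        kwargs: dict[str, Any] = {}
        for key in ("pseudocount", "fpkm_floor", "condense_rule",
                    "blast_evalue_cutoff", "alpha", "top_fraction",
                    "fc_min_log2_candidates", "qpcr_efficiency"):
            if key in raw:
                kwargs[key] = raw[key]
        if "merged_schemes" in raw:
            kwargs["merged_schemes"] = tuple(raw["merged_schemes"])
        return cls(outdir=Path(raw.get("outdir", "ppescreen_out")), seed=seed,
                   simulate=sim, inputs=inputs, criteria=criteria, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})


def _config_hash(config: PipelineConfig) -> str:
    # outdir excluded: the same analysis in two directories is the same run
    fields = {k: v for k, v in vars(config).items() if k != "outdir"}
    blob = repr(sorted(fields.items(), key=lambda kv: kv[0])).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str = "gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def run_screen(config: PipelineConfig) -> dict:
    """Execute the full screen; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": {},
    }

    def stage(name: str):
        logger.info("stage %s", name)
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    try:
        # --- expression matrix: simulated or loaded -----------------------
        if config.simulate is not None:
            info = stage("simulate")
            matrix, truth = simulate_experiment(config.simulate)
            write_truth_table(truth, outdir / "truth.tsv")
            write_expression_table(matrix, outdir / "expression.tsv",
                                   outdir / "samples.tsv")
            info["n_genes"] = matrix.n_genes
            info["n_samples"] = matrix.n_samples
        else:
            info = stage("load")
            matrix = read_expression_table(config.inputs["matrix"],
                                           config.inputs["sample_sheet"])
            info["n_genes"] = matrix.n_genes
            info["n_samples"] = matrix.n_samples

        # --- annotation condensing ---------------------------------------
        if "blast_hits" in config.inputs:
            info = stage("condense")
            hits = read_blast_tabular(config.inputs["blast_hits"],
                                      config.blast_evalue_cutoff)
            matrix, n_dropped = condense_annotations(matrix, hits,
                                                     rule=config.condense_rule)
            info["n_hits"] = len(hits)
            info["n_unannotated_dropped"] = n_dropped
            info["n_genes"] = matrix.n_genes

        # --- transcriptome expression floor ------------------------------
        info = stage("expression_floor")
        matrix = filter_low_expression(matrix, config.fpkm_floor)
        info["n_genes"] = matrix.n_genes
        write_expression_table(matrix, outdir / "expression_floored.tsv",
                               outdir / "samples_floored.tsv")

        # --- per-group contrasts and DE filters --------------------------
        info = stage("contrasts")
        control = compute_contrast(matrix, "uninjected", config.pseudocount)
        contrast_by_group: dict[str, pd.DataFrame] = {}
        de_up: dict[str, set[str]] = {}
        de_down: dict[str, set[str]] = {}
        for group in GROUPS:
            contrast = compute_contrast(matrix, group, config.pseudocount)
            report = contrast_report(contrast, control, config.criteria)
            _write_tsv(report, outdir / f"contrast_{group}.tsv")
            contrast_by_group[group] = contrast
            de_up[group] = set(report.index[report["pass_up"]])
            de_down[group] = set(report.index[report["pass_down"]])
            info[f"{group}_up"] = len(de_up[group])
            info[f"{group}_down"] = len(de_down[group])

        # --- co-regulation classification --------------------------------
        info = stage("coregulation")
        calls = {}
        for direction, de_sets in (("up", de_up), ("down", de_down)):
            part = partition_de_sets(de_sets["six1"], de_sets["eya1"],
                                     de_sets["six1_eya1"], direction)
            calls[direction] = classify_coregulation(part)
            _write_tsv(calls[direction], outdir / f"coregulation_{direction}.tsv")
            info[f"{direction}_regions"] = part.counts
            info[f"{direction}_classes"] = class_counts(calls[direction])
        summary = coregulation_summary(calls["up"], calls["down"])
        overlap_tests = {}
        for a in GROUPS:
            for b in GROUPS:
                if a < b:
                    ranked_a = contrast_by_group[a]["log2fc"]
                    ranked_b = contrast_by_group[b]["log2fc"]
                    orat, p = top_fraction_overlap_test(
                        ranked_a, ranked_b, config.top_fraction)
                    overlap_tests[f"{a}_vs_{b}"] = {
                        "odds_ratio": orat if orat != float("inf") else "inf",
                        "p_value": p}
        summary["top_fraction_overlap"] = overlap_tests
        with open(outdir / "coregulation_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        info["summary"] = {k: v for k, v in summary.items()
                           if not isinstance(v, dict)}

        # --- merged-replicate significance analysis ----------------------
        info = stage("merged")
        merged_results = {}
        for scheme in config.merged_schemes:
            pooled = merge_replicates(matrix, scheme)
            result = test_merged(pooled, alpha=config.alpha,
                                 criteria=config.criteria, control=control,
                                 pseudocount=config.pseudocount)
            _write_tsv(result, outdir / f"merged_{scheme}.tsv")
            merged_results[scheme] = result
            sig = result[result["significant"]]
            info[f"{scheme}_significant_up"] = int((sig["log2fc"] > 0).sum())
            info[f"{scheme}_significant_down"] = int((sig["log2fc"] < 0).sum())

        # --- enrichment (optional) ---------------------------------------
        if "gene_sets" in config.inputs:
            info = stage("enrichment")
            background = set(matrix.gene_ids)
            collection = read_gmt(config.inputs["gene_sets"], background)
            query = set().union(*de_up.values())
            results = enrich_terms(query, collection)
            _write_tsv(results, outdir / "enrichment_terms.tsv",
                       index_label="term_id")
            info["n_terms"] = len(results)
            if "clusters" in config.inputs:
                clusters = read_cluster_table(config.inputs["clusters"])
                cluster_scores = score_clusters(results, clusters)
                _write_tsv(cluster_scores, outdir / "enrichment_clusters.tsv",
                           index_label="cluster_id")
                info["n_clusters"] = len(cluster_scores)

        # --- candidate prioritisation ------------------------------------
        info = stage("prioritization")
        fc_table = pd.DataFrame({
            f"fc_{g}": contrast_by_group[g]["log2fc"] for g in GROUPS})
        fc_table["fc_control"] = control["log2fc"]
        records = well_supported_list(
            fc_table, fc_min_log2=config.fc_min_log2_candidates,
            require_control=True)
        _write_tsv(records, outdir / "well_supported.tsv")
        info["n_well_supported"] = int(records["well_supported"].sum())
        if "tf_list" in config.inputs:
            tf_set = set(pd.read_csv(config.inputs["tf_list"], sep="\t",
                                     header=None)[0])
            rescue: set[str] = set()
            if "rescue_list" in config.inputs:
                rescue = set(pd.read_csv(config.inputs["rescue_list"], sep="\t",
                                         header=None)[0])
            candidates = select_candidates(records, tf_set, rescue)
            _write_tsv(candidates, outdir / "candidates.tsv")
            info["n_candidates"] = len(candidates)

        # --- qPCR cross-validation (optional) ----------------------------
        if "qpcr" in config.inputs:
            info = stage("qpcr")
            table = read_qpcr_table(config.inputs["qpcr"])
            per_rep, per_gene = relative_quantification(
                table, efficiency=config.qpcr_efficiency)
            per_rep.to_csv(outdir / "qpcr_replicates.tsv", sep="\t", index=False)
            _write_tsv(per_gene, outdir / "qpcr_summary.tsv")
            info["n_genes"] = len(per_gene)
    except PipelineError:
        raise
    except Exception as exc:
        failed = list(manifest["stages"])[-1] if manifest["stages"] else "init"
        raise PipelineError(f"stage {failed!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def write_report(manifest: Mapping[str, Any]) -> str:
    """Human-readable run summary from a manifest."""
    lines = [f"ppescreen {manifest.get('version', '?')} run report",
             f"seed: {manifest.get('seed')}   "
             f"config: {manifest.get('config_hash')}", ""]
    stages = manifest.get("stages", {})

    def section(name: str, title: str):
        lines.append(title)
        if name not in stages:
            lines.append("  not run")
            return None
        return stages[name]

    info = section("contrasts", "Per-group DE counts (up / down):")
    if info is not None:
        for group in GROUPS:
            lines.append(f"  {group}: {info.get(f'{group}_up', 0)} / "
                         f"{info.get(f'{group}_down', 0)}")
    lines.append("")
    info = section("coregulation", "Co-regulation classes:")
    if info is not None:
        for direction in ("up", "down"):
            counts = info.get(f"{direction}_classes", {})
            lines.append(f"  {direction}: " + ", ".join(
                f"{k}={counts[k]}" for k in sorted(counts)))
        summary = info.get("summary", {})
        lines.append(
            f"  co-regulated total: "
            f"{summary.get('coregulated_up', 0) + summary.get('coregulated_down', 0)}"
            f" (up {summary.get('coregulated_up', 0)}, "
            f"down {summary.get('coregulated_down', 0)})")
        if summary.get("pct_coregulated_up") is not None:
            lines.append(f"  % of co-regulated genes up-regulated: "
                         f"{summary['pct_coregulated_up']}")
    lines.append("")
    info = section("merged", "Merged-scheme significant genes (up / down):")
    if info is not None:
        for scheme in MERGED_SCHEMES:
            up = info.get(f"{scheme}_significant_up")
            down = info.get(f"{scheme}_significant_down")
            if up is not None:
                lines.append(f"  {scheme}: {up} / {down}")
    lines.append("")
    info = section("prioritization", "Candidates:")
    if info is not None:
        lines.append(f"  well-supported genes: {info.get('n_well_supported', 0)}")
        if "n_candidates" in info:
            lines.append(f"  selected candidates: {info['n_candidates']}")
    return "\n".join(lines) + "\n"
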