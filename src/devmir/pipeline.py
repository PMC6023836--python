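"""End-to-end orchestration: simulate -> filter -> DE -> cluster -> integrate
-> correlate -> prioritize -> enrich, from a single flat YAML config.

Every output is a TSV under the configured output directory; a JSON-lines
manifest records seeds, thresholds, row counts and checksums so a rerun with
the same config can be verified to be bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .clustering import dmin_curve, fuzzy_cmeans, order_clusters, standardize_profiles
from .de import de_feature_ids, de_vs_reference, max_abs_lfc, sex_fold_change_counts
from .enrichment import hypergeom_enrichment
from .io import ExpressionMatrix, filter_expressed, read_expression, stage_means
from .network import annotate_correlations, build_link_matrices, dominant_links
from .prioritize import (
    annotations_from_frame,
    count_anticorr_regulators,
    prioritization_table,
    stringent_filter,
    template_match,
)
from .simulate import DEFAULT_RESOURCES, SyntheticConfig, generate_dataset, write_dataset
from .targets import ScoreCutoff, filter_by_score, merge_resources, score_to_percentile, split_unified_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; every threshold of the analysis is here."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    simulate: bool = True
    simulate_options: dict[str, Any] = field(default_factory=dict)
    # input paths, required when simulate is False
    gene_matrix: str | None = None
    gene_samples: str | None = None
    mirna_matrix: str | None = None
    mirna_samples: str | None = None
    interactions: str | None = None
    annotations: str | None = None
    # thresholds
    expression_threshold: float = 5.0
    p_threshold: float = 1e-5
    lfc_threshold: float = 2.0
    tau_threshold: float = -0.4
    dominance_fraction: float = 0.5
    regulator_min_count: int = 10
    template_threshold: float = 0.6
    template_mirna: str | None = None
    correlation_mode: str = "dev"
    # clustering
    gene_clusters: int = 6
    mirna_clusters: int = 3
    fuzzifier: float = 2.0
    cluster_restarts: int = 5
    # DE references
    references: list[str] = field(default_factory=lambda: ["young", "E19.5"])
    # score cutoffs: resource -> {threshold, direction}; defaults from the
    # synthetic resources when absent
    cutoffs: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.simulate:
            required = [
                "gene_matrix", "gene_samples", "mirna_matrix", "mirna_samples",
                "interactions", "annotations",
            ]
            for name in required:
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"config key {name!r} required when simulate is false")
                if not Path(path).exists():
                    raise ValueError(f"input path for {name!r} does not exist: {path}")
        if not -1 <= self.tau_threshold <= 0:
            raise ValueError("tau_threshold must lie in [-1, 0]")
        if not 0 <= self.dominance_fraction <= 1:
            raise ValueError("dominance_fraction must lie in [0, 1]")

    def score_cutoffs(self) -> dict[str, ScoreCutoff]:
        cutoffs = {
            r.name: ScoreCutoff(r.cutoff, r.direction)
            for r in DEFAULT_RESOURCES
            if r.evidence == "predicted"
        }
        for name, spec in self.cutoffs.items():
            cutoffs[name] = ScoreCutoff(float(spec["threshold"]), spec["direction"])
        return cutoffs


class _Manifest:
    def __init__(self, out_dir: Path, config: PipelineConfig):
        self.path = out_dir / "manifest.jsonl"
        self.entries: list[dict] = [
            {"record": "run", "version": __version__, "seed": config.seed,
             "thresholds": {
                 "expression": config.expression_threshold,
                 "p": config.p_threshold,
                 "lfc": config.lfc_threshold,
                 "tau": config.tau_threshold,
                 "dominance": config.dominance_fraction,
                 "regulator_min": config.regulator_min_count,
                 "template": config.template_threshold,
             }}
        ]

    def add(self, name: str, path: Path, rows: int) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.entries.append(
            {"record": "output", "name": name, "path": path.name, "rows": rows, "sha256": digest}
        )

    def write(self) -> None:
        with open(self.path, "w") as fh:
            for entry in self.entries:
                fh.write(json.dumps(entry, sort_keys=True) + "\n")


def _write_tsv(frame: pd.DataFrame, path: Path, manifest: _Manifest, name: str,
               index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.6g")
    manifest.add(name, path, len(frame))


def summarize_de_counts(de_results: pd.DataFrame) -> pd.DataFrame:
    """Per-contrast up/down DE counts and their ratio (NaN when nothing is
    downregulated)."""
    rows = []
    for contrast, sub in de_results.groupby("contrast", sort=False):
        de = sub.loc[sub["is_DE"]]
        n_up = int((de["log2FC"] > 0).sum())
        n_down = int((de["log2FC"] < 0).sum())
        rows.append(
            {
                "contrast": contrast,
                "n_up": n_up,
                "n_down": n_down,
                "up_down_ratio": n_up / n_down if n_down else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["contrast", "n_up", "n_down", "up_down_ratio"])


def _cluster_stage(profiles_frame, n_clusters, fuzzifier, restarts, seed):
    standardized, excluded = standardize_profiles(profiles_frame)
    model = order_clusters(
        fuzzy_cmeans(standardized, c=n_clusters, m=fuzzifier, restarts=restarts, seed=seed)
    )
    return model, standardized, excluded


def _model_tables(model) -> tuple[pd.DataFrame, pd.DataFrame]:
    labels = model.hard_labels()
    assignment = pd.DataFrame(
        {
            "feature_id": model.feature_ids,
            "cluster": labels.to_numpy(),
            "max_membership": model.membership.max(axis=1).to_numpy(),
        }
    )
    centroids = model.centroids.copy()
    centroids.insert(0, "cluster", range(model.n_clusters))
    return assignment, centroids


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage; returns in-memory results keyed by stage.

    Any stage failure aborts with the stage name; files already written for
    the failing stage are renamed with a ``.partial`` suffix.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out_dir, config)
    results: dict[str, Any] = {}
    stage_files: list[Path] = []

    def run_stage(name, fn):
        stage_files.clear()
        logger.info("stage: %s", name)
        try:
            return fn()
        except Exception as exc:
            for path in stage_files:
                if path.exists():
                    path.rename(path.with_suffix(path.suffix + ".partial"))
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    def write(frame, filename, name, index=False):
        path = out_dir / filename
        stage_files.append(path)
        _write_tsv(frame, path, manifest, name, index=index)

    # -- simulate / load ---------------------------------------------------
    def stage_input():
        if config.simulate:
            sim_cfg = SyntheticConfig(**{"seed": config.seed, **config.simulate_options})
            bundle = generate_dataset(sim_cfg)
            gene_m, mirna_m, interactions, annotations, truth = bundle
            paths = write_dataset(out_dir / "synthetic", *bundle)
            for key, path in paths.items():
                manifest.add(f"synthetic_{key}", path, sum(1 for _ in open(path)) - 1)
            results["truth"] = truth
        else:
            gene_m = read_expression(config.gene_matrix, config.gene_samples, "gene")
            mirna_m = read_expression(config.mirna_matrix, config.mirna_samples, "miRNA")
            interactions = pd.read_csv(config.interactions, sep="\t")
            annotations = pd.read_csv(config.annotations, sep="\t")
        results["gene_matrix"] = gene_m
        results["mirna_matrix"] = mirna_m
        results["interactions_raw"] = interactions
        results["annotations"] = annotations

    run_stage("input", stage_input)

    # -- expression filter -------------------------------------------------
    def stage_filter():
        genes, dropped_g = filter_expressed(results["gene_matrix"], config.expression_threshold)
        mirnas, dropped_m = filter_expressed(results["mirna_matrix"], config.expression_threshold)
        results["genes_expressed"] = genes
        results["mirnas_expressed"] = mirnas
        write(pd.DataFrame({"feature_id": dropped_g}), "dropped_genes.tsv", "dropped_genes")
        write(pd.DataFrame({"feature_id": dropped_m}), "dropped_mirnas.tsv", "dropped_mirnas")

    run_stage("expression_filter", stage_filter)

    # -- differential expression ------------------------------------------
    def stage_de():
        for kind, matrix in (("genes", results["genes_expressed"]),
                             ("mirnas", results["mirnas_expressed"])):
            for ref in config.references:
                if ref not in matrix.stages_present():
                    raise ValueError(f"reference stage {ref!r} absent from {kind} data")
                de = de_vs_reference(matrix, ref, config.p_threshold, config.lfc_threshold)
                results[f"de_{kind}_{ref}"] = de
                write(de, f"de_{kind}_{ref}.tsv", f"de_{kind}_{ref}")
                write(summarize_de_counts(de), f"de_counts_{kind}_{ref}.tsv",
                      f"de_counts_{kind}_{ref}")
            sex_counts = sex_fold_change_counts(matrix)
            write(sex_counts, f"sex_fold_counts_{kind}.tsv", f"sex_fold_counts_{kind}")
        primary_ref = config.references[0]
        results["de_genes"] = de_feature_ids(results[f"de_genes_{primary_ref}"])
        results["de_mirnas"] = de_feature_ids(results[f"de_mirnas_{primary_ref}"])

    run_stage("differential_expression", stage_de)

    # -- clustering --------------------------------------------------------
    def stage_cluster():
        gene_profiles = stage_means(results["genes_expressed"])
        mirna_profiles = stage_means(results["mirnas_expressed"])
        results["gene_profiles"] = gene_profiles
        results["mirna_profiles"] = mirna_profiles

        de_gene_profiles = gene_profiles.values.loc[
            sorted(results["de_genes"] & set(gene_profiles.values.index))
        ]
        de_mirna_profiles = mirna_profiles.values.loc[
            sorted(results["de_mirnas"] & set(mirna_profiles.values.index))
        ]
        gene_model, gene_std, _ = _cluster_stage(
            de_gene_profiles, config.gene_clusters, config.fuzzifier,
            config.cluster_restarts, config.seed,
        )
        mirna_model, mirna_std, _ = _cluster_stage(
            de_mirna_profiles, config.mirna_clusters, config.fuzzifier,
            config.cluster_restarts, config.seed,
        )
        # embryonic-only miRNA re-clustering
        dev_mirna_profiles = stage_means(results["mirnas_expressed"], dev_only=True).values.loc[
            de_mirna_profiles.index
        ]
        mirna_dev_model, _, _ = _cluster_stage(
            dev_mirna_profiles, config.mirna_clusters, config.fuzzifier,
            config.cluster_restarts, config.seed,
        )
        results["gene_model"] = gene_model
        results["mirna_model"] = mirna_model
        results["mirna_dev_model"] = mirna_dev_model
        for tag, model, std in (
            ("genes", gene_model, gene_std),
            ("mirnas", mirna_model, mirna_std),
        ):
            assignment, centroids = _model_tables(model)
            write(assignment, f"clusters_{tag}.tsv", f"clusters_{tag}")
            write(centroids, f"centroids_{tag}.tsv", f"centroids_{tag}")
            max_c = min(10, len(std) - 1)
            if max_c >= 2:
                curve = dmin_curve(std, range(2, max_c + 1), m=config.fuzzifier,
                                   seed=config.seed, restarts=config.cluster_restarts)
                write(curve, f"dmin_{tag}.tsv", f"dmin_{tag}")
        assignment, _ = _model_tables(mirna_dev_model)
        write(assignment, "clusters_mirnas_dev.tsv", "clusters_mirnas_dev")

    run_stage("clustering", stage_cluster)

    # -- target integration ------------------------------------------------
    def stage_integrate():
        per_resource = split_unified_table(results["interactions_raw"])
        cutoffs = config.score_cutoffs()
        directions = {name: c.direction for name, c in cutoffs.items()}
        filtered = []
        for resource, records in per_resource.items():
            records = filter_by_score(records, cutoffs)
            filtered.append(records)
        unified, summary = merge_resources(*filtered)
        unified = score_to_percentile(unified, directions)
        unified = unified.pipe(
            lambda f: f.loc[
                f["gene_id"].isin(results["genes_expressed"].feature_ids)
                & f["mirna_id"].isin(results["mirnas_expressed"].feature_ids)
            ].reset_index(drop=True)
        )
        results["interactions"] = unified
        write(unified, "interactions_filtered.tsv", "interactions_filtered")
        write(summary, "interaction_pairs.tsv", "interaction_pairs")

    run_stage("target_integration", stage_integrate)

    # -- correlation network -----------------------------------------------
    def stage_correlate():
        correlated = annotate_correlations(
            results["interactions"],
            results["mirna_profiles"],
            results["gene_profiles"],
            threshold=config.tau_threshold,
            mode=config.correlation_mode,
        )
        results["correlated"] = correlated
        write(correlated, "correlated_interactions.tsv", "correlated_interactions")
        link = build_link_matrices(
            correlated,
            results["mirna_model"].hard_labels(),
            results["gene_model"].hard_labels(),
        )
        results["link_matrices"] = link
        write(link.m_all, "m_all.tsv", "m_all", index=True)
        write(link.m_neg, "m_neg.tsv", "m_neg", index=True)
        write(link.m_neg_targets, "m_neg_targets.tsv", "m_neg_targets", index=True)
        links = dominant_links(link, config.dominance_fraction)
        results["dominant_links"] = links
        write(pd.DataFrame(links, columns=["mirna_cluster", "gene_cluster"]),
              "dominant_links.tsv", "dominant_links")

    run_stage("correlation_network", stage_correlate)

    # -- prioritization ----------------------------------------------------
    def stage_prioritize():
        annotations = annotations_from_frame(results["annotations"])
        table = prioritization_table(
            results["correlated"], results["de_genes"], annotations,
            min_regulators=config.regulator_min_count,
        )
        results["prioritization"] = table
        write(table, "prioritization.tsv", "prioritization")
        _, shortlist = count_anticorr_regulators(
            results["correlated"], annotations, config.regulator_min_count
        )
        results["regulator_shortlist"] = shortlist

        primary_ref = config.references[0]
        gene_lfc = max_abs_lfc(results[f"de_genes_{primary_ref}"])
        mirna_lfc = max_abs_lfc(results[f"de_mirnas_{primary_ref}"])
        stringent = stringent_filter(
            results["correlated"], mirna_lfc, gene_lfc, annotations,
            lfc_threshold=config.lfc_threshold, tau_threshold=config.tau_threshold,
            tau_column="tau_dev" if config.correlation_mode == "dev" else "tau_full",
        )
        results["stringent"] = stringent
        write(stringent, "stringent_candidates.tsv", "stringent_candidates")

        if config.template_mirna is not None:
            matches = template_match(
                config.template_mirna, results["mirna_profiles"], config.template_threshold
            )
            results["template_matches"] = matches
            write(matches, "template_matches.tsv", "template_matches")

    run_stage("prioritization", stage_prioritize)

    # -- enrichment --------------------------------------------------------
    def stage_enrich():
        categories: dict[str, set[str]] = {}
        for rec in results["annotations"].itertuples(index=False):
            categories.setdefault(rec.category, set()).add(rec.gene_id)
        universe = set(results["genes_expressed"].feature_ids)
        labels = results["gene_model"].hard_labels()
        frames = []
        for cluster in range(results["gene_model"].n_clusters):
            query = set(labels.index[labels == cluster])
            table = hypergeom_enrichment(query, categories, universe)
            table.insert(0, "cluster", cluster)
            frames.append(table)
        enrichment = pd.concat(frames, ignore_index=True)
        results["enrichment"] = enrichment
        write(enrichment, "cluster_enrichment.tsv", "cluster_enrichment")

    run_stage("enrichment", stage_enrich)

    manifest.write()
    results["manifest_path"] = manifest.path
    logger.info("pipeline complete: %s", out_dir)
    return results
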