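"""End-to-end orchestration for one or many dataset pairs.

Per dataset pair: stratify cohorts -> build both correlation-weighted
networks -> extract receptor-TF pathways -> prune to the signaling network
-> feature panel -> motif counts.  Across datasets: paired Wilcoxon
comparison per feature.  Identical config + seed gives identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import correlation, features, io, motifs, pathways, stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DatasetResult:
    dataset: str
    features_normal: features.FeatureVector
    features_tumor: features.FeatureVector
    motif_counts: motifs.MotifCounts
    n_samples: int
    n_hubs: int
    seed: int
    timings: dict[str, float]


def analyze_cohort(
    expr: io.ExpressionMatrix,
    interactions: io.InteractionSet,
    receptors: io.GeneSet,
    tfs: io.GeneSet,
    hub_removal_fraction: float = 0.10,
):
    """One cohort: weighted network -> pathways -> signaling net -> features."""
    net = correlation.build_weighted_network(interactions, expr)
    paths = pathways.extract_pathways(net, receptors, tfs)
    signet = pathways.build_signaling_network(net, paths)
    panel = features.signaling_features(signet, net, hub_removal_fraction)
    return net, signet, panel


def analyze_dataset_pair(
    dataset: str,
    expr_normal: io.ExpressionMatrix,
    expr_tumor: io.ExpressionMatrix,
    interactions: io.InteractionSet,
    receptors: io.GeneSet,
    tfs: io.GeneSet,
    cancer_genes: io.GeneSet | None = None,
    seed: int = 0,
    hub_count: int = 50,
    hub_removal_fraction: float = 0.10,
    category_bounds: tuple[float, float] = (0.3, 0.5),
) -> DatasetResult:
    """Full per-dataset analysis of one (normal, tumor) cohort pair."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    expr_normal, expr_tumor = io.stratify_cohort(expr_normal, expr_tumor, seed=seed)
    timings["stratify"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    _, signet_n, panel_n = analyze_cohort(
        expr_normal, interactions, receptors, tfs, hub_removal_fraction
    )
    _, signet_t, panel_t = analyze_cohort(
        expr_tumor, interactions, receptors, tfs, hub_removal_fraction
    )
    timings["networks_features"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    freq_n = features.FrequencyTable(
        signet_n.link_freq, signet_n.node_freq, len(signet_n.pathways)
    )
    freq_t = features.FrequencyTable(
        signet_t.link_freq, signet_t.node_freq, len(signet_t.pathways)
    )
    hubs = motifs.select_cancer_hubs(freq_n, freq_t, cancer_genes, k=hub_count)
    triangles = motifs.enumerate_shared_triangles(signet_n, signet_t, hubs)
    counts = motifs.MotifCounts(
        integration=motifs.count_integration_motifs(triangles, category_bounds),
        maintenance=motifs.count_maintenance_motifs(triangles, category_bounds),
        comparative=motifs.count_comparative_motifs(
            signet_n.pathways, signet_t.pathways
        ),
    )
    timings["motifs"] = time.perf_counter() - t0

    return DatasetResult(
        dataset=dataset,
        features_normal=panel_n,
        features_tumor=panel_t,
        motif_counts=counts,
        n_samples=expr_normal.n_samples,
        n_hubs=len(hubs),
        seed=seed,
        timings=timings,
    )


def results_to_tables(
    results: list[DatasetResult],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(features, motifs, tidy feature table) DataFrames from dataset results."""
    feat_rows, motif_rows, tidy_rows = [], [], []
    for res in results:
        for cohort, panel in (
            ("normal", res.features_normal),
            ("tumor", res.features_tumor),
        ):
            d = asdict(panel)
            feat_rows.append({"dataset": res.dataset, "cohort": cohort, **d})
        mc = res.motif_counts
        for motif_name, (n_val, t_val) in (
            ("comparative_motif", mc.comparative),
            ("integration_motif", mc.integration),
            ("maintenance_motif", mc.maintenance),
        ):
            motif_rows.append(
                {"dataset": res.dataset, "motif": motif_name,
                 "normal": n_val, "tumor": t_val}
            )
            tidy_rows.append(
                {"dataset": res.dataset, "feature": motif_name,
                 "normal": n_val, "tumor": t_val}
            )
        feature_map = {
            "n_links": "n_links",
            "alpha": "alpha",
            "link_frequency": "avg_link_freq",
            "node_frequency": "avg_node_freq",
            "path_length": "avg_path_length",
            "diameter_increase": "diameter_ratio_after_hub_removal",
            "clustering": "avg_clustering",
            "clustering_positive": "n_nodes_clustering_positive",
            "entropy": "entropy_bits",
            "link_distance": "avg_link_distance",
        }
        for feat, attr in feature_map.items():
            tidy_rows.append(
                {
                    "dataset": res.dataset,
                    "feature": feat,
                    "normal": getattr(res.features_normal, attr),
                    "tumor": getattr(res.features_tumor, attr),
                }
            )
    return pd.DataFrame(feat_rows), pd.DataFrame(motif_rows), pd.DataFrame(tidy_rows)


def _config_hash(config: io.AnalysisConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_full_analysis(config: io.AnalysisConfig) -> dict:
    """Run every configured dataset pair and the cross-dataset comparison.

    A failing dataset is logged and skipped; at least one success is
    required for the comparison stage.  Writes features.tsv, motifs.tsv,
    comparison.tsv and report.json under ``config.output_dir``.
    """
    interactions = io.read_interaction_list(config.interactions)
    receptors = io.read_gene_list(config.receptors, "receptor")
    tfs = io.read_gene_list(config.transcription_factors, "transcription_factor")
    cancer = (
        io.read_gene_list(config.cancer_genes, "cancer_mutated")
        if config.cancer_genes
        else None
    )

    results: list[DatasetResult] = []
    failures: dict[str, str] = {}
    for name, paths in config.datasets.items():
        t0 = time.perf_counter()
        try:
            expr_n = io.read_expression_matrix(paths["normal"])
            expr_t = io.read_expression_matrix(paths["tumor"])
            res = analyze_dataset_pair(
                name, expr_n, expr_t, interactions, receptors, tfs,
                cancer_genes=cancer, seed=config.seed,
                hub_count=config.hub_count,
                hub_removal_fraction=config.hub_removal_fraction,
                category_bounds=config.category_bounds,
            )
        except Exception as exc:  # noqa: BLE001 — keep remaining datasets running
            logger.error("dataset %s failed: %s", name, exc)
            failures[name] = str(exc)
            continue
        logger.info("dataset %s done in %.2fs", name, time.perf_counter() - t0)
        results.append(res)

    if not results:
        raise RuntimeError("every dataset failed; nothing to compare")

    feat_df, motif_df, tidy = results_to_tables(results)
    comparison = stats.compare_feature_across_datasets(tidy)
    out_paths = io.write_feature_report(
        feat_df, motif_df, comparison, config.output_dir,
        extra={
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "failures": failures,
            "timings": {r.dataset: r.timings for r in results},
        },
    )
    return {
        "results": results,
        "comparison": comparison,
        "failures": failures,
        "paths": out_paths,
    }
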