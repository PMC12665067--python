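"""Config-driven orchestration: simulate -> bin -> cluster -> markers -> triad tests.

Each stage writes its tables under the run directory and records row
counts and seeds in ``manifest.json``; deterministic stages reproduce
byte-identical artifacts for the same config.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import (annotate_by_majority, expression_knn_graph,
                      leiden_cluster, retain_tissue_clusters,
                      spatial_neighbors_graph)
from .config import PipelineConfig
from .errors import SeedSpatialError
from .gem import bin_counts, capture_stats, read_gem, write_gem
from .markers import rank_markers, top_k_markers
from .permutation import MACRO_GROUPS, subsample_bins, triad_bias_report
from .preprocess import filter_bins, normalize_log1p, pca_embed
from .synthetic import (calibrate_capture_rate, default_gene_model,
                        make_default_template, simulate_section)

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """In-memory handles to every stage output of one run."""

    gem: pd.DataFrame
    truth: object | None
    binned: object
    filtered: object
    assignment: object
    markers: pd.DataFrame
    top_markers: pd.DataFrame
    bias: object | None
    outdir: Path | None


def run_pipeline(config: PipelineConfig, outdir=None,
                 stages: tuple[str, ...] = ("simulate", "stats", "bin",
                                            "cluster", "markers",
                                            "triad-test")) -> PipelineResult:
    """Run the configured stages, writing artifacts and a manifest."""
    config.validate()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "versions": {"seedspatial": __version__,
                     "python": platform.python_version(),
                     "numpy": np.__version__},
        "stages": {},
    }

    stage = "simulate"
    try:
        truth = model = None
        if config.gem_path is not None:
            gem = read_gem(config.gem_path)
            manifest["stages"]["load"] = {"rows": len(gem)}
        else:
            sim = config.simulate
            template = make_default_template(sim.scale, artifact=sim.artifact)
            model = default_gene_model(side_asymmetry=sim.side_asymmetry)
            capture = sim.capture_rate
            if capture is None:
                capture = calibrate_capture_rate(
                    template, model, target=sim.target_mids_per_dnb)
            gem, truth = simulate_section(template, model,
                                          capture_rate=capture, seed=sim.seed)
            manifest["stages"]["simulate"] = {
                "rows": len(gem), "capture_rate": capture, "seed": sim.seed}
            if outdir is not None and "simulate" in stages:
                write_gem(gem, outdir / "gem.tsv")
                truth.write_tsv(outdir / "ground_truth.tsv")

        stage = "stats"
        if "stats" in stages:
            stats = capture_stats(gem, bin_size=20)
            manifest["stages"]["stats"] = stats.rounded | {
                "n_capturing_dnbs": stats.n_capturing_dnbs,
                "total_mids": stats.total_mids}

        stage = "bin"
        binned = bin_counts(gem, config.bin_size)
        manifest["stages"]["bin"] = {"bins": binned.n_bins,
                                     "genes": len(binned.genes),
                                     "total_mids": binned.total()}
        if outdir is not None and "bin" in stages:
            binned.write(outdir / f"bin{config.bin_size}")

        assignment = markers_tab = top = bias = None
        filtered = None
        if "cluster" in stages or "markers" in stages or "triad-test" in stages:
            stage = "cluster"
            filtered = filter_bins(binned, config.filter.min_mid)
            norm = normalize_log1p(filtered)
            n_comp = min(config.pca.n_components,
                         filtered.n_bins - 1, len(filtered.genes))
            emb = pca_embed(norm, n_components=n_comp, seed=config.pca.seed)
            g_expr = expression_knn_graph(emb, k=min(config.graph.k,
                                                     filtered.n_bins - 1))
            g_comb = spatial_neighbors_graph(filtered.bins, g_expr,
                                             lam=config.graph.lam)
            assignment = leiden_cluster(g_comb,
                                        resolution=config.leiden.resolution,
                                        seed=config.leiden.seed)
            mask = truth.tissue_bins(config.bin_size) if truth is not None else None
            assignment, report = retain_tissue_clusters(assignment, filtered,
                                                        tissue_mask=mask)
            if truth is not None:
                assignment = annotate_by_majority(
                    assignment, truth.bin_majority_zones(config.bin_size))
            manifest["stages"]["cluster"] = {
                "bins": filtered.n_bins,
                "clusters": assignment.n_clusters,
                "retained": len(assignment.retained_clusters()),
                "seed": config.leiden.seed,
            }
            if outdir is not None and "cluster" in stages:
                assignment.to_frame().to_csv(outdir / "clusters.tsv",
                                             sep="\t", index=False)
                report.to_csv(outdir / "cluster_discard_report.tsv",
                              sep="\t", index=False)

        if "markers" in stages:
            stage = "markers"
            markers_tab = rank_markers(filtered, assignment)
            top = top_k_markers(markers_tab, k=config.markers.top_k)
            manifest["stages"]["markers"] = {
                "clusters_tested": int(markers_tab["cluster"].nunique())
                if len(markers_tab) else 0}
            if outdir is not None:
                markers_tab.to_csv(outdir / "marker_ranking.tsv",
                                   sep="\t", index=False)
                top.to_csv(outdir / "marker_top.tsv", sep="\t", index=False)

        if "triad-test" in stages and model is not None:
            stage = "triad-test"
            group_map = MACRO_GROUPS if config.perm.macro_groups else None
            sub = subsample_bins(assignment, group_map=group_map,
                                 f=config.perm.f,
                                 floor_min=config.perm.floor_min,
                                 seed=config.perm.seed)
            bias = triad_bias_report(model.triads, filtered, sub,
                                     M=config.perm.M, level=config.perm.level,
                                     K=config.perm.K, seed=config.perm.seed)
            manifest["stages"]["triad-test"] = {
                "tests": len(bias.results), "K": bias.K,
                "M": config.perm.M, "seed": config.perm.seed}
            if outdir is not None:
                bias.to_frame().to_csv(outdir / "triad_tests.tsv",
                                       sep="\t", index=False)
                bias.homeolog_totals.to_csv(outdir / "homeolog_totals.tsv",
                                            sep="\t", index=False)
    except SeedSpatialError:
        if outdir is not None:
            failed = outdir / "failed"
            failed.mkdir(exist_ok=True)
            (failed / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log.error("pipeline failed at stage %r", stage)
        raise

    if outdir is not None:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(gem=gem, truth=truth, binned=binned,
                          filtered=filtered, assignment=assignment,
                          markers=markers_tab, top_markers=top,
                          bias=bias, outdir=outdir)
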