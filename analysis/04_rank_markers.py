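"""Marker-gene discovery per cluster and cross-replicate consensus.

One-vs-rest Welch t-tests on raw Bin50 MID counts rank candidate
markers for every retained cluster of each replicate; the top five per
cluster are compared across replicates (clusters matched by tissue
annotation) and the planted zone markers are checked against the
rankings.
"""

import json
from pathlib import Path

import pandas as pd

from seedspatial.config import PipelineConfig
from seedspatial.markers import plot_marker_dotplot, replicate_consensus
from seedspatial.pipeline import run_pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    manifest = json.loads((RESULTS / "simulation_manifest.json").read_text())
    tops, truth_markers = [], None
    for seed in manifest["seeds"]:
        cfg = PipelineConfig()
        cfg.simulate.seed = seed
        cfg.simulate.capture_rate = manifest["capture_rate"]
        cfg.leiden.seed = seed
        res = run_pipeline(cfg, outdir=None,
                           stages=("simulate", "bin", "cluster", "markers"))
        top = res.top_markers
        top.to_csv(RESULTS / f"markers_top5_rep{seed}.tsv", sep="\t",
                   index=False)
        tops.append(top)
        truth_markers = res.truth.markers
        if seed == manifest["seeds"][0]:
            res.markers.to_csv(RESULTS / "marker_ranking_rep1.tsv",
                               sep="\t", index=False)
            plot_marker_dotplot(top, RESULTS / "marker_dotplot_rep1.png")
    cons = replicate_consensus(tops)
    cons.to_csv(RESULTS / "marker_consensus.tsv", sep="\t", index=False)
    planted = [(z, g) for z, genes in truth_markers.items() for g in genes]
    full = sum(1 for z, g in planted
               if ((cons.tissue_group == z) & (cons.gene_id == g) &
                   (cons.n_replicates == len(tops))).any())
    print(f"{full}/{len(planted)} planted markers are top-5 candidates for "
          f"their zone in all {len(tops)} replicates")
    print(cons.head(12).to_string(index=False))


if __name__ == "__main__":
    main()
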