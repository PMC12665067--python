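"""Marker-gene ranking by one-vs-rest Welch t-test on raw MID counts.

For each retained cluster, every gene is scored with an unequal-variance
two-sample t statistic contrasting the cluster's bins against all other
retained bins, on raw (unnormalised) counts.  Genes are ranked by
descending t; the top-k per cluster are the marker candidates, and a
consensus table counts how often a gene is a candidate for the same
tissue group across replicate sections.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment
from .gem import BinnedExpression

log = logging.getLogger(__name__)


def _group_stats(X, sel: np.ndarray):
    """Per-gene mean, variance (ddof=1) and detection rate over rows sel."""
    n = int(sel.sum())
    sub = X[sel]
    s1 = np.asarray(sub.sum(axis=0)).ravel()
    s2 = np.asarray(sub.multiply(sub).sum(axis=0)).ravel()
    mean = s1 / n
    var = (s2 - n * mean ** 2) / (n - 1) if n > 1 else np.zeros_like(mean)
    var = np.maximum(var, 0.0)
    pct = np.asarray((sub > 0).sum(axis=0)).ravel() / n
    return mean, var, pct, n


def rank_markers(binned: BinnedExpression,
                 assignment: ClusterAssignment) -> pd.DataFrame:
    """Welch t ranking of genes per retained cluster (one vs rest).

    Returns a long table with cluster, gene_id, t_statistic, mean_in,
    mean_out, pct_in and rank (1 = strongest).  Genes with zero variance
    in both groups get t = 0.  Clusters with fewer than two bins on
    either side are skipped with a warning.
    """
    retained = assignment.retained_mask()
    X = binned.counts
    rows = []
    genes = np.asarray(binned.genes)
    for c in assignment.retained_clusters():
        inside = (assignment.labels == c) & retained
        outside = (assignment.labels != c) & retained
        if inside.sum() < 2 or outside.sum() < 2:
            log.warning("cluster %d skipped: needs >= 2 bins in and out", c)
            continue
        m1, v1, pct1, n1 = _group_stats(X, inside)
        m2, v2, _, n2 = _group_stats(X, outside)
        denom = np.sqrt(v1 / n1 + v2 / n2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom > 0, (m1 - m2) / np.where(denom > 0, denom, 1.0), 0.0)
        tab = pd.DataFrame({
            "cluster": c,
            "gene_id": genes,
            "t_statistic": t,
            "mean_in": m1,
            "mean_out": m2,
            "pct_in": pct1,
        })
        # rank by t desc; ties by mean_in desc then gene id
        tab = tab.sort_values(["t_statistic", "mean_in", "gene_id"],
                              ascending=[False, False, True],
                              kind="mergesort").reset_index(drop=True)
        tab["rank"] = np.arange(1, len(tab) + 1)
        rows.append(tab)
    if not rows:
        return pd.DataFrame(columns=["cluster", "gene_id", "t_statistic",
                                     "mean_in", "mean_out", "pct_in", "rank"])
    out = pd.concat(rows, ignore_index=True)
    if assignment.annotation:
        out["tissue_group"] = out["cluster"].map(assignment.annotation).fillna("")
    return out


def top_k_markers(results: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Top-k marker candidates per cluster (ranking already tie-broken)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return (results[results["rank"] <= k]
            .sort_values(["cluster", "rank"])
            .reset_index(drop=True))


def replicate_consensus(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Count, per (tissue group, gene), the replicates calling it a marker.

    Clusters are matched across replicates by their tissue-group
    annotation, not by raw integer label.  Replicates lacking an
    annotation for a group are excluded for that group (logged).
    """
    if not tables:
        raise ValueError("at least one replicate table required")
    counts: dict[tuple[str, str], int] = {}
    for i, tab in enumerate(tables):
        if "tissue_group" not in tab.columns:
            log.warning("replicate %d has no tissue_group annotation; skipped", i)
            continue
        ann = tab[tab["tissue_group"].astype(str) != ""]
        skipped = tab["cluster"].nunique() - ann["cluster"].nunique()
        if skipped:
            log.warning("replicate %d: %d unannotated cluster(s) excluded",
                        i, skipped)
        for grp, gene in ann[["tissue_group", "gene_id"]].itertuples(index=False):
            counts[(grp, gene)] = counts.get((grp, gene), 0) + 1
    out = pd.DataFrame(
        [(g, gene, n) for (g, gene), n in counts.items()],
        columns=["tissue_group", "gene_id", "n_replicates"])
    return out.sort_values(["tissue_group", "n_replicates", "gene_id"],
                           ascending=[True, False, True]).reset_index(drop=True)


def plot_marker_dotplot(top: pd.DataFrame, path) -> None:
    """Dot plot of candidates: size = detection rate, colour = mean count."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genes = top["gene_id"].unique()
    clusters = sorted(top["cluster"].unique())
    gpos = {g: i for i, g in enumerate(genes)}
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(genes)), 0.5 * len(clusters) + 2))
    sc = ax.scatter(
        [gpos[g] for g in top["gene_id"]],
        [clusters.index(c) for c in top["cluster"]],
        s=20 + 200 * top["pct_in"], c=top["mean_in"], cmap="viridis")
    ax.set_xticks(range(len(genes)), genes, rotation=90, fontsize=6)
    ax.set_yticks(range(len(clusters)), [str(c) for c in clusters])
    fig.colorbar(sc, label="mean expression (MIDs)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
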