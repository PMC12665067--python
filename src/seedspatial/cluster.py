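"""Neighbor graphs, spatial Leiden clustering and cluster retention.

Clustering follows the standard binned Stereo-seq recipe: a kNN graph in
PCA space captures expression similarity, an 8-neighborhood grid graph
captures spatial adjacency, and Leiden runs on a convex blend of the
two.  Clusters dominated by bins outside the tissue boundary (background
noise, duplicated tissue from folding) are then discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .errors import EmptyInputError, ParameterError
from .gem import BinnedExpression
from .preprocess import Embedding

log = logging.getLogger(__name__)


@dataclass
class NeighborGraph:
    """Weighted undirected graph over bins (symmetric sparse matrix)."""

    bins: pd.DataFrame
    weights: sp.csr_matrix
    provenance: str     # "expression" | "spatial" | "combined"
    lam: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def expression_knn_graph(embedding: Embedding, k: int = 15) -> NeighborGraph:
    """k-nearest-neighbour graph in embedding space.

    Euclidean kNN, symmetrised by union; edge weight 1 / (1 + distance).
    """
    n = embedding.coordinates.shape[0]
    if not (1 <= k < n):
        raise ParameterError(f"k={k} outside [1, #bins-1] = [1, {n - 1}]")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding.coordinates)
    dist, idx = nn.kneighbors(embedding.coordinates)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    w = 1.0 / (1.0 + dist[:, 1:].ravel())
    W = sp.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    W = W.maximum(W.T)          # union symmetrisation
    W.setdiag(0)
    W.eliminate_zeros()
    return NeighborGraph(bins=embedding.bins, weights=W, provenance="expression")


def spatial_neighbors_graph(bins: pd.DataFrame, expr_graph: NeighborGraph,
                            lam: float = 0.5) -> NeighborGraph:
    """Blend the expression graph with grid adjacency.

    Spatial edges connect bins within Chebyshev distance 1 of each other
    (8-neighborhood).  Each spatial edge carries the mean expression edge
    weight, so ``lam`` balances the two graphs rather than their units;
    the combined graph has weight ``(1 - lam) * expression +
    lam * spatial`` on the edge union.
    """
    if not (0.0 <= lam <= 1.0):
        raise ParameterError(f"lambda must be in [0, 1], got {lam}")
    n = len(bins)
    if n != expr_graph.n_nodes:
        raise ParameterError("bins and expression graph sizes differ")
    index = {(bx, by): i for i, (bx, by) in
             enumerate(zip(bins["bin_x"], bins["bin_y"]))}
    rows, cols = [], []
    for (bx, by), i in index.items():
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                if dx == dy == 0:
                    continue
                j = index.get((bx + dx, by + dy))
                if j is not None:
                    rows.append(i)
                    cols.append(j)
    w_spatial = (expr_graph.weights.data.mean()
                 if expr_graph.weights.nnz else 1.0)
    S = sp.coo_matrix((np.full(len(rows), w_spatial), (rows, cols)),
                      shape=(n, n)).tocsr()
    combined = (1.0 - lam) * expr_graph.weights + lam * S
    combined.eliminate_zeros()
    return NeighborGraph(bins=bins, weights=combined, provenance="combined",
                         lam=lam)


@dataclass
class ClusterAssignment:
    """Per-bin Leiden labels with retention flags and zone annotations."""

    bins: pd.DataFrame
    labels: np.ndarray                      # int, 0..C-1, ordered by size
    resolution: float
    seed: int
    retained: dict[int, bool] = field(default_factory=dict)
    annotation: dict[int, str] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def retained_clusters(self) -> list[int]:
        return [c for c in range(self.n_clusters) if self.retained.get(c, True)]

    def retained_mask(self) -> np.ndarray:
        flags = np.array([self.retained.get(c, True)
                          for c in range(self.n_clusters)])
        return flags[self.labels]

    def to_frame(self) -> pd.DataFrame:
        out = self.bins.copy()
        out["cluster"] = self.labels
        out["retained"] = self.retained_mask()
        out["tissue_group"] = [self.annotation.get(c, "") for c in self.labels]
        return out


def _canonical_order(bins: pd.DataFrame) -> np.ndarray:
    """Bin order by (bin_x, bin_y): makes labels input-order invariant."""
    return np.lexsort((bins["bin_y"].to_numpy(), bins["bin_x"].to_numpy()))


def leiden_cluster(graph: NeighborGraph, resolution: float = 1.0,
                   seed: int = 0) -> ClusterAssignment:
    """Modularity-based Leiden partition of the neighbor graph.

    Deterministic for a fixed seed; labels are relabelled 0..C-1 by
    decreasing cluster size (ties: smallest canonical bin index first).
    """
    n = graph.n_nodes
    if n == 0:
        raise EmptyInputError("cannot cluster an empty graph")
    order = _canonical_order(graph.bins)
    inv = np.empty_like(order)
    inv[order] = np.arange(n)
    W = graph.weights[order][:, order].tocoo()
    mask = W.row < W.col
    edges = list(zip(W.row[mask].tolist(), W.col[mask].tolist()))
    g = ig.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights=W.data[mask].tolist(), resolution_parameter=resolution,
        seed=seed)
    raw = np.asarray(part.membership)
    # canonical relabel: size desc, then first-occurrence (smallest bin index)
    sizes = np.bincount(raw)
    first = np.full(sizes.shape, n)
    for i, lab in enumerate(raw):
        first[lab] = min(first[lab], i)
    order_lab = sorted(range(len(sizes)), key=lambda c: (-sizes[c], first[c]))
    remap = {old: new for new, old in enumerate(order_lab)}
    canon = np.array([remap[c] for c in raw])
    labels = canon[inv]     # back to the caller's bin order
    return ClusterAssignment(bins=graph.bins, labels=labels,
                             resolution=resolution, seed=seed,
                             retained={c: True for c in range(len(sizes))})


def retain_tissue_clusters(
    assignment: ClusterAssignment,
    binned: BinnedExpression,
    tissue_mask: set[tuple[int, int]] | None = None,
    outside_fraction: float = 0.5,
    background_quantile: float = 0.10,
) -> tuple[ClusterAssignment, pd.DataFrame]:
    """Flag background / fold-artifact clusters as discarded.

    With a tissue mask (a set of in-tissue ``(bin_x, bin_y)``), a cluster
    is discarded when more than ``outside_fraction`` of its bins fall
    outside the mask.  Without a mask, a cluster is discarded when its
    median per-bin MID total falls below the ``background_quantile``
    quantile of all bin totals.  Returns the updated assignment and a
    per-cluster report.
    """
    totals = binned.bin_totals()
    coords = list(zip(assignment.bins["bin_x"], assignment.bins["bin_y"]))
    rows = []
    for c in range(assignment.n_clusters):
        sel = assignment.labels == c
        n_bins = int(sel.sum())
        if tissue_mask is not None:
            out_frac = float(np.mean([coords[i] not in tissue_mask
                                      for i in np.flatnonzero(sel)]))
            keep = out_frac <= outside_fraction
            reason = "" if keep else f"outside tissue mask ({out_frac:.0%} of bins)"
            rows.append({"cluster": c, "n_bins": n_bins,
                         "outside_fraction": out_frac,
                         "median_mids": float(np.median(totals[sel])),
                         "retained": keep, "reason": reason})
        else:
            thresh = float(np.quantile(totals, background_quantile))
            med = float(np.median(totals[sel]))
            keep = med >= thresh
            reason = "" if keep else f"median MIDs {med:.0f} below q{background_quantile:.2f}"
            rows.append({"cluster": c, "n_bins": n_bins,
                         "outside_fraction": float("nan"),
                         "median_mids": med, "retained": keep,
                         "reason": reason})
        assignment.retained[c] = keep
        if not keep:
            log.info("cluster %d discarded: %s", c, rows[-1]["reason"])
    return assignment, pd.DataFrame(rows)


def annotate_by_majority(assignment: ClusterAssignment,
                         bin_zones: pd.DataFrame) -> ClusterAssignment:
    """Annotate retained clusters with their majority ground-truth zone.

    ``bin_zones`` has columns bin_x, bin_y, zone (e.g. from
    :meth:`GroundTruth.bin_majority_zones`).
    """
    zmap = {(bx, by): z for bx, by, z in
            zip(bin_zones["bin_x"], bin_zones["bin_y"], bin_zones["zone"])}
    for c in assignment.retained_clusters():
        sel = np.flatnonzero(assignment.labels == c)
        zones = [zmap.get((assignment.bins["bin_x"].iat[i],
                           assignment.bins["bin_y"].iat[i]), "?")
                 for i in sel]
        assignment.annotation[c] = pd.Series(zones).mode().iat[0]
    return assignment


def umap_embed(embedding: Embedding, seed: int = 0) -> np.ndarray:
    """2-D UMAP of the PCA coordinates (visualisation only)."""
    import umap

    n = embedding.coordinates.shape[0]
    reducer = umap.UMAP(n_components=2, random_state=seed,
                        n_neighbors=min(15, max(2, n - 1)))
    return reducer.fit_transform(embedding.coordinates)


def plot_cluster_map(assignment: ClusterAssignment, path) -> None:
    """Static zone map coloured by cluster (retained clusters solid)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    frame = assignment.to_frame()
    for c, grp in frame.groupby("cluster"):
        alpha = 1.0 if assignment.retained.get(c, True) else 0.25
        label = assignment.annotation.get(c, f"cluster {c}")
        ax.scatter(grp["bin_x"], grp["bin_y"], s=8, alpha=alpha, label=label)
    ax.set_aspect("equal")
    ax.invert_yaxis()
    ax.legend(fontsize=6, markerscale=2, loc="upper right")
    fig.savefig(path, dpi=150)
    plt.close(fig)
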