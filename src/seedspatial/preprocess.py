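"""Bin filtering, log1p normalisation and PCA embedding.

Low-signal bins (background noise outside the tissue boundary) are
removed by a minimum-MID threshold before normalisation; the retained
bins are log1p-transformed and embedded with PCA for graph building.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .errors import EmptyResultError, ParameterError
from .gem import BinnedExpression

log = logging.getLogger(__name__)


def filter_bins(binned: BinnedExpression, min_mid: int = 30) -> BinnedExpression:
    """Retain bins whose total MID count is >= ``min_mid`` (inclusive)."""
    if min_mid < 0:
        raise ParameterError(f"min_mid must be >= 0, got {min_mid}")
    totals = binned.bin_totals()
    keep = totals >= min_mid
    n_keep = int(keep.sum())
    log.info("filter_bins: %d of %d bins retained at min_mid=%d",
             n_keep, binned.n_bins, min_mid)
    if n_keep == 0:
        raise EmptyResultError(
            f"min_mid={min_mid} removed all {binned.n_bins} bins; "
            "lower the threshold")
    return binned.subset_bins(keep)


@dataclass
class NormalizedExpression:
    """log1p-transformed expression with the same bin/gene indexing."""

    bin_size: int
    bins: pd.DataFrame
    genes: pd.Index
    values: sp.csr_matrix   # ln(1 + count), sparsity pattern preserved


def normalize_log1p(binned: BinnedExpression) -> NormalizedExpression:
    """Elementwise natural-log(1 + count); zeros stay zero."""
    values = binned.counts.astype(np.float64).copy()
    values.data = np.log1p(values.data)
    return NormalizedExpression(bin_size=binned.bin_size, bins=binned.bins,
                                genes=binned.genes, values=values)


@dataclass
class Embedding:
    """PCA coordinates per bin plus explained-variance fractions."""

    bins: pd.DataFrame
    n_components: int
    coordinates: np.ndarray             # bins x components
    explained_variance_ratio: np.ndarray


def pca_embed(norm: NormalizedExpression, n_components: int = 50,
              seed: int = 0) -> Embedding:
    """PCA of the centred log1p matrix.

    The sign of each component is fixed by forcing its largest-magnitude
    loading positive, so the embedding is deterministic.
    """
    n_bins, n_genes = norm.values.shape
    if not (1 <= n_components <= min(n_bins - 1, n_genes)):
        raise ParameterError(
            f"n_components={n_components} outside [1, min(#bins-1, #genes)]"
            f" = [1, {min(n_bins - 1, n_genes)}]")
    X = np.asarray(norm.values.todense())
    pca = PCA(n_components=n_components, svd_solver="full",
              random_state=seed)
    coords = pca.fit_transform(X)
    # canonical sign: largest-|loading| positive per component
    flip = np.sign(pca.components_[
        np.arange(n_components),
        np.abs(pca.components_).argmax(axis=1)])
    flip[flip == 0] = 1.0
    coords = coords * flip
    return Embedding(bins=norm.bins, n_components=n_components,
                     coordinates=coords,
                     explained_variance_ratio=pca.explained_variance_ratio_)
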