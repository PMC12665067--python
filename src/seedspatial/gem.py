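"""GEM table I/O, BinN aggregation and capture statistics.

A GEM ("gene expression matrix") file is the spatially tagged export of a
DNB capture array: one TSV row per (gene, spot) with the molecule (MID)
count captured at that spot.  Columns are ``geneID``, ``x``, ``y``,
``MIDCount``; ``#`` comment lines are allowed and gzip is autodetected.

Sparse capture is alleviated by grouping adjacent DNBs into N x N bins
(Bin20, Bin50, ...), which is the unit all downstream analysis works on.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import EmptyInputError, GemFormatError, ParameterError

GEM_COLUMNS = ("geneID", "x", "y", "MIDCount")


def _open_maybe_gzip(path):
    """Open a text file, transparently decompressing gzip (by magic bytes)."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_gem(path) -> pd.DataFrame:
    """Read a GEM TSV into a table of (geneID, x, y, MIDCount) records.

    Duplicate (geneID, x, y) rows are summed.  Raises
    :class:`GemFormatError` naming the missing column or the first
    offending line for non-integer / non-positive values.
    """
    with _open_maybe_gzip(path) as fh:
        text = fh.read()
    return parse_gem(text)


def parse_gem(text: str) -> pd.DataFrame:
    """Parse GEM TSV content from a string (see :func:`read_gem`)."""
    df = pd.read_csv(io.StringIO(text), sep="\t", comment="#", dtype=str)
    for col in GEM_COLUMNS:
        if col not in df.columns:
            raise GemFormatError(f"GEM file is missing required column {col!r}")
    df = df[list(GEM_COLUMNS)]
    # line numbers of the data rows in the original file (1-based, incl. header/comments)
    data_line = _data_line_numbers(text, len(df))
    for col in ("x", "y", "MIDCount"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals))
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise GemFormatError(
                f"non-integer value {df[col].iloc[i]!r} in column {col!r} "
                f"at line {data_line[i]}"
            )
        df[col] = vals.astype(np.int64)
    for col, lo, what in (("x", 0, "coordinate"), ("y", 0, "coordinate"),
                          ("MIDCount", 1, "count")):
        bad = df[col] < lo
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise GemFormatError(
                f"invalid {what} {df[col].iloc[i]} in column {col!r} "
                f"at line {data_line[i]} (must be >= {lo})"
            )
    merged = (
        df.groupby(["geneID", "x", "y"], as_index=False, sort=True)["MIDCount"]
        .sum()
    )
    return merged


def _data_line_numbers(text: str, n_rows: int) -> list[int]:
    """1-based file line numbers of the data rows, skipping comments/header."""
    out, seen_header = [], False
    for ln, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#") or not line.strip():
            continue
        if not seen_header:
            seen_header = True
            continue
        out.append(ln)
    # pandas may drop trailing blank lines; align defensively
    return out[:n_rows] if len(out) >= n_rows else out + [-1] * (n_rows - len(out))


def write_gem(gem: pd.DataFrame, path, compress: bool = False) -> None:
    """Write a GEM table as TSV with deterministic (geneID, x, y) ordering."""
    out = gem.sort_values(["geneID", "x", "y"], kind="mergesort")
    path = Path(path)
    opener = gzip.open if compress else open
    with opener(path, "wt") as fh:
        out.to_csv(fh, sep="\t", index=False)


@dataclass
class BinnedExpression:
    """Sparse bins x genes count matrix at a fixed bin size.

    ``bins`` holds one row per occupied bin with integer ``bin_x``/``bin_y``
    indices (``floor(coord / bin_size)``); ``counts`` is CSR with the same
    row order.  Empty bins are simply absent.
    """

    bin_size: int
    bins: pd.DataFrame          # columns bin_x, bin_y
    genes: pd.Index
    counts: sp.csr_matrix       # bins x genes

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def bin_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def total(self) -> int:
        return int(self.counts.sum())

    def subset_bins(self, mask: np.ndarray) -> "BinnedExpression":
        mask = np.asarray(mask)
        return BinnedExpression(
            bin_size=self.bin_size,
            bins=self.bins.loc[mask].reset_index(drop=True),
            genes=self.genes,
            counts=self.counts[mask].tocsr(),
        )

    def to_anndata(self):
        """Convenience view as an AnnData (obs = bins, var = genes)."""
        import anndata as ad

        obs = self.bins.copy()
        obs.index = [f"{bx}_{by}" for bx, by in zip(obs.bin_x, obs.bin_y)]
        obs["total_mids"] = self.bin_totals()
        return ad.AnnData(X=self.counts.copy(), obs=obs,
                          var=pd.DataFrame(index=self.genes))

    def write(self, prefix) -> None:
        """Write as matrix-market triples plus gene/bin index sidecars."""
        from scipy.io import mmwrite

        prefix = Path(prefix)
        mmwrite(str(prefix) + ".counts.mtx", self.counts.tocoo())
        self.bins.to_csv(str(prefix) + ".bins.tsv", sep="\t", index=False)
        pd.Series(self.genes, name="geneID").to_csv(
            str(prefix) + ".genes.tsv", sep="\t", index=False)


def bin_counts(gem: pd.DataFrame, bin_size: int) -> BinnedExpression:
    """Aggregate DNB records into ``bin_size`` x ``bin_size`` bins.

    Total counts are conserved; bin indices are floor(coord / bin_size).
    """
    if bin_size < 1:
        raise ParameterError(f"bin_size must be >= 1, got {bin_size}")
    bx = gem["x"].to_numpy() // bin_size
    by = gem["y"].to_numpy() // bin_size
    genes = pd.Index(sorted(gem["geneID"].unique()), name="geneID")
    gene_code = genes.get_indexer(gem["geneID"])
    bin_key = pd.MultiIndex.from_arrays([bx, by])
    bin_index = bin_key.unique().sortlevel([0, 1])[0]
    bin_code = bin_index.get_indexer(bin_key)
    counts = sp.coo_matrix(
        (gem["MIDCount"].to_numpy(), (bin_code, gene_code)),
        shape=(len(bin_index), len(genes)),
    ).tocsr()
    counts.sum_duplicates()
    bins = pd.DataFrame({
        "bin_x": bin_index.get_level_values(0).astype(np.int64),
        "bin_y": bin_index.get_level_values(1).astype(np.int64),
    })
    return BinnedExpression(bin_size=int(bin_size), bins=bins, genes=genes,
                            counts=counts)


@dataclass
class CaptureStats:
    """Capture-array summary statistics at DNB and bin resolution."""

    n_capturing_dnbs: int
    total_mids: int
    total_gene_dnb_pairs: int
    mids_per_dnb: float
    genes_per_dnb: float
    bin_size: int | None = None
    mids_per_bin: float | None = None
    genes_per_bin: float | None = None
    denominator: str = "occupied"
    rounded: dict = field(default_factory=dict)

    @classmethod
    def from_totals(cls, total_mids: int, n_capturing_dnbs: int,
                    total_gene_dnb_pairs: int | None = None) -> "CaptureStats":
        """Build the DNB-level ratios from already-summarised totals."""
        if n_capturing_dnbs <= 0:
            raise EmptyInputError("n_capturing_dnbs must be positive")
        pairs = total_gene_dnb_pairs if total_gene_dnb_pairs is not None else -1
        mids = total_mids / n_capturing_dnbs
        genes = pairs / n_capturing_dnbs if pairs >= 0 else float("nan")
        stats = cls(
            n_capturing_dnbs=int(n_capturing_dnbs),
            total_mids=int(total_mids),
            total_gene_dnb_pairs=int(pairs),
            mids_per_dnb=mids,
            genes_per_dnb=genes,
        )
        stats.rounded = {"mids_per_dnb": round(mids, 2),
                         "genes_per_dnb": round(genes, 2) if pairs >= 0 else None}
        return stats


def capture_stats(gem: pd.DataFrame, bin_size: int = 20,
                  denominator: str = "occupied",
                  n_bins: int | None = None) -> CaptureStats:
    """Summarise the capture array: MIDs and genes per DNB and per bin.

    A "capturing DNB" is a distinct (x, y) with at least one record.
    Per-bin means divide by occupied bins by default; pass
    ``denominator='fixed'`` with ``n_bins`` to use another denominator
    (e.g. bins under the tissue mask or the full grid).
    """
    if len(gem) == 0:
        raise EmptyInputError("capture_stats requires a non-empty GEM table")
    total_mids = int(gem["MIDCount"].sum())
    dnb = gem[["x", "y"]].drop_duplicates()
    n_dnb = len(dnb)
    n_pairs = len(gem.drop_duplicates(["geneID", "x", "y"]))
    binned = bin_counts(gem, bin_size)
    if denominator == "occupied":
        denom = binned.n_bins
    elif denominator == "fixed":
        if n_bins is None or n_bins < binned.n_bins:
            raise ParameterError("denominator='fixed' needs n_bins >= occupied bins")
        denom = n_bins
    else:
        raise ParameterError(f"unknown denominator {denominator!r}")
    genes_per_occupied = (binned.counts > 0).sum(axis=1)
    mids_per_bin = total_mids / denom
    genes_per_bin = float(np.asarray(genes_per_occupied).sum()) / denom
    stats = CaptureStats(
        n_capturing_dnbs=n_dnb,
        total_mids=total_mids,
        total_gene_dnb_pairs=n_pairs,
        mids_per_dnb=total_mids / n_dnb,
        genes_per_dnb=n_pairs / n_dnb,
        bin_size=int(bin_size),
        mids_per_bin=mids_per_bin,
        genes_per_bin=genes_per_bin,
        denominator=denominator,
    )
    stats.rounded = {
        "mids_per_dnb": round(stats.mids_per_dnb, 2),
        "genes_per_dnb": round(stats.genes_per_dnb, 2),
        "mids_per_bin": round(mids_per_bin, 2),
        "genes_per_bin": round(genes_per_bin, 2),
    }
    return stats
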