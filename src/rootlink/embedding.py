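"""TF-IDF / LSI embedding of the accessibility matrix and KNN metacell
aggregation.

The embedding is the standard scATAC latent semantic indexing: term frequency
(peak count over cell total) times inverse document frequency (cells over
cells detecting the peak), log-scaled, then truncated SVD. The first
component tracks sequencing depth and is excluded from the neighbor metric.
Metacells are greedy KNN neighborhoods whose counts are exact column sums of
their member cells; candidates overlapping an accepted metacell too much are
rejected, which caps redundancy.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg
from scipy.stats import spearmanr
from sklearn.neighbors import NearestNeighbors


@dataclass
class LsiEmbedding:
    """Cell x component LSI embedding.

    ``coords[:, 0]`` is depth-correlated; use :meth:`usable` (components
    2..n) for distance computations.
    """

    coords: np.ndarray            # n_cells x n_components
    singular_values: np.ndarray
    depth_correlation: float      # Spearman of component 1 vs per-cell totals
    barcodes: list[str]

    def usable(self) -> np.ndarray:
        return self.coords[:, 1:]


def tfidf_lsi(atac: sp.spmatrix, barcodes, n_components: int = 30, seed: int = 0) -> LsiEmbedding:
    """LSI embedding of a peak x cell count matrix.

    TF = count / cell total; IDF = n_cells / n_cells_detecting_peak;
    X = log(1 + TF * IDF * 1e4); embedding = truncated SVD of X. Deterministic
    for a fixed seed (the SVD start vector is seeded).
    """
    atac = sp.csc_matrix(atac)
    n_peaks, n_cells = atac.shape
    totals = np.asarray(atac.sum(axis=0)).ravel()
    if (totals == 0).any():
        bad = int(np.argmax(totals == 0))
        raise ValueError(f"all-zero cell at barcode {list(barcodes)[bad]!r}; QC-filter first")
    nonzero_rows = int((np.asarray((atac > 0).sum(axis=1)).ravel() > 0).sum())
    if min(nonzero_rows, n_cells) < n_components:
        raise ValueError("matrix has fewer non-empty rows/columns than n_components")

    tf = atac.multiply(1.0 / totals[None, :])
    df = np.asarray((atac > 0).sum(axis=1)).ravel()
    idf = np.where(df > 0, n_cells / np.maximum(df, 1), 0.0)
    x = tf.multiply(idf[:, None]).tocsr()
    x.data = np.log1p(x.data * 1e4)

    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(min(x.shape))
    u, s, vt = scipy.sparse.linalg.svds(x, k=n_components, v0=v0)
    order = np.argsort(-s)
    s, vt = s[order], vt[order]
    coords = (vt * s[:, None]).T  # cells x components
    # fix the sign of each component deterministically
    for j in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    depth_corr = float(spearmanr(coords[:, 0], totals).statistic)
    return LsiEmbedding(coords, s, depth_corr, list(barcodes))


@dataclass
class MetacellSet:
    """Greedy KNN metacells over one embedding.

    ``matrix`` is peak x metacell with entries that are exact sums of the
    member cells' columns; ``members`` lists member cell indices per
    metacell; ``composition`` summarizes condition / cell-type makeup when a
    cell table is supplied.
    """

    members: list[np.ndarray]
    matrix: sp.csr_matrix
    barcodes: list[str]
    composition: pd.DataFrame | None = None

    @property
    def n_metacells(self) -> int:
        return len(self.members)


def make_metacells(
    embedding: LsiEmbedding,
    atac: sp.spmatrix,
    k: int = 50,
    max_overlap: float = 0.8,
    cell_table: pd.DataFrame | None = None,
) -> MetacellSet:
    """Aggregate cells into greedy KNN metacells.

    Cells are visited in canonical barcode order; each seed proposes itself
    plus its k-1 nearest neighbors (Euclidean on LSI components 2..n), and the
    proposal is accepted unless it shares more than ``max_overlap`` of its
    members with an already accepted metacell. Aggregated counts are exact
    member-column sums.
    """
    atac = sp.csc_matrix(atac)
    n_cells = atac.shape[1]
    if k > n_cells:
        raise ValueError(f"k={k} exceeds the number of cells ({n_cells})")
    coords = embedding.usable()
    if coords.shape[0] != n_cells:
        raise ValueError("embedding and matrix disagree on cell count")

    order = np.argsort(np.asarray(embedding.barcodes, dtype=object), kind="stable")
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    _, neigh = nn.kneighbors(coords[order])

    members: list[np.ndarray] = []
    accepted_rows: list[np.ndarray] = []
    for row in neigh:
        cand = np.unique(row)
        if accepted_rows:
            overlap = np.array([mask[cand].sum() for mask in accepted_rows])
            if (overlap > max_overlap * len(cand)).any():
                continue
        mask = np.zeros(n_cells, dtype=bool)
        mask[cand] = True
        accepted_rows.append(mask)
        members.append(np.sort(cand))

    cols = []
    for m in members:
        cols.append(np.asarray(atac[:, m].sum(axis=1)).ravel())
    matrix = sp.csr_matrix(np.column_stack(cols)) if cols else sp.csr_matrix((atac.shape[0], 0))

    composition = None
    if cell_table is not None:
        bc = np.asarray(embedding.barcodes, dtype=object)
        table = cell_table.set_index("barcode")
        rows = []
        for mi, m in enumerate(members):
            sub = table.loc[bc[m]]
            rows.append(
                {
                    "metacell": mi,
                    "n_cells": len(m),
                    "condition": sub["condition"].mode().iat[0],
                    "majority_type": sub["rna_label"].mode().iat[0],
                    "majority_fraction": float((sub["rna_label"] == sub["rna_label"].mode().iat[0]).mean()),
                }
            )
        composition = pd.DataFrame(rows)
    return MetacellSet(members, matrix, list(embedding.barcodes), composition)


def aggregate_matrix(matrix: sp.spmatrix, metacells: MetacellSet) -> sp.csr_matrix:
    """Sum any feature x cell matrix over the metacell memberships (for
    aggregating RNA on the same cell grouping as the ATAC metacells)."""
    matrix = sp.csc_matrix(matrix)
    cols = [np.asarray(matrix[:, m].sum(axis=1)).ravel() for m in metacells.members]
    if not cols:
        return sp.csr_matrix((matrix.shape[0], 0))
    return sp.csr_matrix(np.column_stack(cols))
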