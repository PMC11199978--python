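"""ATAC-derived gene activity: fragment counts over gene body + upstream window."""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._intervals import ChromFragmentIndex
from .types import FragmentFrame, GeneModel

logger = logging.getLogger("rootlink")

DEFAULT_UPSTREAM = 2_000


def gene_window(gene: GeneModel, upstream: int = DEFAULT_UPSTREAM) -> tuple[int, int]:
    """Strand-aware counting window: gene body extended ``upstream`` bp past
    the TSS, clipped at 0."""
    if gene.strand == "+":
        return max(0, gene.start - upstream), gene.end
    return gene.start, gene.end + upstream


def gene_activity_matrix(
    fragments,
    gene_models: Sequence[GeneModel],
    barcodes: Sequence[str],
    upstream: int = DEFAULT_UPSTREAM,
) -> sp.csr_matrix:
    """Sparse gene x cell matrix of fragment counts over each gene's body
    plus ``upstream`` bp beyond the TSS.

    A fragment contributes its ``count`` to every gene window it overlaps by
    at least 1 bp. Fragments whose barcode is not in ``barcodes`` are skipped
    (tallied in a single warning).
    """
    frame = fragments if isinstance(fragments, FragmentFrame) else FragmentFrame.from_fragments(fragments)
    bc_index = pd.Index(list(barcodes))
    codes = bc_index.get_indexer(frame.barcode)
    n_unknown = int((codes < 0).sum())
    if n_unknown:
        logger.warning("gene_activity_matrix: %d fragments with unknown barcodes skipped", n_unknown)
    index = ChromFragmentIndex(frame, codes)

    n_cells = len(bc_index)
    rows, cols, vals = [], [], []
    for gi, gene in enumerate(gene_models):
        ws, we = gene_window(gene, upstream)
        _, _, fc, fn = index.query(gene.chrom, ws, we)
        known = fc >= 0
        if not known.any():
            continue
        per_cell = np.bincount(fc[known], weights=fn[known], minlength=n_cells)
        nz = np.nonzero(per_cell)[0]
        rows.append(np.full(len(nz), gi, dtype=np.int64))
        cols.append(nz)
        vals.append(per_cell[nz])
    if rows:
        mat = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(len(gene_models), n_cells),
        )
    else:
        mat = sp.coo_matrix((len(gene_models), n_cells))
    return mat.tocsr()
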