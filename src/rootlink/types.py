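"""Shared genomic domain types.

All coordinates are 0-based half-open (BED convention) everywhere inside the
package; GTF/GFF ingestion in :mod:`rootlink.io` is the single conversion point.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware transcription start site.

    ``tss`` is the 5' end: ``start`` on the + strand and ``end - 1`` on the
    - strand (both 0-based positions).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.gene_id)


@dataclass(frozen=True)
class Fragment:
    """One ATAC fragment record (chrom, start, end, barcode, count)."""

    chrom: str
    start: int
    end: int
    barcode: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"fragment end must exceed start at {self.chrom}:{self.start}")
        if self.count <= 0:
            raise ValueError("fragment count must be positive")

    @property
    def length(self) -> int:
        return self.end - self.start


class FragmentFrame:
    """Columnar fragment store for vectorised interval arithmetic.

    Holds the same records as a stream of :class:`Fragment` objects but as
    numpy arrays, which is what the QC and gene-activity kernels operate on.
    """

    def __init__(
        self,
        chrom: np.ndarray,
        start: np.ndarray,
        end: np.ndarray,
        barcode: np.ndarray,
        count: np.ndarray,
    ):
        n = len(start)
        if not (len(chrom) == len(end) == len(barcode) == len(count) == n):
            raise ValueError("fragment columns must share length")
        # categorical chrom/barcode keeps multi-million fragment sets compact
        self.chrom = chrom if isinstance(chrom, pd.Categorical) else np.asarray(chrom)
        self.start = np.asarray(start, dtype=np.int64)
        self.end = np.asarray(end, dtype=np.int64)
        self.barcode = barcode if isinstance(barcode, pd.Categorical) else np.asarray(barcode)
        self.count = np.asarray(count, dtype=np.int64)
        if n and ((self.end <= self.start).any()):
            raise ValueError("fragment end must exceed start")

    def __len__(self) -> int:
        return len(self.start)

    @classmethod
    def from_fragments(cls, fragments) -> "FragmentFrame":
        recs = list(fragments)
        return cls(
            np.array([f.chrom for f in recs], dtype=object),
            np.array([f.start for f in recs], dtype=np.int64),
            np.array([f.end for f in recs], dtype=np.int64),
            np.array([f.barcode for f in recs], dtype=object),
            np.array([f.count for f in recs], dtype=np.int64),
        )

    def to_fragments(self) -> list[Fragment]:
        return [
            Fragment(c, int(s), int(e), b, int(n))
            for c, s, e, b, n in zip(self.chrom, self.start, self.end, self.barcode, self.count)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "barcode": self.barcode,
                "count": self.count,
            }
        )


@dataclass
class MultiomeMatrix:
    """Paired sparse RNA (gene x cell) and ATAC (peak x cell) count matrices
    over one shared, duplicate-free barcode ordering."""

    barcodes: list[str]
    genes: list[str]
    peaks: list[GenomicInterval]
    rna: sp.csr_matrix
    atac: sp.csr_matrix

    def __post_init__(self) -> None:
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes")
        if self.rna.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError("rna matrix shape does not match genes x barcodes")
        if self.atac.shape != (len(self.peaks), len(self.barcodes)):
            raise ValueError("atac matrix shape does not match peaks x barcodes")
        if self.rna.nnz and self.rna.data.min() < 0:
            raise ValueError("negative RNA counts")
        if self.atac.nnz and self.atac.data.min() < 0:
            raise ValueError("negative ATAC counts")

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def subset_cells(self, keep_barcodes) -> "MultiomeMatrix":
        """Restrict both modalities to ``keep_barcodes`` (order preserved
        from the current barcode ordering)."""
        keep = set(keep_barcodes)
        idx = [i for i, b in enumerate(self.barcodes) if b in keep]
        return MultiomeMatrix(
            barcodes=[self.barcodes[i] for i in idx],
            genes=self.genes,
            peaks=self.peaks,
            rna=self.rna[:, idx].tocsr(),
            atac=self.atac[:, idx].tocsr(),
        )


CELL_TABLE_COLUMNS = [
    "barcode",
    "condition",
    "rna_label",
    "atac_label",
    "n_count_rna",
    "n_count_atac",
    "n_genes",
    "n_peaks",
    "nucleosome_signal",
    "tss_enrichment",
]


def make_cell_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and order a per-barcode cell annotation/QC table."""
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    if df["barcode"].duplicated().any():
        raise ValueError("duplicate barcodes in cell table")
    bad = ~df["condition"].isin(["control", "stress"])
    if bad.any():
        raise ValueError(f"unknown conditions: {sorted(df.loc[bad, 'condition'].unique())}")
    for col in ["n_count_rna", "n_count_atac", "n_genes", "n_peaks"]:
        if (df[col] < 0).any():
            raise ValueError(f"negative values in {col}")
    return df[CELL_TABLE_COLUMNS].reset_index(drop=True)
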