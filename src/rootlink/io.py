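"""Readers and writers for the plain-text formats the pipeline touches.

Matrix Market triplets (10x-style matrix + features + barcodes), BED3+,
GTF/GFF3 gene records and 5-column fragment files. All readers return
0-based half-open coordinates; GTF/GFF ingestion is the only place a
1-based inclusive convention is converted.
"""
from __future__ import annotations

import gzip
import io as _io
import logging
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import Fragment, GeneModel, GenomicInterval

logger = logging.getLogger("rootlink")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# Matrix Market triplet trio


def read_triplet_matrix(matrix_path, features_path, barcodes_path):
    """Read a 10x-style triplet export.

    Returns ``(matrix, feature_names, barcode_names)`` where ``matrix`` is a
    CSR feature x cell matrix. Raises :class:`FormatError` when the features
    or barcodes line counts disagree with the Matrix Market header.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"{matrix_path}: not a valid Matrix Market file ({exc})")
    mat = sp.csr_matrix(mat)
    features = _read_single_column(features_path)
    barcodes = _read_single_column(barcodes_path)
    if mat.shape[0] != len(features):
        raise FormatError(
            f"{features_path}: {len(features)} features but matrix declares {mat.shape[0]} rows"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix declares {mat.shape[1]} columns"
        )
    return mat, features, barcodes


def write_triplet_matrix(matrix, features, barcodes, matrix_path, features_path, barcodes_path):
    """Write the triplet trio; inverse of :func:`read_triplet_matrix`."""
    matrix = sp.coo_matrix(matrix)
    if matrix.shape != (len(features), len(barcodes)):
        raise ValueError("matrix shape does not match features x barcodes")
    scipy.io.mmwrite(str(matrix_path), matrix, field="integer" if np.issubdtype(matrix.dtype, np.integer) else None)
    Path(features_path).write_text("".join(f"{f}\n" for f in features))
    Path(barcodes_path).write_text("".join(f"{b}\n" for b in barcodes))


def _read_single_column(path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# BED


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3+ into intervals, preserving file order."""
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = parts[3] if len(parts) > 3 else None
            out.append(GenomicInterval(chrom, start, end, name=name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "wt") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


# ---------------------------------------------------------------------------
# GTF / GFF3 gene records


def _gtf_gene_id(attributes: str) -> str | None:
    # GTF: gene_id "AT1G01010"; GFF3: ID=gene:AT1G01010 or ID=AT1G01010
    attributes = attributes.strip()
    if "gene_id" in attributes:
        rest = attributes.split("gene_id", 1)[1].strip()
        if rest.startswith('"'):
            return rest[1:].split('"', 1)[0]
        return rest.split(";", 1)[0].strip()
    for field in attributes.split(";"):
        field = field.strip()
        if field.startswith("ID="):
            val = field[3:]
            return val.split(":", 1)[1] if val.startswith("gene:") else val
    return None


def read_gene_models(path, feature_types=("gene",)) -> list[GeneModel]:
    """Read gene-level records from GTF or GFF3.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Records without a usable strand are skipped with a warning.
    """
    genes: list[GeneModel] = []
    skipped = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: fewer than 9 columns")
            chrom, _source, ftype, start1, end1, _score, strand, _frame, attrs = parts[:9]
            if ftype not in feature_types:
                continue
            if strand not in ("+", "-"):
                skipped += 1
                continue
            try:
                start, end = int(start1) - 1, int(end1)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates")
            gene_id = _gtf_gene_id(attrs)
            if gene_id is None:
                skipped += 1
                continue
            genes.append(GeneModel(gene_id, chrom, start, end, strand))
    if skipped:
        logger.warning("read_gene_models: skipped %d records lacking strand or gene id", skipped)
    return genes


def write_gene_models_gtf(genes: Iterable[GeneModel], path) -> None:
    with open(path, "wt") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\tsynthetic\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f'gene_id "{g.gene_id}";\n'
            )


# ---------------------------------------------------------------------------
# Fragments


def read_fragments(path) -> Iterator[Fragment]:
    """Stream a 5-column fragments file (optionally gzipped), in file order.

    '#' comment lines are skipped. Non-integer coordinates raise
    :class:`FormatError` with the offending line number.
    """
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: fewer than 5 columns")
            try:
                start, end, count = int(parts[1]), int(parts[2]), int(parts[4])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates or count")
            yield Fragment(parts[0], start, end, parts[3], count)


def write_fragments(fragments: Iterable[Fragment], path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.barcode}\t{f.count}\n")


# ---------------------------------------------------------------------------
# Generic TSV output (all tabular outputs carry a header row)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
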