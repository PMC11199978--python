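"""Preprocessing: cross-batch peak merging, peak width filtering, per-cell
ATAC quality metrics (nucleosome signal, TSS enrichment) and cell filtering.

All filter inequalities are strict, matching the published thresholds
(counts between 1,000 and 100,000/25,000 exclusive, nucleosome signal < 2,
TSS enrichment > 1, peak width strictly between 20 and 10,000 bp).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import Fragment, FragmentFrame, GeneModel, GenomicInterval


@dataclass(frozen=True)
class QcThresholds:
    max_count_atac: float = 100_000
    max_count_rna: float = 25_000
    min_count_atac: float = 1_000
    min_count_rna: float = 1_000
    max_nucleosome_signal: float = 2.0
    min_tss_enrichment: float = 1.0
    min_peak_width: int = 20      # exclusive
    max_peak_width: int = 10_000  # exclusive

    def __post_init__(self) -> None:
        if not (self.min_count_atac < self.max_count_atac):
            raise ValueError("ATAC count bounds inverted")
        if not (self.min_count_rna < self.max_count_rna):
            raise ValueError("RNA count bounds inverted")
        if not (self.min_peak_width < self.max_peak_width):
            raise ValueError("peak width bounds inverted")


# Fragment-length bands for the nucleosome signal: sub-nucleosomal vs
# mononucleosomal (one nucleosome protects ~147 bp).
SUBNUCLEOSOMAL_MAX = 147   # lengths < 147 are sub-nucleosomal
MONONUCLEOSOME_MAX = 294   # lengths in [147, 294] are mononucleosomal

TSS_CENTER_HALF = 100      # center window [tss-100, tss+100)
TSS_FLANK_INNER = 1_900    # flanks [tss-2000, tss-1900) and [tss+1900, tss+2000)
TSS_FLANK_OUTER = 2_000


def merge_peaks(*peak_sets: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union-merge intersecting intervals across any number of batches.

    Output is sorted by (chrom, start) and pairwise non-overlapping. Intervals
    that merely touch (end == start) are NOT merged: under half-open
    coordinates they share no position.
    """
    pooled: list[GenomicInterval] = []
    for batch in peak_sets:
        pooled.extend(batch)
    if not pooled:
        return []
    pooled.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = pooled[0].chrom, pooled[0].start, pooled[0].end
    for iv in pooled[1:]:
        if iv.chrom == cur_chrom and iv.start < cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return merged


def filter_peaks_by_width(
    peaks: Iterable[GenomicInterval], thresholds: QcThresholds | None = None
) -> list[GenomicInterval]:
    """Retain peaks with min_peak_width < width < max_peak_width (both strict)."""
    thr = thresholds or QcThresholds()
    return [p for p in peaks if thr.min_peak_width < p.width < thr.max_peak_width]


def _as_frame(fragments) -> FragmentFrame:
    if isinstance(fragments, FragmentFrame):
        return fragments
    return FragmentFrame.from_fragments(fragments)


def compute_nucleosome_signal(fragments, barcodes: Sequence[str]) -> pd.Series:
    """Per-cell ratio of mononucleosomal (147-294 bp) to sub-nucleosomal
    (< 147 bp) fragment counts. Cells with no sub-nucleosomal fragments get
    +inf (they fail the < 2 cutoff)."""
    frame = _as_frame(fragments)
    barcodes = list(barcodes)
    bc_index = pd.Index(barcodes)
    codes = bc_index.get_indexer(frame.barcode)
    known = codes >= 0
    lengths = frame.end - frame.start
    counts = frame.count
    sub = np.bincount(
        codes[known & (lengths < SUBNUCLEOSOMAL_MAX)],
        weights=counts[known & (lengths < SUBNUCLEOSOMAL_MAX)],
        minlength=len(barcodes),
    )
    mono_mask = known & (lengths >= SUBNUCLEOSOMAL_MAX) & (lengths <= MONONUCLEOSOME_MAX)
    mono = np.bincount(codes[mono_mask], weights=counts[mono_mask], minlength=len(barcodes))
    with np.errstate(divide="ignore", invalid="ignore"):
        signal = np.where(sub > 0, mono / np.maximum(sub, 1e-300), np.inf)
    signal = np.where((sub == 0) & (mono == 0), np.inf, signal)
    return pd.Series(signal, index=bc_index, name="nucleosome_signal")


def compute_tss_enrichment(
    fragments, gene_models: Sequence[GeneModel], barcodes: Sequence[str]
) -> pd.Series:
    """Per-cell TSS enrichment: mean per-base fragment coverage in the
    [tss-100, tss+100) windows over all TSSs, divided by mean coverage in the
    distal flanks [tss-2000, tss-1900) and [tss+1900, tss+2000).

    Zero flank coverage yields 0 when the center is also empty and +inf
    otherwise (such cells pass the > 1 cutoff).
    """
    from ._intervals import ChromFragmentIndex, overlap_bp

    if not gene_models:
        raise ValueError("compute_tss_enrichment requires at least one gene model")
    frame = _as_frame(fragments)
    barcodes = list(barcodes)
    bc_index = pd.Index(barcodes)
    codes = bc_index.get_indexer(frame.barcode)
    index = ChromFragmentIndex(frame, codes)

    center = np.zeros(len(barcodes))
    flank = np.zeros(len(barcodes))
    n_tss = 0
    for g in gene_models:
        t = g.tss
        n_tss += 1
        fs, fe, fc, fn = index.query(g.chrom, t - TSS_FLANK_OUTER, t + TSS_FLANK_OUTER)
        known = fc >= 0
        if not known.any():
            continue
        fs, fe, fc, fn = fs[known], fe[known], fc[known], fn[known]
        c_ov = overlap_bp(fs, fe, t - TSS_CENTER_HALF, t + TSS_CENTER_HALF)
        f_ov = overlap_bp(fs, fe, t - TSS_FLANK_OUTER, t - TSS_FLANK_INNER)
        f_ov = f_ov + overlap_bp(fs, fe, t + TSS_FLANK_INNER, t + TSS_FLANK_OUTER)
        np.add.at(center, fc, fn * c_ov)
        np.add.at(flank, fc, fn * f_ov)

    center_mean = center / (2 * TSS_CENTER_HALF * n_tss)
    flank_mean = flank / (2 * (TSS_FLANK_OUTER - TSS_FLANK_INNER) * n_tss)
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = np.where(flank_mean > 0, center_mean / np.maximum(flank_mean, 1e-300), np.inf)
    enr = np.where(center_mean == 0, 0.0, enr)
    return pd.Series(enr, index=bc_index, name="tss_enrichment")


_QC_METRICS = [
    "n_count_atac",
    "n_count_rna",
    "nucleosome_signal",
    "tss_enrichment",
]


def filter_cells(cell_table: pd.DataFrame, thresholds: QcThresholds | None = None) -> list[str]:
    """Return barcodes passing all six strict QC inequalities."""
    thr = thresholds or QcThresholds()
    for col in _QC_METRICS:
        if col not in cell_table.columns:
            raise ValueError(f"cell table missing metric column {col!r}")
        bad = cell_table[col].isna()
        if bad.any():
            bc = cell_table.loc[bad, "barcode"].iloc[0]
            raise ValueError(f"missing {col} for barcode {bc}")
    keep = (
        (cell_table["n_count_atac"] < thr.max_count_atac)
        & (cell_table["n_count_atac"] > thr.min_count_atac)
        & (cell_table["n_count_rna"] < thr.max_count_rna)
        & (cell_table["n_count_rna"] > thr.min_count_rna)
        & (cell_table["nucleosome_signal"] < thr.max_nucleosome_signal)
        & (cell_table["tss_enrichment"] > thr.min_tss_enrichment)
    )
    return cell_table.loc[keep, "barcode"].tolist()
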