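"""Peak merging, width filtering, per-cell QC metrics and cell filtering."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootlink import (
    Fragment,
    GeneModel,
    GenomicInterval,
    QcThresholds,
    compute_nucleosome_signal,
    compute_tss_enrichment,
    filter_cells,
    filter_peaks_by_width,
    merge_peaks,
)


# ---------------------------------------------------------------------------
# merge_peaks


def test_merge_overlapping():
    merged = merge_peaks(
        [GenomicInterval("chr1", 100, 200)], [GenomicInterval("chr1", 150, 300)]
    )
    assert [(m.chrom, m.start, m.end) for m in merged] == [("chr1", 100, 300)]


def test_merge_adjacency_not_merged():
    merged = merge_peaks(
        [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 200, 300)]
    )
    assert [(m.start, m.end) for m in merged] == [(100, 200), (200, 300)]


def _merge_oracle(intervals):
    """Connected components of the strict-overlap graph (touching intervals
    share no base under half-open coordinates, so they are separate)."""
    out = []
    by_chrom = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = by_chrom[chrom]
        n = len(ivs)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if ivs[i].start < ivs[j].end and ivs[j].start < ivs[i].end:
                    parent[find(i)] = find(j)
        comps = {}
        for i in range(n):
            comps.setdefault(find(i), []).append(ivs[i])
        for members in comps.values():
            out.append((chrom, min(m.start for m in members), max(m.end for m in members)))
    out.sort()
    return out


def test_merge_matches_per_base_oracle(rng):
    intervals = [
        GenomicInterval(f"chr{rng.integers(1, 4)}", int(s), int(s) + int(w))
        for s, w in zip(rng.integers(0, 5_000, 500), rng.integers(1, 120, 500))
    ]
    merged = merge_peaks(intervals)
    assert [(m.chrom, m.start, m.end) for m in merged] == _merge_oracle(intervals)


@settings(derandomize=True, max_examples=30)
@given(
    st.lists(
        st.tuples(st.integers(0, 400), st.integers(1, 60)).map(
            lambda t: GenomicInterval("chr1", t[0], t[0] + t[1])
        ),
        min_size=1,
        max_size=30,
    )
)
def test_merge_properties(intervals):
    merged = merge_peaks(intervals)
    # sorted, pairwise non-overlapping, covering exactly the union of bases
    for a, b in zip(merged, merged[1:]):
        assert (a.chrom, a.start) <= (b.chrom, b.start)
        assert a.end <= b.start or a.chrom != b.chrom
    assert [(m.chrom, m.start, m.end) for m in merged] == _merge_oracle(intervals)


# ---------------------------------------------------------------------------
# width filter


def test_width_filter_strict_bounds():
    peaks = [
        GenomicInterval("chr1", 0, 20, "w20"),
        GenomicInterval("chr1", 0, 21, "w21"),
        GenomicInterval("chr1", 0, 9_999, "w9999"),
        GenomicInterval("chr1", 0, 10_000, "w10000"),
    ]
    kept = filter_peaks_by_width(peaks)
    assert [p.name for p in kept] == ["w21", "w9999"]


# ---------------------------------------------------------------------------
# per-cell metrics


def test_nucleosome_signal_hand_case():
    frags = [
        Fragment("chr1", 0, 100, "A", 1),     # sub-nucleosomal (100)
        Fragment("chr1", 0, 146, "A", 1),     # sub-nucleosomal (146)
        Fragment("chr1", 0, 200, "A", 1),     # mononucleosomal (200)
        Fragment("chr1", 0, 147, "B", 1),     # mononucleosomal (147)
        Fragment("chr1", 0, 500, "B", 1),     # neither band
    ]
    ns = compute_nucleosome_signal(frags, ["A", "B", "C"])
    assert ns["A"] == pytest.approx(1.0 / 2.0)
    assert np.isinf(ns["B"])  # no sub-nucleosomal fragments
    assert np.isinf(ns["C"])  # no fragments at all: undefined, fails QC


def test_tss_enrichment_hand_case():
    gene = GeneModel("G", "chr1", 50_000, 52_000, "+")  # tss = 50_000
    frags = [
        Fragment("chr1", 49_990, 50_010, "A", 1),  # center
        Fragment("chr1", 49_950, 50_050, "A", 1),  # center
        Fragment("chr1", 48_050, 48_090, "A", 1),  # left flank [48000,48100)
        Fragment("chr1", 51_910, 51_950, "A", 1),  # right flank [51900,52000)
    ]
    enr = compute_tss_enrichment(frags, [gene], ["A"])
    # per-base coverage: center (20 + 100) / 200 = 0.6; flanks (40 + 40) / 200 = 0.4
    assert enr["A"] == pytest.approx(1.5)


def test_tss_enrichment_no_flank_coverage_is_inf():
    gene = GeneModel("G", "chr1", 50_000, 52_000, "+")
    frags = [Fragment("chr1", 49_990, 50_010, "A", 1)]
    enr = compute_tss_enrichment(frags, [gene], ["A"])
    assert np.isinf(enr["A"])


# ---------------------------------------------------------------------------
# filter_cells


def _boundary_table():
    rows = []
    i = 0
    for rna in (999, 1000, 1001, 24_999, 25_000, 25_001):
        for atac in (999, 1000, 1001, 99_999, 100_000, 100_001):
            for ns in (1.99, 2.0, 2.01):
                for tss in (0.99, 1.0, 1.01):
                    rows.append(
                        {
                            "barcode": f"bc{i:04d}",
                            "n_count_rna": rna,
                            "n_count_atac": atac,
                            "nucleosome_signal": ns,
                            "tss_enrichment": tss,
                        }
                    )
                    i += 1
    return pd.DataFrame(rows)


def test_filter_cells_strict_inequalities():
    df = _boundary_table()
    kept = set(filter_cells(df))
    expected = set(
        df.loc[
            (df["n_count_rna"] > 1000)
            & (df["n_count_rna"] < 25_000)
            & (df["n_count_atac"] > 1000)
            & (df["n_count_atac"] < 100_000)
            & (df["nucleosome_signal"] < 2.0)
            & (df["tss_enrichment"] > 1.0),
            "barcode",
        ]
    )
    assert kept == expected
    # a cell exactly on any boundary is dropped
    on_boundary = df[(df["n_count_rna"] == 1000)]
    assert not (set(on_boundary["barcode"]) & kept)


def test_filter_cells_missing_metric_names_barcode():
    df = _boundary_table().head(3)
    df.loc[1, "tss_enrichment"] = np.nan
    with pytest.raises(ValueError, match="bc0001"):
        filter_cells(df)


def test_thresholds_validation():
    with pytest.raises(ValueError):
        QcThresholds(min_count_rna=30_000)
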