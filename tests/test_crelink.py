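"""Gene-linked cCRE construction, hot-point selection and CNS overlap."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rootlink import (
    GeneModel,
    GenomicInterval,
    annotate_promoter_peaks,
    build_gl_ccres,
    cns_overlap,
    compare_cns_fractions,
    linkage_counts,
    nearest_gene,
    pearson_with_p,
    promoter_window,
    select_hgl_ccres,
    stress_specific_gl_ccres,
)


# ---------------------------------------------------------------------------
# promoter annotation


def test_promoter_window_strand_cases():
    plus = GeneModel("G", "chr1", 10_000, 12_000, "+")     # tss 10000
    minus = GeneModel("G", "chr1", 10_000, 12_000, "-")    # tss 11999
    assert promoter_window(plus) == (8_000, 10_200)
    assert promoter_window(minus) == (11_800, 14_000)
    near = GeneModel("G", "chr1", 500, 900, "+")
    assert promoter_window(near) == (0, 700)


def test_annotate_promoters_brute_force(rng):
    genes = [
        GeneModel(
            f"G{i}",
            f"chr{rng.integers(1, 3)}",
            int(s := rng.integers(3_000, 80_000)),
            int(s + rng.integers(500, 3_000)),
            "+" if rng.random() < 0.5 else "-",
        )
        for i in range(15)
    ]
    peaks = [
        GenomicInterval(f"chr{rng.integers(1, 3)}", int(s), int(s) + 300, f"pk{i}")
        for i, s in enumerate(rng.integers(0, 85_000, 60))
    ]
    out = annotate_promoter_peaks(peaks, genes)
    for p in peaks:
        hits = sorted(
            g.gene_id
            for g in genes
            if g.chrom == p.chrom
            and p.start < promoter_window(g)[1]
            and promoter_window(g)[0] < p.end
        )
        assert out.get(p.name, []) == hits if hits else p.name not in out


def test_promoter_peak_can_serve_two_genes():
    g1 = GeneModel("Gb", "chr1", 10_000, 12_000, "+")
    g2 = GeneModel("Ga", "chr1", 9_000, 9_500, "-")  # tss 9499, window up to 11500
    peak = GenomicInterval("chr1", 9_400, 9_600, "pk")
    assert annotate_promoter_peaks([peak], [g1, g2]) == {"pk": ["Ga", "Gb"]}


def test_nearest_gene_ties_and_empty(caplog):
    genes = [
        GeneModel("Gb", "chr1", 1_000, 2_000, "+"),   # tss 1000
        GeneModel("Ga", "chr1", 3_000, 4_000, "-"),   # tss 3999... not a tie
    ]
    # midpoint 2500: distances 1500 vs 1499 -> Ga
    assert nearest_gene(GenomicInterval("chr1", 2_400, 2_600, "pk"), genes) == "Ga"
    tie = [
        GeneModel("Gz", "chr1", 2_000, 2_500, "+"),   # tss 2000, distance 500
        GeneModel("Ga", "chr1", 3_000, 3_500, "+"),   # tss 3000, distance 500
    ]
    assert nearest_gene(GenomicInterval("chr1", 2_400, 2_600, "pk"), tie) == "Ga"
    with caplog.at_level("WARNING"):
        assert nearest_gene(GenomicInterval("chr9", 0, 100, "pk"), genes) is None
    assert any("chr9" in m for m in caplog.messages)


# ---------------------------------------------------------------------------
# correlation predicate


def test_pearson_with_p_matches_scipy(rng):
    for n in (5, 12, 40):
        x, y = rng.standard_normal(n), rng.standard_normal(n)
        r, p = pearson_with_p(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)
    assert np.isnan(pearson_with_p(np.ones(10), rng.standard_normal(10))[0])
    assert np.isnan(pearson_with_p(np.arange(2.0), np.arange(2.0))[0])
    x = rng.standard_normal(8)
    r, p = pearson_with_p(x, 2 * x + 1)
    assert r == pytest.approx(1.0, abs=1e-12)
    assert p < 1e-30


def _link_fixture(rng, n_pairs=20, n_units=20):
    """One (promoter, cCRE) pair per gene with random unit profiles."""
    gene_names = [f"g{i}" for i in range(n_pairs)]
    peak_names = [f"prom{i}" for i in range(n_pairs)] + [f"cre{i}" for i in range(n_pairs)]
    expr = rng.poisson(8.0, size=(n_pairs, n_units)).astype(float)
    acc = rng.poisson(8.0, size=(2 * n_pairs, n_units)).astype(float)
    # plant a few strong links so both branches of the predicate occur
    for i in range(0, n_pairs, 4):
        acc[n_pairs + i] = expr[i] * 3 + rng.poisson(1.0, n_units)
    pairs = pd.DataFrame(
        {
            "peak_a": [f"prom{i}" for i in range(n_pairs)],
            "peak_b": [f"cre{i}" for i in range(n_pairs)],
            "score": rng.random(n_pairs),
        }
    )
    promoter_map = {f"prom{i}": [f"g{i}"] for i in range(n_pairs)}
    gene_of_target = {f"prom{i}": f"g{i}" for i in range(n_pairs)}
    return pairs, promoter_map, expr, acc, gene_names, peak_names, gene_of_target


def _norm(M):
    totals = M.sum(axis=0)
    totals = np.where(totals == 0, 1.0, totals)
    return np.log1p(M / totals[None, :] * 1e4)


def test_build_gl_ccres_matches_predicate_oracle(rng):
    pairs, promoter_map, expr, acc, genes, peaks, got = _link_fixture(rng)
    out = build_gl_ccres(pairs, promoter_map, expr, acc, genes, peaks, gene_of_target=got)
    ne, na = _norm(expr), _norm(acc)
    expected = set()
    for i in range(len(pairs)):
        r, p = stats.pearsonr(na[20 + i], ne[i])
        if r > 0.5 and p < 0.05:
            expected.add((f"cre{i}", f"prom{i}", f"g{i}"))
    assert set(zip(out["ccre_peak"], out["target_peak"], out["gene_id"])) == expected
    assert expected  # the fixture plants at least one true link
    assert len(expected) < len(pairs)  # and leaves some below threshold
    for rec in out.itertuples():
        assert rec.correlation > 0.5 and rec.p_value < 0.05


def test_build_gl_ccres_discards_ambiguous_pairs(rng):
    _, _, expr, acc, genes, peaks, got = _link_fixture(rng, n_pairs=4)
    pairs = pd.DataFrame(
        {
            "peak_a": ["prom0", "cre1", "prom2"],
            "peak_b": ["prom1", "cre2", "cre2"],
            "score": [0.5, 0.5, 0.5],
        }
    )
    out = build_gl_ccres(pairs, {f"prom{i}": [f"g{i}"] for i in range(4)}, expr, acc,
                         genes, peaks, gene_of_target=got)
    # two-promoter and zero-promoter pairs never appear
    assert set(out["target_peak"]) <= {"prom2"}


def test_build_gl_ccres_small_n_high_p_dropped():
    # r ~ 0.8 on 4 units has p ~ 0.2: correlation bar met, p bar not
    expr = np.array([[10.0, 30.0, 20.0, 40.0], [90.0, 70.0, 80.0, 60.0]])
    acc = np.array([[10.0, 20.0, 30.0, 40.0], [90.0, 80.0, 70.0, 60.0]])
    r, p = stats.pearsonr(_norm(acc)[0], _norm(expr)[0])
    assert r > 0.5 and p >= 0.05  # the case this test is about
    pairs = pd.DataFrame({"peak_a": ["prom0"], "peak_b": ["cre0"], "score": [0.4]})
    out = build_gl_ccres(
        pairs, {"prom0": ["g0"]}, expr, acc, ["g0", "g1"], ["cre0", "prom0"],
        gene_of_target={"prom0": "g0"},
    )
    assert len(out) == 0


def test_build_gl_ccres_groups_any_pass(rng):
    n_units = 24
    groups = np.array(["one"] * 12 + ["two"] * 12)
    v = rng.integers(1, 40, n_units).astype(float)
    # large constant filler rows keep depth normalization close to a plain
    # rescaling so the planted monotone relation survives it
    expr = np.vstack([v, np.full(n_units, 1_000.0)])
    cre = np.concatenate([v[:12] * 3, rng.integers(1, 40, 12)])  # linked in "one" only
    acc = np.vstack([cre, np.full(n_units, 1_000.0)])
    pairs = pd.DataFrame({"peak_a": ["prom0"], "peak_b": ["cre0"], "score": [0.4]})
    out = build_gl_ccres(
        pairs, {"prom0": ["g0"]}, expr, acc, ["g0", "g1"], ["cre0", "prom0"],
        gene_of_target={"prom0": "g0"}, groups=groups,
    )
    assert list(out["group"]) == ["one"]


def test_build_gl_ccres_requires_gene_map(rng):
    pairs, promoter_map, expr, acc, genes, peaks, _ = _link_fixture(rng, n_pairs=2)
    with pytest.raises(ValueError, match="gene_of_target"):
        build_gl_ccres(pairs, promoter_map, expr, acc, genes, peaks)


# ---------------------------------------------------------------------------
# stress-specific sets, hot points, CNS


def _gl_frame(records):
    return pd.DataFrame(
        [
            {
                "ccre_peak": c, "target_peak": t, "gene_id": g,
                "coaccess": 0.5, "correlation": 0.7, "p_value": 0.01,
                "condition": None, "group": None,
            }
            for c, t, g in records
        ]
    )


def test_stress_specific_key_difference():
    stress = _gl_frame([("c1", "t1", "g1"), ("c2", "t2", "g2"), ("c3", "t3", "g3")])
    control = _gl_frame([("c2", "t2", "gX")])  # same key, different gene: still shared
    out = stress_specific_gl_ccres(stress, control)
    assert set(zip(out["ccre_peak"], out["target_peak"])) == {("c1", "t1"), ("c3", "t3")}
    empty = stress_specific_gl_ccres(stress.iloc[0:0], control)
    assert len(empty) == 0


def test_linkage_counts_distinct():
    gl = _gl_frame(
        [("c1", "t1", "g1"), ("c1", "t2", "g1"), ("c1", "t2", "g1"), ("c2", "t1", "g1")]
    )
    assert linkage_counts(gl).to_dict() == {"c1": 2, "c2": 1}
    assert linkage_counts(gl, count="genes").to_dict() == {"c1": 1, "c2": 1}


def test_hgl_worked_case():
    # linkage counts {1, 2, 2, 3, 20}: Q1=2, Q3=3, fence 4.5, only 20 is hot
    records = []
    for ci, n_targets in enumerate([1, 2, 2, 3, 20]):
        for t in range(n_targets):
            records.append((f"c{ci}", f"t{ci}_{t}", "g"))
    out = select_hgl_ccres(_gl_frame(records))
    assert list(out["ccre_peak"]) == ["c4"]
    assert out["linkage_count"].iat[0] == 20
    assert out["threshold"].iat[0] == pytest.approx(4.5)


def test_hgl_under_four_ccres_empty(caplog):
    gl = _gl_frame([("c1", "t1", "g"), ("c2", "t2", "g"), ("c3", "t3", "g")])
    with caplog.at_level("WARNING"):
        out = select_hgl_ccres(gl)
    assert len(out) == 0
    assert any("fewer than 4" in m for m in caplog.messages)


def test_cns_overlap_brute_force(rng):
    peaks = [
        GenomicInterval(f"chr{rng.integers(1, 3)}", int(s), int(s) + 200, f"p{i}")
        for i, s in enumerate(rng.integers(0, 20_000, 40))
    ]
    cns = [
        GenomicInterval(f"chr{rng.integers(1, 3)}", int(s), int(s) + int(w))
        for s, w in zip(rng.integers(0, 20_000, 30), rng.integers(10, 400, 30))
    ]
    frac, df = cns_overlap(peaks, cns)
    expected = [
        sum(1 for c in cns if c.chrom == p.chrom and p.start < c.end and c.start < p.end)
        for p in peaks
    ]
    assert list(df["n_cns"]) == expected
    assert frac == pytest.approx(np.mean([e > 0 for e in expected]))
    assert cns_overlap(peaks, [])[0] == 0.0


def test_compare_cns_fractions_hand_case():
    gl = [GenomicInterval("chr1", i * 1_000, i * 1_000 + 100, f"g{i}") for i in range(10)]
    hgl = [GenomicInterval("chr1", i * 1_000, i * 1_000 + 100, f"h{i}") for i in range(5)]
    cns = [GenomicInterval("chr1", i * 1_000 + 50, i * 1_000 + 60) for i in range(4)]
    out = compare_cns_fractions(gl, hgl, cns)
    assert out["fraction_gl"] == pytest.approx(0.4)
    assert out["fraction_hgl"] == pytest.approx(0.8)
    pooled = 8 / 15
    se = np.sqrt(pooled * (1 - pooled) * (1 / 10 + 1 / 5))
    z = (0.8 - 0.4) / se
    assert out["z"] == pytest.approx(z)
    assert out["p_value"] == pytest.approx(2 * stats.norm.sf(abs(z)))
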