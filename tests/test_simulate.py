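"""Generator contracts: structure, conservation invariants and scoring."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rootlink import (
    SimConfig,
    TruthSet,
    evaluate_link_recovery,
    evaluate_priming_recovery,
    generate_multiome,
    read_bed,
    read_fragments,
    read_gene_models,
    read_triplet_matrix,
    write_dataset,
)
from rootlink.simulate import _type_counts, DEFAULT_PROPORTIONS


def test_config_validation():
    with pytest.raises(ValueError, match="link_strength"):
        SimConfig(link_strength=1.5)
    with pytest.raises(ValueError, match="sum"):
        SimConfig(proportions={"initial": 0.5})
    with pytest.raises(ValueError, match="peak"):
        SimConfig(n_genes=100, n_peaks=50)


def test_type_counts_largest_remainder():
    counts = _type_counts(2_000, DEFAULT_PROPORTIONS)
    assert sum(counts.values()) == 2_000
    # realized counts never deviate from the exact share by one whole cell
    for t, p in DEFAULT_PROPORTIONS.items():
        assert abs(counts[t] - 2_000 * p) < 1.0


def test_shapes_and_barcodes(small_sim, small_config):
    mm = small_sim.multiome
    n = 2 * small_config.n_cells_per_condition
    assert mm.rna.shape == (small_config.n_genes, n)
    assert mm.atac.shape == (small_config.n_peaks, n)
    assert len(set(mm.barcodes)) == n
    assert small_sim.cell_table["condition"].value_counts().to_dict() == {
        "control": small_config.n_cells_per_condition,
        "stress": small_config.n_cells_per_condition,
    }


def test_truth_links_scopes(small_sim, small_config):
    links = small_sim.truth.links
    assert len(links) == small_config.n_planted_links + small_config.n_stress_only_links
    assert links["scope"].value_counts().to_dict() == {
        "both": small_config.n_planted_links,
        "stress_only": small_config.n_stress_only_links,
    }
    # planted peak/gene ids resolve against the dataset
    peak_names = {p.name for p in mm_peaks(small_sim)}
    assert set(links["ccre_peak"]) <= peak_names
    assert set(links["target_peak"]) <= peak_names
    assert set(links["gene_id"]) <= set(small_sim.multiome.genes)


def mm_peaks(sim):
    return sim.multiome.peaks


def test_primed_counts(small_sim, small_config):
    cells = small_sim.truth.cells
    primed = small_sim.truth.primed
    for cond in ("control", "stress"):
        init = cells[(cells["cell_type"] == "initial") & (cells["condition"] == cond)]
        n_primed = primed["barcode"].isin(init["barcode"]).sum()
        assert n_primed == round(small_config.primed_fraction * len(init))


def test_fragment_peak_conservation(small_sim):
    """Fragments lying in a peak reproduce that peak's count column exactly."""
    mm = small_sim.multiome
    frame = small_sim.fragments
    bc = {b: i for i, b in enumerate(mm.barcodes)}
    counts = np.zeros(mm.atac.shape, dtype=np.int64)
    chroms = np.asarray(frame.chrom, dtype=object)
    starts, ends = frame.start, frame.end
    codes = np.array([bc[b] for b in np.asarray(frame.barcode, dtype=object)])
    for pi, peak in enumerate(mm.peaks):
        mask = (chroms == peak.chrom) & (starts < peak.end) & (ends > peak.start)
        np.add.at(counts[pi], codes[mask], frame.count[mask])
    np.testing.assert_array_equal(counts, mm.atac.toarray())


def test_determinism_and_seed_sensitivity(small_config):
    a = generate_multiome(small_config)
    b = generate_multiome(small_config)
    assert (a.multiome.rna != b.multiome.rna).nnz == 0
    assert (a.multiome.atac != b.multiome.atac).nnz == 0
    c = generate_multiome(SimConfig(**{**small_config.__dict__, "seed": 12}))
    assert (a.multiome.rna != c.multiome.rna).nnz > 0


def test_planted_correlation_beats_unplanted(small_sim, rng):
    """Planted pairs correlate above the 95th percentile of unplanted pairs."""
    mm = small_sim.multiome
    rna = np.log1p(mm.rna.toarray() / np.maximum(mm.rna.toarray().sum(0), 1) * 1e4)
    atac = np.log1p(mm.atac.toarray() / np.maximum(mm.atac.toarray().sum(0), 1) * 1e4)
    pidx = {p.name: i for i, p in enumerate(mm.peaks)}
    gidx = {g: i for i, g in enumerate(mm.genes)}

    def corr(pi, gi):
        x, y = atac[pi], rna[gi]
        if x.std() == 0 or y.std() == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    planted = [
        corr(pidx[r.ccre_peak], gidx[r.gene_id])
        for r in small_sim.truth.links.itertuples()
        if r.scope == "both"
    ]
    unplanted_pairs = set(zip(small_sim.truth.links["ccre_peak"], small_sim.truth.links["gene_id"]))
    background = []
    names = list(pidx)
    genes = list(gidx)
    while len(background) < 300:
        p = names[rng.integers(len(names))]
        g = genes[rng.integers(len(genes))]
        if (p, g) not in unplanted_pairs:
            background.append(corr(pidx[p], gidx[g]))
    assert min(planted) > np.quantile(background, 0.95)


def test_zero_strength_kills_correlation(small_config):
    cfg = SimConfig(**{**small_config.__dict__, "link_strength": 0.0})
    sim = generate_multiome(cfg)
    mm = sim.multiome
    rna = np.log1p(mm.rna.toarray() / np.maximum(mm.rna.toarray().sum(0), 1) * 1e4)
    atac = np.log1p(mm.atac.toarray() / np.maximum(mm.atac.toarray().sum(0), 1) * 1e4)
    pidx = {p.name: i for i, p in enumerate(mm.peaks)}
    gidx = {g: i for i, g in enumerate(mm.genes)}
    rs = []
    for r in sim.truth.links.itertuples():
        x, y = atac[pidx[r.ccre_peak]], rna[gidx[r.gene_id]]
        if x.std() > 0 and y.std() > 0:
            rs.append(abs(np.corrcoef(x, y)[0, 1]))
    # sampling error bound for n = 600 cells
    assert np.mean(rs) < 0.1


# ---------------------------------------------------------------------------
# recovery scoring


def _toy_truth():
    links = pd.DataFrame(
        {
            "ccre_peak": [f"p{i}" for i in range(10)],
            "target_peak": [f"t{i}" for i in range(10)],
            "gene_id": [f"g{i}" for i in range(10)],
            "scope": ["both"] * 10,
        }
    )
    return TruthSet(links=links, primed=pd.DataFrame(columns=["barcode", "borrowed_type"]),
                    cells=pd.DataFrame(columns=["barcode", "condition", "cell_type",
                                                "atac_program_type"]))


def test_recovery_arithmetic():
    truth = _toy_truth()
    predicted = {(f"p{i}", f"g{i}") for i in range(8)} | {("x", "y"), ("u", "v")}
    out = evaluate_link_recovery(predicted, truth)
    assert out["precision"] == pytest.approx(0.8)
    assert out["recall"] == pytest.approx(0.8)


def test_recovery_edge_cases():
    truth = _toy_truth()
    exact = evaluate_link_recovery(set(zip(truth.links["ccre_peak"], truth.links["gene_id"])), truth)
    assert exact["precision"] == 1.0 and exact["recall"] == 1.0
    disjoint = evaluate_link_recovery({("a", "b")}, truth)
    assert disjoint["precision"] == 0.0 and disjoint["recall"] == 0.0
    empty = evaluate_link_recovery(set(), truth)
    assert empty["precision"] is None and empty["recall"] == 0.0
    with pytest.raises(ValueError, match="scope"):
        truth.planted_pairs("sometimes")


def test_priming_recovery_arithmetic():
    cells = pd.DataFrame(
        {
            "barcode": [f"c{i}" for i in range(10)],
            "condition": ["control"] * 10,
            "cell_type": ["initial"] * 10,
            "atac_program_type": ["initial"] * 10,
        }
    )
    primed = pd.DataFrame({"barcode": ["c0", "c1", "c2"], "borrowed_type": ["cortex"] * 3})
    truth = TruthSet(links=pd.DataFrame(columns=["ccre_peak", "target_peak", "gene_id", "scope"]),
                     primed=primed, cells=cells)
    assignment = {f"c{i}": "INIT.Pr" for i in range(10)}
    assignment["c0"] = "INIT.cortex"  # 1 primed right, 2 wrong, 7 rest right
    acc, confusion = evaluate_priming_recovery(assignment, truth)
    assert acc == pytest.approx(0.8)
    assert confusion.loc["INIT.cortex", "INIT.Pr"] == 2
    with pytest.raises(ValueError, match="unknown barcode"):
        evaluate_priming_recovery({**assignment, "ghost": "INIT.Pr"}, truth)


# ---------------------------------------------------------------------------
# file export


def test_write_dataset_round_trip(tmp_path, small_sim):
    write_dataset(small_sim, tmp_path)
    mat, genes, barcodes = read_triplet_matrix(
        tmp_path / "rna_matrix.mtx", tmp_path / "rna_features.tsv", tmp_path / "barcodes.tsv"
    )
    assert genes == small_sim.multiome.genes
    assert barcodes == small_sim.multiome.barcodes
    assert (mat != small_sim.multiome.rna).nnz == 0
    peaks = read_bed(tmp_path / "peaks.bed")
    assert peaks == small_sim.multiome.peaks
    gene_models = read_gene_models(tmp_path / "genes.gtf")
    assert gene_models == small_sim.genes
    n_frag_lines = sum(1 for _ in read_fragments(tmp_path / "fragments.tsv.gz"))
    assert n_frag_lines == len(small_sim.fragments.start)
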