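"""Synthetic paired RNA/ATAC data with planted ground truth.

The generator emulates a two-condition (control / osmotic stress) root-tip
multiome: ~15 RNA-defined cell types, type-specific negative-binomial
expression programs, type-specific Bernoulli-thinned Poisson peak
accessibility, promoter peaks anchored at each gene's TSS, planted
cCRE -> gene linkages coupled through a per-cell latent activity, "primed"
initial cells that borrow a differentiated type's accessibility program while
keeping initial-cell expression, and a fragments file consistent with the
peak counts. A :class:`TruthSet` records everything planted so recovery can
be scored.

Statistical model
-----------------
RNA counts are gamma-Poisson (negative binomial with Var = m + phi * m^2).
ATAC peak counts are Poisson thinned by a per-(peak, type) Bernoulli open
probability. Each planted link draws one latent z ~ N(0,1) per cell and
multiplies the cCRE peak rate, the target gene's promoter peak rate and the
target gene's expression mean by exp(s*z - s^2/2) (mean-one lognormal), with
s the configured link strength; stress-only links apply the factor only in
stress cells. Primed initial cells use the borrowed type's accessibility
program but the initial-cell expression program.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import io as rio
from .activity import gene_window
from .qc import compute_nucleosome_signal, compute_tss_enrichment
from .types import FragmentFrame, GeneModel, GenomicInterval, MultiomeMatrix, make_cell_table

logger = logging.getLogger("rootlink")


CELL_TYPES = [
    "initial",
    "QC",
    "epidermis",
    "trichoblast",
    "atrichoblast",
    "cortex",
    "endodermis",
    "suberin_endodermis",
    "stele",
    "xylem",
    "phloem",
    "pericycle",
    "columella",
    "lateral_root_cap",
    "procambium",
]

DEFAULT_PROPORTIONS = {
    "initial": 0.10,
    "QC": 0.04,
    "epidermis": 0.09,
    "trichoblast": 0.08,
    "atrichoblast": 0.07,
    "cortex": 0.10,
    "endodermis": 0.08,
    "suberin_endodermis": 0.04,
    "stele": 0.08,
    "xylem": 0.05,
    "phloem": 0.05,
    "pericycle": 0.06,
    "columella": 0.08,
    "lateral_root_cap": 0.05,
    "procambium": 0.03,
}

# Accessibility-based groups used both for the ATAC-level annotation and for
# the initial-cell sub-cluster references ("Pr" = primary: quiescent center
# and initials themselves).
DEFAULT_TYPE_GROUPS: dict[str, tuple[str, ...]] = {
    "epidermis": ("epidermis", "trichoblast", "atrichoblast"),
    "cortex": ("cortex",),
    "endodermis": ("endodermis", "suberin_endodermis"),
    "stele": ("stele", "xylem", "phloem", "pericycle", "procambium"),
    "root_cap": ("columella", "lateral_root_cap"),
    "Pr": ("QC", "initial"),
}

GROUP_OF_TYPE = {t: g for g, ts in DEFAULT_TYPE_GROUPS.items() for t in ts}

# one representative differentiated program per non-primary group, used when
# assigning borrowed programs to primed initial cells
PRIMED_PROGRAM_TYPES = ["epidermis", "cortex", "endodermis", "stele", "columella"]

# distance within which a distal peak could be linked to a gene downstream;
# type-structured background accessibility is only planted beyond it
LINKAGE_HORIZON = 250_000

SUBCLUSTERS = [
    "INIT.epidermis",
    "INIT.cortex",
    "INIT.endodermis",
    "INIT.stele",
    "INIT.root_cap",
    "INIT.Pr",
]


@dataclass
class SimConfig:
    """Generator configuration; defaults are the desk-scale study conditions."""

    n_cells_per_condition: int = 2_000
    proportions: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    n_genes: int = 300
    n_peaks: int = 1_000
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    n_planted_links: int = 30        # both-condition links
    n_stress_only_links: int = 20
    primed_fraction: float = 0.6
    link_strength: float = 0.9       # latent-activity coupling in [0, 1]
    rna_depth: float = 2_500.0       # mean RNA UMI per cell
    atac_depth: float = 2_000.0      # mean in-peak ATAC fragment units per cell
    dispersion: float = 0.3          # NB dispersion phi (Var = m + phi m^2)
    background_fraction: float = 0.10  # off-peak fragments, relative to atac_depth
    depth_sd_log: float = 0.25       # per-cell depth factor, lognormal sigma
    markers_per_type: int = 6
    gene_length: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        total = float(sum(self.proportions.values()))
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"cell-type proportions sum to {total}, not 1")
        unknown = set(self.proportions) - set(CELL_TYPES)
        if unknown:
            raise ValueError(f"unknown cell types in proportions: {sorted(unknown)}")
        if not (0.0 <= self.link_strength <= 1.0):
            raise ValueError("link_strength must lie in [0, 1]")
        if not (0.0 <= self.primed_fraction <= 1.0):
            raise ValueError("primed_fraction must lie in [0, 1]")
        for name in ("n_cells_per_condition", "n_genes", "n_peaks", "n_chroms",
                     "chrom_length", "rna_depth", "atac_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_peaks < self.n_genes:
            raise ValueError("need at least one peak per gene (promoter peaks)")
        # feasibility of the genome layout: genes + distal peaks + margins
        per_chrom = -(-self.n_genes // self.n_chroms)
        if per_chrom * 12_000 > self.chrom_length:
            raise ValueError("genome too small for the requested gene count")
        n_distal = self.n_peaks - self.n_genes
        if (n_distal * 2_000 + self.n_genes * 12_000) > self.n_chroms * self.chrom_length:
            raise ValueError("genome too small for the requested peak count")


@dataclass
class TruthSet:
    """Planted linkages, primed flags and labels for recovery scoring."""

    links: pd.DataFrame        # ccre_peak, target_peak, gene_id, scope
    primed: pd.DataFrame       # barcode, borrowed_type
    cells: pd.DataFrame        # barcode, condition, cell_type, atac_program_type
    type_groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_GROUPS)
    )

    def planted_pairs(self, scope: str | None = None) -> set[tuple[str, str]]:
        """Set of planted (ccre_peak, gene_id) keys, optionally by scope."""
        if scope not in (None, "both", "stress_only"):
            raise ValueError(f"unknown scope {scope!r}")
        df = self.links if scope is None else self.links[self.links["scope"] == scope]
        return set(zip(df["ccre_peak"], df["gene_id"]))


@dataclass
class SimResult:
    multiome: MultiomeMatrix
    cell_table: pd.DataFrame
    fragments: FragmentFrame
    genes: list[GeneModel]
    truth: TruthSet


def _type_counts(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment so realized counts match proportions."""
    items = [(t, n * p) for t, p in proportions.items()]
    counts = {t: int(np.floor(x)) for t, x in items}
    short = n - sum(counts.values())
    by_frac = sorted(items, key=lambda tx: (tx[1] - np.floor(tx[1]), tx[0]), reverse=True)
    for t, _ in by_frac[:short]:
        counts[t] += 1
    return counts


def _layout_genome(cfg: SimConfig, rng: np.random.Generator):
    """Place genes on a jittered grid and distal peaks in intergenic space."""
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    genes: list[GeneModel] = []
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    gi = 0
    for ci, chrom in enumerate(chroms):
        k = per_chrom[ci]
        if k == 0:
            continue
        spacing = cfg.chrom_length // (k + 1)
        jitter = rng.integers(-spacing // 8, spacing // 8 + 1, size=k)
        strands = rng.choice(["+", "-"], size=k)
        for j in range(k):
            start = int((j + 1) * spacing + jitter[j])
            genes.append(
                GeneModel(f"GENE{gi:04d}", chrom, start, start + cfg.gene_length, str(strands[j]))
            )
            gi += 1

    promoter_peaks = []
    for g in genes:
        promoter_peaks.append(GenomicInterval(g.chrom, g.tss - 200, g.tss + 200))

    # intergenic segments that keep distal peaks clear of gene windows and
    # of the TSS-enrichment flanks
    forbidden: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for g in genes:
        ws, we = gene_window(g)
        forbidden[g.chrom].append((max(0, ws - 3_000), min(cfg.chrom_length, we + 3_000)))
    segments: list[tuple[str, int, int]] = []
    max_width = 800
    for chrom in chroms:
        zones = sorted(forbidden[chrom])
        cursor = 0
        for zs, ze in zones + [(cfg.chrom_length, cfg.chrom_length)]:
            if zs - cursor > 2 * max_width:
                segments.append((chrom, cursor, zs - max_width))
            cursor = max(cursor, ze)

    n_distal = cfg.n_peaks - cfg.n_genes
    seg_lens = np.array([e - s for _, s, e in segments], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(seg_lens)])
    total = int(cum[-1])
    if total < n_distal * 1_500:
        raise ValueError("genome too small for the requested peak count")
    offsets = np.sort(rng.uniform(0, total, size=n_distal))
    for i in range(1, n_distal):  # enforce a minimum 1.5 kb spacing
        offsets[i] = max(offsets[i], offsets[i - 1] + 1_500)
    if n_distal and offsets[-1] >= total:
        raise ValueError("genome too small for the requested peak count")
    widths = rng.integers(300, 701, size=n_distal)
    distal_peaks = []
    seg_idx = np.searchsorted(cum, offsets, side="right") - 1
    for off, w, si in zip(offsets, widths, seg_idx):
        chrom, s, _e = segments[si]
        pos = int(s + (off - cum[si]))
        distal_peaks.append(GenomicInterval(chrom, pos, pos + int(w)))

    # canonical peak ordering: (chrom, start), ids assigned after sorting
    tagged = [(p, "promoter", gidx) for gidx, p in enumerate(promoter_peaks)]
    tagged += [(p, "distal", -1) for p in distal_peaks]
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start))
    peaks: list[GenomicInterval] = []
    promoter_peak_of_gene: dict[int, int] = {}
    is_promoter = np.zeros(len(tagged), dtype=bool)
    for pi, (p, kind, gidx) in enumerate(tagged):
        peaks.append(GenomicInterval(p.chrom, p.start, p.end, name=f"peak_{pi:04d}"))
        if kind == "promoter":
            promoter_peak_of_gene[gidx] = pi
            is_promoter[pi] = True
    return genes, peaks, promoter_peak_of_gene, is_promoter


def _plant_links(cfg, rng, genes, peaks, promoter_peak_of_gene, is_promoter, gene_weight):
    """Pick planted (cCRE peak, target promoter, gene) triples.

    Target genes come from the upper half of baseline expression; each cCRE is
    a distal peak 5-200 kb from its gene's TSS, used at most once.
    """
    n_links = cfg.n_planted_links + cfg.n_stress_only_links
    order = np.argsort(-gene_weight)
    candidates = order[: max(n_links, len(genes) // 2)]
    gene_choice = rng.choice(candidates, size=n_links, replace=False)

    peak_mid = np.array([p.midpoint for p in peaks])
    peak_chrom = np.array([p.chrom for p in peaks])
    used = set()
    rows = []
    for li, gidx in enumerate(gene_choice):
        g = genes[int(gidx)]
        dist = np.abs(peak_mid - g.tss)
        ok = (
            (peak_chrom == g.chrom)
            & ~is_promoter
            & (dist >= 5_000)
            & (dist <= 200_000)
        )
        cand = [i for i in np.nonzero(ok)[0] if i not in used]
        if not cand:
            cand = [
                i
                for i in np.nonzero((peak_chrom == g.chrom) & ~is_promoter)[0]
                if i not in used
            ]
            if not cand:
                raise ValueError("not enough distal peaks to plant the requested links")
        ccre = int(rng.choice(cand))
        used.add(ccre)
        scope = "both" if li < cfg.n_planted_links else "stress_only"
        rows.append(
            {
                "ccre_peak": peaks[ccre].name,
                "target_peak": peaks[promoter_peak_of_gene[int(gidx)]].name,
                "gene_id": g.gene_id,
                "scope": scope,
                "_ccre_idx": ccre,
                "_target_idx": promoter_peak_of_gene[int(gidx)],
                "_gene_idx": int(gidx),
            }
        )
    return pd.DataFrame(rows)


def generate_multiome(cfg: SimConfig | None = None) -> SimResult:
    """Generate the full paired dataset plus truth tables. Deterministic for
    a fixed config (identical seed => byte-identical outputs)."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    n_types = len(CELL_TYPES)
    type_index = {t: i for i, t in enumerate(CELL_TYPES)}

    genes, peaks, promoter_peak_of_gene, is_promoter = _layout_genome(cfg, rng)
    n_genes, n_peaks = len(genes), len(peaks)

    # ---------------- cells ----------------
    barcodes, conditions, cell_types = [], [], []
    for cond, tag in (("control", "CTRL"), ("stress", "STRS")):
        counts = _type_counts(cfg.n_cells_per_condition, cfg.proportions)
        types_cond = [t for t in CELL_TYPES for _ in range(counts.get(t, 0))]
        types_cond = list(rng.permutation(types_cond))
        for i, t in enumerate(types_cond):
            barcodes.append(f"{tag}-{i:05d}")
            conditions.append(cond)
            cell_types.append(t)
    n_cells = len(barcodes)
    cond_arr = np.array(conditions)
    type_arr = np.array(cell_types)
    is_stress = cond_arr == "stress"

    # primed initials: borrow a differentiated accessibility program
    program_type = type_arr.copy()
    primed_rows = []
    for cond in ("control", "stress"):
        init_idx = np.nonzero((type_arr == "initial") & (cond_arr == cond))[0]
        n_primed = int(round(cfg.primed_fraction * len(init_idx)))
        chosen = rng.choice(init_idx, size=n_primed, replace=False)
        programs = np.array(PRIMED_PROGRAM_TYPES)[
            np.arange(n_primed) % len(PRIMED_PROGRAM_TYPES)
        ]
        programs = rng.permutation(programs)
        for ci, pt in zip(chosen, programs):
            program_type[ci] = pt
            primed_rows.append({"barcode": barcodes[ci], "borrowed_type": pt})
    primed_df = pd.DataFrame(primed_rows, columns=["barcode", "borrowed_type"])

    t_of_cell = np.array([type_index[t] for t in type_arr])
    pt_of_cell = np.array([type_index[t] for t in program_type])

    # ---------------- expression programs ----------------
    gene_weight = rng.lognormal(mean=0.0, sigma=0.6, size=n_genes)
    marker_gene_of_type: dict[str, np.ndarray] = {}
    pool = rng.permutation(n_genes)
    cursor = 0
    for t in CELL_TYPES:
        marker_gene_of_type[t] = pool[cursor : cursor + cfg.markers_per_type]
        cursor += cfg.markers_per_type
    marker_pool = set(pool[:cursor].tolist())
    # balanced marker base weights: every type's marker load is identical, so
    # expected library composition is type-independent for non-marker genes
    gene_weight[pool[:cursor]] = 1.0

    links = _plant_links(
        cfg, rng, genes, peaks, promoter_peak_of_gene, is_promoter,
        np.where(np.isin(np.arange(n_genes), list(marker_pool)), -np.inf, gene_weight),
    )

    # gene x type expression multipliers: markers 4x in their own type
    expr_fac = np.ones((n_genes, n_types))
    for t, gidx in marker_gene_of_type.items():
        expr_fac[gidx, type_index[t]] = 4.0
    # mild stress induction for a handful of unplanted, unmarked genes
    free = sorted(set(range(n_genes)) - marker_pool - set(links["_gene_idx"]))
    de_genes = np.array(free[:20], dtype=int)
    stress_fac = np.ones(n_genes)
    stress_fac[de_genes] = 2.0

    # ---------------- accessibility programs ----------------
    peak_intensity = np.empty(n_peaks)
    peak_intensity[is_promoter] = 1.2
    peak_intensity[~is_promoter] = rng.lognormal(mean=np.log(0.55), sigma=0.4, size=int((~is_promoter).sum()))
    open_prob = np.full((n_peaks, n_types), 0.4)
    open_prob[is_promoter, :] = 0.85
    atac_fac = np.ones((n_peaks, n_types))
    # marker promoters open across the marker type's whole group
    for t, gidxs in marker_gene_of_type.items():
        grp = GROUP_OF_TYPE[t]
        in_group = np.array([type_index[tt] for tt in DEFAULT_TYPE_GROUPS[grp]])
        for gidx in gidxs:
            pi = promoter_peak_of_gene[int(gidx)]
            open_prob[pi, :] = 0.08
            open_prob[pi, in_group] = 0.9
    # distal background peaks: broad opening, mildly elevated in ~half the
    # types. The linkage predicate cannot tell cell-type co-regulation from a
    # direct link, so type-structured background is placed only beyond the
    # linkage horizon of type-structured (marker) genes: distal peaks within
    # that horizon keep a flat profile and ground-truth negatives stay true
    # negatives by construction.
    marker_tss = {}
    for t, gidxs in marker_gene_of_type.items():
        for gidx in gidxs:
            g = genes[int(gidx)]
            marker_tss.setdefault(g.chrom, []).append(g.tss)
    distal_idx = np.nonzero(~is_promoter)[0]
    for pi in distal_idx:
        peak = peaks[pi]
        mid = (peak.start + peak.end) // 2
        near_marker = any(
            abs(mid - tss) <= LINKAGE_HORIZON for tss in marker_tss.get(peak.chrom, ())
        )
        if near_marker:
            continue
        subset = rng.choice(n_types, size=7, replace=False)
        atac_fac[pi, subset] = 1.8
    # planted elements are constitutively accessible
    for _, row in links.iterrows():
        for pi in (row["_ccre_idx"], row["_target_idx"]):
            open_prob[pi, :] = 0.95
            atac_fac[pi, :] = 1.0
            peak_intensity[pi] = 1.2

    # ---------------- latent link activities ----------------
    s = cfg.link_strength
    rna_mod = np.ones((n_genes, n_cells))
    atac_mod = np.ones((n_peaks, n_cells))
    for _, row in links.iterrows():
        z = rng.standard_normal(n_cells)
        f = np.exp(s * z - 0.5 * s * s)
        if row["scope"] == "stress_only":
            f = np.where(is_stress, f, 1.0)
        rna_mod[row["_gene_idx"], :] *= f
        atac_mod[row["_ccre_idx"], :] *= f
        atac_mod[row["_target_idx"], :] *= f

    # ---------------- RNA counts ----------------
    depth_rna = rng.lognormal(mean=-0.5 * cfg.depth_sd_log**2, sigma=cfg.depth_sd_log, size=n_cells)
    depth_atac = rng.lognormal(mean=-0.5 * cfg.depth_sd_log**2, sigma=cfg.depth_sd_log, size=n_cells)

    base_expr = gene_weight[:, None] * expr_fac[:, t_of_cell]  # gene x cell
    base_expr = base_expr * np.where(is_stress, stress_fac[:, None], 1.0)
    # scale every cell's expected library to the target depth, so programs set
    # relative gene proportions and depth factors alone set totals
    base_expr *= cfg.rna_depth / base_expr.sum(axis=0)[None, :]
    rna_mean = base_expr * rna_mod * depth_rna[None, :]
    shape = 1.0 / cfg.dispersion
    rna_counts = rng.poisson(rng.gamma(shape, rna_mean * cfg.dispersion))
    rna = sp.csr_matrix(rna_counts)

    # ---------------- ATAC counts ----------------
    atac_rate = peak_intensity[:, None] * atac_fac[:, pt_of_cell]
    mean_open = open_prob[:, pt_of_cell]
    # per-cell library scaling, as for RNA
    atac_rate *= cfg.atac_depth / (atac_rate * mean_open).sum(axis=0)[None, :]
    atac_rate = atac_rate * atac_mod * depth_atac[None, :]
    opened = rng.random((n_peaks, n_cells)) < mean_open
    atac_counts = np.where(opened, rng.poisson(atac_rate), 0)
    atac = sp.csr_matrix(atac_counts)

    multiome = MultiomeMatrix(
        barcodes=list(barcodes),
        genes=[g.gene_id for g in genes],
        peaks=peaks,
        rna=rna,
        atac=atac,
    )

    # ---------------- fragments ----------------
    fragments = _emit_fragments(cfg, rng, multiome, barcodes, depth_atac)

    # ---------------- cell table ----------------
    ns = compute_nucleosome_signal(fragments, barcodes)
    tss = compute_tss_enrichment(fragments, genes, barcodes)
    atac_label = np.array([GROUP_OF_TYPE[t] for t in program_type])
    cell_table = make_cell_table(
        pd.DataFrame(
            {
                "barcode": barcodes,
                "condition": conditions,
                "rna_label": type_arr,
                "atac_label": atac_label,
                "n_count_rna": np.asarray(rna.sum(axis=0)).ravel(),
                "n_count_atac": np.asarray(atac.sum(axis=0)).ravel(),
                "n_genes": np.asarray((rna > 0).sum(axis=0)).ravel(),
                "n_peaks": np.asarray((atac > 0).sum(axis=0)).ravel(),
                "nucleosome_signal": ns.values,
                "tss_enrichment": tss.values,
            }
        )
    )

    truth = TruthSet(
        links=links[["ccre_peak", "target_peak", "gene_id", "scope"]].copy(),
        primed=primed_df,
        cells=pd.DataFrame(
            {
                "barcode": barcodes,
                "condition": conditions,
                "cell_type": type_arr,
                "atac_program_type": program_type,
            }
        ),
    )
    return SimResult(multiome, cell_table, fragments, genes, truth)


def _emit_fragments(cfg, rng, multiome, barcodes, depth_atac) -> FragmentFrame:
    """One fragment per ATAC count unit, placed inside its peak, plus
    off-peak background fragments (background never overlaps a peak, so
    in-peak fragment counts reproduce the matrix exactly)."""
    peaks = multiome.peaks
    peak_start = np.array([p.start for p in peaks], dtype=np.int64)
    peak_width = np.array([p.width for p in peaks], dtype=np.int64)
    peak_chrom_code = pd.Categorical([p.chrom for p in peaks])

    coo = multiome.atac.tocoo()
    reps = coo.data.astype(np.int64)
    peak_idx = np.repeat(coo.row, reps)
    cell_idx = np.repeat(coo.col, reps)

    def sample_lengths(n):
        is_mono = rng.random(n) < 0.30
        return np.where(
            is_mono,
            rng.integers(160, 261, size=n),
            rng.integers(60, 141, size=n),
        ).astype(np.int64)

    lengths = sample_lengths(len(peak_idx))
    lengths = np.minimum(lengths, peak_width[peak_idx] - 1)
    offsets = np.floor(
        rng.random(len(peak_idx)) * (peak_width[peak_idx] - lengths)
    ).astype(np.int64)
    starts = peak_start[peak_idx] + offsets
    ends = starts + lengths
    chrom_codes = peak_chrom_code.codes[peak_idx]

    # background fragments: uniform over the genome, rejected off peaks
    chrom_names = list(peak_chrom_code.categories)
    all_chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    n_bg = rng.poisson(cfg.background_fraction * cfg.atac_depth * depth_atac)
    bg_cell = np.repeat(np.arange(len(barcodes)), n_bg)
    m = len(bg_cell)
    bg_len = sample_lengths(m)
    bg_chrom = rng.integers(0, cfg.n_chroms, size=m)
    bg_start = np.empty(m, dtype=np.int64)
    pending = np.arange(m)
    # peak bounds per chromosome for overlap rejection
    bounds = {}
    for ci, cname in enumerate(all_chroms):
        sel = np.array([p.chrom == cname for p in peaks])
        bounds[ci] = (peak_start[sel], (peak_start + peak_width)[sel])
    for _ in range(50):
        if len(pending) == 0:
            break
        cand = rng.integers(0, cfg.chrom_length - 300, size=len(pending))
        bad = np.zeros(len(pending), dtype=bool)
        for ci in range(cfg.n_chroms):
            onc = bg_chrom[pending] == ci
            if not onc.any():
                continue
            ps, pe = bounds[ci]
            c = cand[onc]
            j = np.searchsorted(ps, c + bg_len[pending][onc], side="left")
            # overlaps previous peak if its end exceeds candidate start
            prev_end = np.where(j > 0, pe[np.maximum(j - 1, 0)], 0)
            bad_onc = prev_end > c
            tmp = bad[onc]
            tmp |= bad_onc
            bad[onc] = tmp
        bg_start[pending] = cand
        pending = pending[bad]
    if len(pending):  # extremely unlikely; drop irreplaceable stragglers
        keep = np.ones(m, dtype=bool)
        keep[pending] = False
        bg_cell, bg_len, bg_chrom, bg_start = (
            bg_cell[keep], bg_len[keep], bg_chrom[keep], bg_start[keep],
        )

    chrom_map = {name: i for i, name in enumerate(all_chroms)}
    code_remap = np.array([chrom_map[c] for c in chrom_names])
    all_chrom_codes = np.concatenate([code_remap[chrom_codes], bg_chrom])
    all_start = np.concatenate([starts, bg_start])
    all_end = np.concatenate([ends, bg_start + bg_len])
    all_cell = np.concatenate([cell_idx, bg_cell])

    barcode_cat = pd.Categorical.from_codes(all_cell, categories=list(barcodes))
    chrom_cat = pd.Categorical.from_codes(all_chrom_codes, categories=all_chroms)
    return FragmentFrame(
        chrom_cat, all_start, all_end, barcode_cat, np.ones(len(all_start), dtype=np.int64)
    )


# ---------------------------------------------------------------------------
# recovery scoring


def evaluate_link_recovery(
    predicted: Iterable[tuple[str, str]], truth: TruthSet, scope: str | None = None
) -> dict[str, float | None]:
    """Precision/recall/F1 of predicted (ccre_peak, gene_id) pairs against the
    planted links. Empty predictions give precision None and recall 0."""
    planted = truth.planted_pairs(scope)
    pred = set(predicted)
    if pred and not planted:
        raise ValueError("truth set has no planted links")
    hits = len(pred & planted)
    if not pred:
        return {"precision": None, "recall": 0.0, "f1": None, "n_predicted": 0, "n_planted": len(planted)}
    precision = hits / len(pred)
    recall = hits / len(planted)
    f1 = 0.0 if (precision + recall) == 0 else 2 * precision * recall / (precision + recall)
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "n_predicted": len(pred),
        "n_planted": len(planted),
    }


def evaluate_priming_recovery(
    assignment: Mapping[str, str], truth: TruthSet
) -> tuple[float, pd.DataFrame]:
    """Accuracy and confusion of initial-cell sub-cluster calls.

    The expected label is INIT.<group of borrowed type> for primed cells and
    INIT.Pr otherwise. The assignment must cover every initial barcode; an
    assignment for a barcode the truth does not know raises an error.
    """
    cells = truth.cells
    initials = cells.loc[cells["cell_type"] == "initial", "barcode"]
    known = set(cells["barcode"])
    for bc in assignment:
        if bc not in known:
            raise ValueError(f"unknown barcode in assignment: {bc}")
    missing = [bc for bc in initials if bc not in assignment]
    if missing:
        raise ValueError(f"assignment misses {len(missing)} initial barcodes (e.g. {missing[0]})")
    borrowed = dict(zip(truth.primed["barcode"], truth.primed["borrowed_type"]))
    expected, observed = [], []
    for bc in initials:
        if bc in borrowed:
            grp = truth.type_groups and GROUP_OF_TYPE[borrowed[bc]]
            expected.append(f"INIT.{grp}")
        else:
            expected.append("INIT.Pr")
        observed.append(assignment[bc])
    expected = pd.Series(expected, name="truth")
    observed = pd.Series(observed, name="assigned")
    accuracy = float((expected.values == observed.values).mean())
    confusion = pd.crosstab(expected, observed)
    return accuracy, confusion


# ---------------------------------------------------------------------------
# file export


def write_dataset(result: SimResult, outdir) -> None:
    """Write the full plain-text file set: triplet matrices for both
    modalities, fragments, gene annotation, peak BED, cell table and truth
    tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mm = result.multiome
    rio.write_triplet_matrix(
        mm.rna, mm.genes, mm.barcodes,
        out / "rna_matrix.mtx", out / "rna_features.tsv", out / "barcodes.tsv",
    )
    rio.write_triplet_matrix(
        mm.atac, [p.name for p in mm.peaks], mm.barcodes,
        out / "atac_matrix.mtx", out / "atac_features.tsv", out / "atac_barcodes.tsv",
    )
    rio.write_bed(mm.peaks, out / "peaks.bed")
    rio.write_gene_models_gtf(result.genes, out / "genes.gtf")
    rio.write_fragments(result.fragments.to_fragments(), out / "fragments.tsv.gz")
    rio.write_tsv(result.cell_table, out / "cell_table.tsv")
    rio.write_tsv(result.truth.links, out / "truth_links.tsv")
    rio.write_tsv(result.truth.primed, out / "truth_primed.tsv")
    rio.write_tsv(result.truth.cells, out / "truth_cells.tsv")
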