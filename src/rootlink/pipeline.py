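"""End-to-end convenience drivers: QC -> LSI/metacells -> co-accessibility ->
gl-cCRE linkage, run per condition, plus the priming study."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coaccess as ca
from . import crelink as cl
from .activity import gene_activity_matrix
from .embedding import aggregate_matrix, make_metacells, tfidf_lsi
from .priming import assign_subclusters, reference_accessibility_profiles
from .qc import QcThresholds, filter_cells
from .simulate import SimResult
from .types import MultiomeMatrix

logger = logging.getLogger("rootlink")


@dataclass
class LinkPipelineResult:
    gl_by_condition: dict[str, pd.DataFrame]
    stress_specific: pd.DataFrame
    hgl: pd.DataFrame
    predicted_pairs: set[tuple[str, str]]
    stress_specific_pairs: set[tuple[str, str]]
    n_cells_retained: int = 0
    coaccess_by_condition: dict[str, pd.DataFrame] = field(default_factory=dict)


def run_link_pipeline(
    result: SimResult,
    window: float = ca.DEFAULT_WINDOW,
    distance_constraint: float = ca.DEFAULT_CONSTRAINT,
    k: int = 50,
    n_components: int = 30,
    seed: int = 0,
    thresholds: QcThresholds | None = None,
    groups: str | None = None,
) -> LinkPipelineResult:
    """Full linkage pipeline on a paired dataset.

    QC-filter cells; per condition: LSI embedding, metacell aggregation,
    distance-penalized co-accessibility, coaccess > 0.1 thresholding,
    promoter anchoring and the r > 0.5 / p < 0.05 correlation filter on
    metacell aggregates; finally the stress-specific set and hot-point
    selection. ``groups='celltype'`` evaluates correlations within
    majority-cell-type metacell groups instead of pooled per condition.
    """
    mm = result.multiome
    retained = filter_cells(result.cell_table, thresholds)
    sub = mm.subset_cells(retained)
    table = result.cell_table.set_index("barcode").loc[sub.barcodes].reset_index()

    gene_models = result.genes
    promoter_map = cl.annotate_promoter_peaks(sub.peaks, gene_models)
    gene_of_target = {
        name: cl.nearest_gene(peak, gene_models)
        for name, peak in zip([p.name for p in sub.peaks], sub.peaks)
        if name in promoter_map
    }
    peak_names = [p.name for p in sub.peaks]

    gl_by_condition: dict[str, pd.DataFrame] = {}
    coaccess_by_condition: dict[str, pd.DataFrame] = {}
    for cond in ("control", "stress"):
        idx = np.nonzero((table["condition"] == cond).to_numpy())[0]
        bcs = [sub.barcodes[i] for i in idx]
        atac_c = sub.atac[:, idx].tocsc()
        rna_c = sub.rna[:, idx].tocsc()
        lsi = tfidf_lsi(atac_c, bcs, n_components=n_components, seed=seed)
        metacells = make_metacells(
            lsi, atac_c, k=min(k, len(bcs)), cell_table=table.iloc[idx]
        )
        logger.info("%s: %d cells -> %d metacells", cond, len(bcs), metacells.n_metacells)
        rna_meta = aggregate_matrix(rna_c, metacells)
        pairs = ca.coaccess_scores(
            metacells.matrix, sub.peaks,
            window=window, distance_constraint=distance_constraint, condition=cond,
        )
        kept = ca.threshold_pairs(pairs)
        coaccess_by_condition[cond] = kept
        group_labels = None
        if groups == "celltype":
            group_labels = metacells.composition["majority_type"].to_numpy()
        gl = cl.build_gl_ccres(
            kept, promoter_map, rna_meta, metacells.matrix,
            sub.genes, peak_names,
            condition=cond, gene_of_target=gene_of_target, groups=group_labels,
        )
        gl_by_condition[cond] = gl

    stress_specific = cl.stress_specific_gl_ccres(
        gl_by_condition["stress"], gl_by_condition["control"]
    )
    hgl = cl.select_hgl_ccres(stress_specific)
    predicted = set()
    for gl in gl_by_condition.values():
        predicted |= set(zip(gl["ccre_peak"], gl["gene_id"]))
    stress_pairs = set(zip(stress_specific["ccre_peak"], stress_specific["gene_id"]))
    return LinkPipelineResult(
        gl_by_condition=gl_by_condition,
        stress_specific=stress_specific,
        hgl=hgl,
        predicted_pairs=predicted,
        stress_specific_pairs=stress_pairs,
        n_cells_retained=len(retained),
        coaccess_by_condition=coaccess_by_condition,
    )


@dataclass
class PrimingPipelineResult:
    assignment: dict[str, str]
    primed_fraction: dict[str, float]
    reference_profiles: pd.DataFrame


def run_priming_pipeline(
    result: SimResult,
    thresholds: QcThresholds | None = None,
) -> PrimingPipelineResult:
    """QC-filter, compute gene activity from fragments, build reference group
    profiles and assign every initial cell to a sub-cluster."""
    retained = set(filter_cells(result.cell_table, thresholds))
    # keep all initial cells assessable; QC applies to reference cells
    table = result.cell_table
    keep = table["barcode"].isin(retained) | (table["rna_label"] == "initial")
    table = table[keep].reset_index(drop=True)
    barcodes = table["barcode"].tolist()
    activity = gene_activity_matrix(result.fragments, result.genes, barcodes)
    refs = reference_accessibility_profiles(
        activity, table, gene_names=[g.gene_id for g in result.genes]
    )
    assign = assign_subclusters(activity, table, refs)
    return PrimingPipelineResult(assign.assignment, assign.primed_fraction, refs)
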