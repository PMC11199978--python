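"""Accessibility-based sub-clustering of initial cells ("chromatin priming").

Initial cells whose accessibility profile matches a differentiated lineage
are taken to be primed toward it: each RNA-annotated initial cell is
assigned, by Spearman correlation of its gene-activity vector against
reference group profiles, to one of six sub-clusters (INIT.epidermis /
cortex / endodermis / stele / root_cap, or INIT.Pr for primary-like
chromatin). The primed fraction is the fraction of initials not assigned
INIT.Pr, reported per condition.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .concordance import average_profiles, modality_correlation
from .simulate import DEFAULT_TYPE_GROUPS, SUBCLUSTERS

logger = logging.getLogger("rootlink")


@dataclass
class SubclusterAssignment:
    assignment: dict[str, str]            # barcode -> INIT.* sub-cluster
    primed_fraction: dict[str, float]     # per condition
    correlations: pd.DataFrame            # initial cell x group Spearman


def reference_accessibility_profiles(
    activity: sp.spmatrix | np.ndarray,
    cell_table: pd.DataFrame,
    type_groups: Mapping[str, Sequence[str]] | None = None,
    gene_names=None,
    initial_label: str = "initial",
) -> pd.DataFrame:
    """Group x gene mean normalized gene-activity profiles.

    ``type_groups`` maps each sub-cluster reference group to the RNA cell
    types it aggregates; the Pr group holds the primary types (quiescent
    center and initials). Initial cells themselves are excluded from every
    reference: they are the cells the profiles will classify, and primed
    initials would otherwise leak their borrowed programs into the Pr
    reference. Empty groups raise.
    """
    groups = dict(type_groups or DEFAULT_TYPE_GROUPS)
    labels = np.full(len(cell_table), "", dtype=object)
    rna = cell_table["rna_label"].to_numpy()
    for gname, types in groups.items():
        labels[np.isin(rna, list(types))] = gname
    labels[rna == initial_label] = ""
    for gname in groups:
        if not (labels == gname).any():
            raise ValueError(f"reference group {gname!r} has no cells")
    keep = labels != ""
    activity = sp.csc_matrix(activity)[:, np.nonzero(keep)[0]]
    profiles = average_profiles(activity, labels[keep], feature_names=gene_names)
    return profiles


def _spearman_to_profiles(vec: np.ndarray, profiles: np.ndarray) -> np.ndarray:
    """Spearman correlation of one vector against each profile row."""
    if np.ptp(vec) == 0:
        return np.full(profiles.shape[0], np.nan)
    rv = rankdata(vec)
    rv = (rv - rv.mean()) / rv.std()
    out = np.empty(profiles.shape[0])
    for i in range(profiles.shape[0]):
        row = profiles[i]
        if np.ptp(row) == 0:
            out[i] = np.nan
            continue
        rr = rankdata(row)
        rr = (rr - rr.mean()) / rr.std()
        out[i] = float((rv * rr).mean())
    return out


def assign_subclusters(
    activity: sp.spmatrix | np.ndarray,
    cell_table: pd.DataFrame,
    reference_profiles: pd.DataFrame,
    initial_label: str = "initial",
) -> SubclusterAssignment:
    """Assign each initial cell to the reference group of maximal Spearman
    correlation with its normalized gene-activity vector.

    Ties break toward INIT.Pr, then lexicographically. Cells with no defined
    correlation are assigned INIT.Pr (flagged via NaN row in
    ``correlations``). The primed fraction per condition is the fraction of
    initials not assigned INIT.Pr.
    """
    ref = reference_profiles.to_numpy(dtype=float)
    ref_groups = list(reference_profiles.index)
    if ref.shape[0] < 2:
        raise ValueError("need at least two reference groups")
    nonconstant = np.ptp(ref, axis=0) > 0
    if nonconstant.sum() < 3:
        raise ValueError("need >= 3 genes with variance across references")

    dense = np.asarray(sp.csr_matrix(activity).todense(), dtype=float)
    totals = dense.sum(axis=0)
    safe = np.where(totals > 0, totals, 1.0)
    norm = np.log1p(dense / safe[None, :] * 1e4)

    is_init = (cell_table["rna_label"] == initial_label).to_numpy()
    barcodes = cell_table["barcode"].to_numpy()
    conditions = cell_table["condition"].to_numpy()

    assignment: dict[str, str] = {}
    corr_rows = []
    for ci in np.nonzero(is_init)[0]:
        cors = _spearman_to_profiles(norm[:, ci], ref)
        corr_rows.append(cors)
        if np.all(np.isnan(cors)):
            assignment[barcodes[ci]] = "INIT.Pr"
            continue
        best = np.nanmax(cors)
        cand = [ref_groups[i] for i in range(len(cors)) if not np.isnan(cors[i]) and cors[i] == best]
        if "Pr" in cand:
            choice = "Pr"
        else:
            choice = sorted(cand)[0]
        assignment[barcodes[ci]] = f"INIT.{choice}"

    init_bc = barcodes[is_init]
    init_cond = conditions[is_init]
    primed_fraction = {}
    for cond in pd.unique(init_cond):
        bcs = init_bc[init_cond == cond]
        if len(bcs):
            primed_fraction[cond] = float(
                np.mean([assignment[b] != "INIT.Pr" for b in bcs])
            )
    correlations = pd.DataFrame(corr_rows, index=init_bc, columns=ref_groups)
    return SubclusterAssignment(assignment, primed_fraction, correlations)


def subcluster_profiles(
    activity: sp.spmatrix | np.ndarray,
    cell_table: pd.DataFrame,
    assignment: Mapping[str, str],
    gene_names=None,
) -> pd.DataFrame:
    """Sub-cluster x gene mean normalized activity profiles over the assigned
    initial cells."""
    bc = cell_table["barcode"].to_numpy()
    labels = np.array([assignment.get(b, "") for b in bc], dtype=object)
    keep = labels != ""
    act = sp.csc_matrix(activity)[:, np.nonzero(keep)[0]]
    return average_profiles(act, labels[keep], feature_names=gene_names)


def subcluster_type_correlation(
    subcluster_profiles: pd.DataFrame,
    type_profiles: pd.DataFrame,
) -> pd.DataFrame:
    """Sub-cluster x cell-type Spearman matrix (activity vs activity or
    expression profiles over shared genes)."""
    return modality_correlation(subcluster_profiles, type_profiles)
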