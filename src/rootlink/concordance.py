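"""Same-cell cross-modality analyses: annotation agreement flows, averaged
profiles, Spearman expression-activity correlation, cell-proportion fold
changes, differential abundance, and min-max profile normalization."""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .diffexpr import bh_adjust

logger = logging.getLogger("rootlink")


def cross_annotation_flows(cell_table: pd.DataFrame, condition: str | None = None) -> pd.DataFrame:
    """RNA-label x ATAC-label cell-count matrix (the Sankey flow table).

    Row sums equal RNA-label counts and column sums ATAC-label counts, so the
    marginals conserve cells per modality.
    """
    df = cell_table if condition is None else cell_table[cell_table["condition"] == condition]
    return pd.crosstab(df["rna_label"], df["atac_label"])


def normalize_counts(matrix: sp.spmatrix | np.ndarray, scale: float = 1e4) -> np.ndarray:
    """Library-size normalize columns (cells) to ``scale`` counts, then log1p."""
    dense = np.asarray(sp.csr_matrix(matrix).todense(), dtype=float)
    totals = dense.sum(axis=0)
    safe = np.where(totals > 0, totals, 1.0)
    return np.log1p(dense / safe[None, :] * scale)


def average_profiles(
    matrix: sp.spmatrix | np.ndarray,
    labels,
    feature_names=None,
) -> pd.DataFrame:
    """Label x feature matrix of mean normalized values.

    Values are library-size normalized to 10,000 per cell and log1p-scaled
    before averaging. Labels with no cells are excluded with a warning;
    single-cell labels return that cell's normalized vector.
    """
    labels = np.asarray(labels)
    norm = normalize_counts(matrix)
    if norm.shape[1] != len(labels):
        raise ValueError("labels length must equal number of cells")
    uniq = pd.unique(labels)
    rows = {}
    for lab in uniq:
        sel = labels == lab
        if not sel.any():
            logger.warning("average_profiles: label %r has no cells, excluded", lab)
            continue
        rows[lab] = norm[:, sel].mean(axis=1)
    out = pd.DataFrame(rows).T
    if feature_names is not None:
        out.columns = list(feature_names)
    return out


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with average ranks; NaN for constant vectors."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rx, ry = rankdata(x), rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    return float((rx * ry).mean())


def modality_correlation(
    avg_expression: pd.DataFrame,
    avg_activity: pd.DataFrame,
    shared_genes=None,
) -> pd.DataFrame:
    """Label x label Spearman matrix between expression and activity profiles
    over shared genes. Entry (i, j) correlates the expression profile of type
    i with the activity profile of type j; undefined (constant) correlations
    are NaN."""
    if shared_genes is None:
        shared_genes = [g for g in avg_expression.columns if g in set(avg_activity.columns)]
    shared_genes = list(shared_genes)
    if len(shared_genes) < 3:
        raise ValueError("need at least 3 shared genes")
    E = avg_expression[shared_genes]
    A = avg_activity[shared_genes]
    out = pd.DataFrame(index=E.index, columns=A.index, dtype=float)
    for i in E.index:
        for j in A.index:
            out.loc[i, j] = _spearman(E.loc[i].to_numpy(), A.loc[j].to_numpy())
    return out


def proportion_fold_change(cell_table: pd.DataFrame) -> pd.DataFrame:
    """Per-type stress/control fold change of cell-type proportions:
    (n_t,stress / N_stress) / (n_t,control / N_control). Types absent from
    control get +inf and an ``absent_in_control`` flag."""
    counts = pd.crosstab(cell_table["rna_label"], cell_table["condition"])
    for cond in ("control", "stress"):
        if cond not in counts.columns:
            raise ValueError(f"no {cond} cells present")
    n_control, n_stress = counts["control"].sum(), counts["stress"].sum()
    prop_c = counts["control"] / n_control
    prop_s = counts["stress"] / n_stress
    with np.errstate(divide="ignore"):
        fc = np.where(prop_c > 0, prop_s / prop_c, np.inf)
    return pd.DataFrame(
        {
            "cell_type": counts.index,
            "n_control": counts["control"].values,
            "n_stress": counts["stress"].values,
            "fold_change": fc,
            "absent_in_control": (counts["control"] == 0).values,
        }
    ).reset_index(drop=True)


def _binom_loglik(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(k * np.log(p) + (n - k) * np.log(1 - p)))


def differential_abundance(cell_table: pd.DataFrame) -> pd.DataFrame:
    """Per-type likelihood-ratio test of a condition effect on cell-type
    membership (binomial GLM: full model has per-condition membership
    probabilities, the null a shared one), BH-adjusted across types."""
    counts = pd.crosstab(cell_table["rna_label"], cell_table["condition"])
    counts = counts[counts.sum(axis=1) > 0]
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 cell types")
    n_cond = counts.sum(axis=0)
    rows = []
    for t, row in counts.iterrows():
        k = row.to_numpy(dtype=float)            # cells of type t per condition
        n = n_cond.to_numpy(dtype=float)         # total cells per condition
        p_full = k / n
        p_null = k.sum() / n.sum()
        lrt = 2 * (_binom_loglik(k, n, p_full) - _binom_loglik(k, n, np.full_like(k, p_null)))
        lrt = max(lrt, 0.0)
        from scipy.stats import chi2

        pval = float(chi2.sf(lrt, df=1))
        rows.append({"cell_type": t, "lrt_statistic": lrt, "p_value": pval})
    out = pd.DataFrame(rows)
    out["adjusted_p"] = bh_adjust(out["p_value"].to_numpy())
    return out


def min_max_normalize(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-feature (column) min-max scaling to [0, 1]; constant features map
    to 0."""
    vals = profiles.to_numpy(dtype=float)
    lo = vals.min(axis=0)
    hi = vals.max(axis=0)
    span = hi - lo
    out = np.zeros_like(vals)
    nz = span > 0
    out[:, nz] = (vals[:, nz] - lo[nz]) / span[nz]
    return pd.DataFrame(out, index=profiles.index, columns=profiles.columns)
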