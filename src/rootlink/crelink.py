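"""Gene-linked candidate cis-regulatory elements (gl-cCREs).

Starting from thresholded co-accessible peak pairs: the promoter-annotated
member of a pair is the target peak and the other member the cCRE; the cCRE
is linked to the nearest gene of the target peak when the cCRE's
accessibility correlates with that gene's expression (r > 0.5, p < 0.05,
both strict). Stress-specific sets are keyed differences between conditions;
"hot point" cCREs (hgl-cCREs) are upper outliers (> Q3 + 1.5 IQR) of the
per-cCRE linkage-count distribution; CNS overlap reports the fraction of
cCREs containing at least one conserved noncoding sequence.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .types import GeneModel, GenomicInterval

logger = logging.getLogger("rootlink")

PROMOTER_UPSTREAM = 2_000
PROMOTER_DOWNSTREAM = 200
MIN_CORRELATION = 0.5
MAX_P = 0.05


@dataclass(frozen=True)
class GlCCRE:
    ccre_peak: str
    target_peak: str
    gene_id: str
    coaccess: float
    correlation: float
    p_value: float
    condition: str | None = None
    group: str | None = None


def promoter_window(gene: GeneModel, upstream: int = PROMOTER_UPSTREAM,
                    downstream: int = PROMOTER_DOWNSTREAM) -> tuple[int, int]:
    """Strand-aware promoter window [tss-upstream, tss+downstream), clipped
    at zero (on the minus strand the window extends upstream to the right)."""
    if gene.strand == "+":
        return max(0, gene.tss - upstream), gene.tss + downstream
    return max(0, gene.tss - downstream + 1), gene.tss + upstream + 1


def annotate_promoter_peaks(
    peaks: Sequence[GenomicInterval],
    gene_models: Sequence[GeneModel],
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> dict[str, list[str]]:
    """Map peak name -> gene ids whose promoter window the peak overlaps by
    at least 1 bp. A peak may be the promoter of several genes."""
    out: dict[str, list[str]] = {}
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for g in gene_models:
        ws, we = promoter_window(g, upstream, downstream)
        by_chrom.setdefault(g.chrom, []).append((ws, we, g.gene_id))
    for p in peaks:
        hits = [
            gid
            for (ws, we, gid) in by_chrom.get(p.chrom, [])
            if p.start < we and ws < p.end
        ]
        if hits:
            out[p.name] = sorted(hits)
    return out


def nearest_gene(peak: GenomicInterval, gene_models: Sequence[GeneModel]) -> str | None:
    """Gene whose TSS is closest to the peak midpoint; ties break to the
    lexicographically smallest gene id. None (with a warning) when the peak's
    chromosome has no genes."""
    best: tuple[float, str] | None = None
    mid = peak.midpoint
    for g in gene_models:
        if g.chrom != peak.chrom:
            continue
        d = abs(mid - g.tss)
        if best is None or (d, g.gene_id) < best:
            best = (d, g.gene_id)
    if best is None:
        logger.warning("nearest_gene: no genes on chromosome %s", peak.chrom)
        return None
    return best[1]


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with a t-distribution p-value on n-2 df."""
    n = len(x)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def build_gl_ccres(
    pairs: pd.DataFrame,
    promoter_map: Mapping[str, Sequence[str]],
    expression: np.ndarray | sp.spmatrix,
    accessibility: np.ndarray | sp.spmatrix,
    gene_names: Sequence[str],
    peak_names: Sequence[str],
    condition: str | None = None,
    gene_of_target: Mapping[str, str] | None = None,
    method: str = "pearson",
    min_correlation: float = MIN_CORRELATION,
    max_p: float = MAX_P,
    groups: Sequence | None = None,
) -> pd.DataFrame:
    """Promoter-anchor thresholded pairs and apply the correlation filter.

    For each pair with exactly one promoter-annotated member, the promoter
    peak is the target and the other peak the cCRE; the linked gene is the
    nearest gene of the target peak (``gene_of_target``). The cCRE's
    accessibility and the gene's expression are correlated across the
    observation units (columns of ``expression``/``accessibility``, typically
    metacells); a record is retained iff r > min_correlation and
    p < max_p (both strict). Pairs with zero or two promoter members are
    discarded and tallied. When ``groups`` is given, the correlation is
    evaluated separately within each group of observation units and a link is
    retained if it passes in any group (recorded with that group tag).
    """
    if gene_of_target is None:
        raise ValueError("gene_of_target mapping (target peak -> nearest gene) is required")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    expr = np.asarray(sp.csr_matrix(expression).todense(), dtype=float)
    acc = np.asarray(sp.csr_matrix(accessibility).todense(), dtype=float)
    if expr.shape[1] != acc.shape[1]:
        raise ValueError("expression and accessibility must share observation units")
    # depth-normalize observation units so library size is not a confounder
    for M in (expr, acc):
        totals = M.sum(axis=0)
        totals[totals == 0] = 1.0
        M /= totals[None, :]
        M *= 1e4
    expr = np.log1p(expr)
    acc = np.log1p(acc)

    gene_idx = {g: i for i, g in enumerate(gene_names)}
    peak_idx = {p: i for i, p in enumerate(peak_names)}

    if groups is None:
        group_masks = {None: np.ones(expr.shape[1], dtype=bool)}
    else:
        groups = np.asarray(groups)
        group_masks = {g: groups == g for g in pd.unique(groups)}

    n_discarded = 0
    n_skipped_small = 0
    rows = []
    for rec in pairs.itertuples(index=False):
        a, b = rec.peak_a, rec.peak_b
        a_prom, b_prom = a in promoter_map, b in promoter_map
        if a_prom == b_prom:  # zero or two promoter members
            n_discarded += 1
            continue
        target, ccre = (a, b) if a_prom else (b, a)
        gene = gene_of_target.get(target)
        if gene is None or gene not in gene_idx or ccre not in peak_idx:
            n_discarded += 1
            continue
        x_full = acc[peak_idx[ccre]]
        y_full = expr[gene_idx[gene]]
        for gname, mask in group_masks.items():
            n = int(mask.sum())
            if n < 3:
                n_skipped_small += 1
                continue
            x, y = x_full[mask], y_full[mask]
            if method == "pearson":
                r, p = pearson_with_p(x, y)
            else:
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    r, p = float("nan"), float("nan")
                else:
                    res = stats.spearmanr(x, y)
                    r, p = float(res.statistic), float(res.pvalue)
            if np.isnan(r):
                continue
            if r > min_correlation and p < max_p:
                rows.append(
                    {
                        "ccre_peak": ccre,
                        "target_peak": target,
                        "gene_id": gene,
                        "coaccess": rec.score,
                        "correlation": r,
                        "p_value": p,
                        "condition": condition,
                        "group": gname,
                    }
                )
    if n_discarded:
        logger.info("build_gl_ccres: %d pairs discarded (0 or 2 promoter members / unmapped)", n_discarded)
    if n_skipped_small:
        logger.warning("build_gl_ccres: %d group evaluations skipped (< 3 observation units)", n_skipped_small)
    out = pd.DataFrame(
        rows,
        columns=[
            "ccre_peak", "target_peak", "gene_id", "coaccess",
            "correlation", "p_value", "condition", "group",
        ],
    )
    return out


def stress_specific_gl_ccres(gl_stress: pd.DataFrame, gl_control: pd.DataFrame) -> pd.DataFrame:
    """Records present in the stress set and absent from the control set,
    keyed on (ccre_peak, target_peak)."""
    key = ["ccre_peak", "target_peak"]
    control_keys = set(map(tuple, gl_control[key].to_numpy().tolist())) if len(gl_control) else set()
    if not len(gl_stress):
        return gl_stress.copy()
    mask = [tuple(k) not in control_keys for k in gl_stress[key].to_numpy().tolist()]
    return gl_stress[mask].reset_index(drop=True)


def linkage_counts(gl_ccres: pd.DataFrame, count: str = "target_peaks") -> pd.Series:
    """Number of distinct linkages per cCRE ('target_peaks' or 'genes')."""
    col = {"target_peaks": "target_peak", "genes": "gene_id"}[count]
    if not len(gl_ccres):
        return pd.Series(dtype=int)
    return gl_ccres.groupby("ccre_peak")[col].nunique()


def select_hgl_ccres(gl_ccres: pd.DataFrame, count: str = "target_peaks") -> pd.DataFrame:
    """Hot-point cCREs: linkage count strictly above Q3 + 1.5 IQR.

    Quartiles use linear interpolation over the per-cCRE counts. Fewer than 4
    distinct cCREs make quartiles meaningless: returns empty with a warning.
    """
    counts = linkage_counts(gl_ccres, count=count)
    if len(counts) < 4:
        logger.warning("select_hgl_ccres: fewer than 4 cCREs, returning empty set")
        return pd.DataFrame(columns=["ccre_peak", "linkage_count", "threshold"])
    q1, q3 = np.quantile(counts.to_numpy(dtype=float), [0.25, 0.75])
    threshold = q3 + 1.5 * (q3 - q1)
    selected = counts[counts > threshold]
    return pd.DataFrame(
        {
            "ccre_peak": selected.index,
            "linkage_count": selected.to_numpy(),
            "threshold": threshold,
        }
    ).reset_index(drop=True)


def cns_overlap(
    ccre_peaks: Sequence[GenomicInterval],
    cns: Sequence[GenomicInterval],
) -> tuple[float, pd.DataFrame]:
    """Fraction of cCREs overlapping >= 1 conserved noncoding sequence, plus
    per-cCRE CNS counts. Empty CNS set gives fraction 0."""
    rows = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for c in cns:
        by_chrom.setdefault(c.chrom, []).append(c)
    for p in ccre_peaks:
        n = sum(1 for c in by_chrom.get(p.chrom, []) if p.start < c.end and c.start < p.end)
        rows.append({"ccre_peak": p.name, "n_cns": n})
    df = pd.DataFrame(rows, columns=["ccre_peak", "n_cns"])
    frac = float((df["n_cns"] > 0).mean()) if len(df) else 0.0
    return frac, df


def compare_cns_fractions(
    gl_peaks: Sequence[GenomicInterval],
    hgl_peaks: Sequence[GenomicInterval],
    cns: Sequence[GenomicInterval],
) -> dict:
    """CNS-containing fractions for the gl and hgl sets with a two-proportion
    z-test of their difference."""
    frac_gl, df_gl = cns_overlap(gl_peaks, cns)
    frac_hgl, df_hgl = cns_overlap(hgl_peaks, cns)
    n1, n2 = len(df_gl), len(df_hgl)
    k1, k2 = int((df_gl["n_cns"] > 0).sum()), int((df_hgl["n_cns"] > 0).sum())
    if n1 and n2:
        pooled = (k1 + k2) / (n1 + n2)
        se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        z = (k2 / n2 - k1 / n1) / se if se > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z))
    else:
        z, p = float("nan"), float("nan")
    return {
        "fraction_gl": frac_gl,
        "fraction_hgl": frac_hgl,
        "z": float(z),
        "p_value": float(p),
        "per_ccre_gl": df_gl,
        "per_ccre_hgl": df_hgl,
    }
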