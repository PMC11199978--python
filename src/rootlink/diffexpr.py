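"""Differential tests: Wilcoxon rank-sum differential expression,
logistic-regression likelihood-ratio differential accessibility with a latent
count covariate, and Benjamini-Hochberg adjustment."""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import chi2, mannwhitneyu

logger = logging.getLogger("rootlink")

PSEUDOCOUNT = 1.0


def bh_adjust(pvalues) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _normalize(matrix) -> np.ndarray:
    dense = np.asarray(sp.csr_matrix(matrix).todense(), dtype=float)
    totals = dense.sum(axis=0)
    safe = np.where(totals > 0, totals, 1.0)
    return np.log1p(dense / safe[None, :] * 1e4)


def wilcoxon_de(
    rna,
    group_a: np.ndarray,
    group_b: np.ndarray,
    gene_names=None,
    min_abs_log2fc: float = 0.25,
    max_adj_p: float = 0.05,
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum test between two cell groups.

    Values are library-normalized (10k per cell, log1p). log2FC is
    log2(mean_a + 1) - log2(mean_b + 1) on the normalized scale. P-values are
    exact when group sizes are small and the values are tie-free, normal
    approximation with tie correction otherwise; genes constant across both
    groups get p = 1. A gene passes when |log2FC| >= min_abs_log2fc and the
    BH-adjusted p is < max_adj_p.
    """
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("both groups need at least 3 cells")
    norm = _normalize(rna)
    A = norm[:, group_a]
    B = norm[:, group_b]
    n_genes = norm.shape[0]
    stats = np.empty(n_genes)
    pvals = np.empty(n_genes)
    for g in range(n_genes):
        a, b = A[g], B[g]
        if np.ptp(np.concatenate([a, b])) == 0:
            stats[g] = len(a) * len(b) / 2.0
            pvals[g] = 1.0
            continue
        res = mannwhitneyu(a, b, alternative="two-sided", method="auto")
        stats[g] = res.statistic
        pvals[g] = res.pvalue
    log2fc = np.log2(A.mean(axis=1) + PSEUDOCOUNT) - np.log2(B.mean(axis=1) + PSEUDOCOUNT)
    adj = bh_adjust(pvals)
    out = pd.DataFrame(
        {
            "gene": list(gene_names) if gene_names is not None else np.arange(n_genes),
            "statistic": stats,
            "log2fc": log2fc,
            "p_value": pvals,
            "adjusted_p": adj,
        }
    )
    out["pass"] = (np.abs(out["log2fc"]) >= min_abs_log2fc) & (out["adjusted_p"] < max_adj_p)
    return out


def _logistic_loglik(y, X) -> float:
    """Maximized log-likelihood of a logistic regression fit by Newton-raphson
    with a small ridge for separability."""
    import statsmodels.api as sm

    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=200)
        return float(res.llf)
    except Exception:
        res = model.fit_regularized(alpha=1e-8, L1_wt=0.0, maxiter=500)
        params = np.asarray(res.params)
        eta = X @ params
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def lr_dacr(
    atac,
    group_a: np.ndarray,
    group_b: np.ndarray,
    peak_names=None,
    latent: np.ndarray | None = None,
    min_abs_log2fc: float = 0.125,
    max_adj_p: float = 0.05,
) -> pd.DataFrame:
    """Per-peak likelihood-ratio test for differential accessibility.

    The ATAC matrix is binarized to detection events. For each peak, group
    membership is modeled by logistic regression on peak detection plus the
    latent covariate (per-cell total ATAC count by default) and compared with
    the latent-only null; the LR statistic is referred to chi-square with 1
    df. log2FC is computed on detection fractions with a pseudocount. Peaks
    detected in no cell of either group are skipped.
    """
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("both groups need at least 3 cells")
    dense = np.asarray(sp.csr_matrix(atac).todense(), dtype=float)
    if latent is None:
        latent = dense.sum(axis=0)
    latent = np.asarray(latent, dtype=float)

    cells = np.concatenate([group_a, group_b])
    y = np.concatenate([np.ones(len(group_a)), np.zeros(len(group_b))])
    lat = latent[cells]
    lat = (lat - lat.mean()) / (lat.std() if lat.std() > 0 else 1.0)
    detected = (dense[:, cells] > 0).astype(float)

    X_null = np.column_stack([np.ones_like(lat), lat])
    ll_null = _logistic_loglik(y, X_null)

    rows = []
    n_a, n_b = len(group_a), len(group_b)
    for g in range(dense.shape[0]):
        det = detected[g]
        name = peak_names[g] if peak_names is not None else g
        if det.sum() == 0:
            continue
        frac_a = det[: n_a].mean()
        frac_b = det[n_a:].mean()
        log2fc = np.log2(frac_a + 1e-2) - np.log2(frac_b + 1e-2)
        if det.std() == 0:
            lrt, pval = 0.0, 1.0
        else:
            X_full = np.column_stack([np.ones_like(lat), lat, det])
            ll_full = _logistic_loglik(y, X_full)
            lrt = max(0.0, 2.0 * (ll_full - ll_null))
            pval = float(chi2.sf(lrt, df=1))
        rows.append(
            {
                "peak": name,
                "lrt_statistic": lrt,
                "log2fc": log2fc,
                "p_value": pval,
                "detection_a": frac_a,
                "detection_b": frac_b,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["adjusted_p"] = bh_adjust(out["p_value"].to_numpy())
        out["pass"] = (np.abs(out["log2fc"]) >= min_abs_log2fc) & (out["adjusted_p"] < max_adj_p)
    return out
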