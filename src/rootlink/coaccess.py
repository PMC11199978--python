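"""Distance-penalized co-accessibility of peak pairs on metacell counts.

The genome is tiled into overlapping windows (stride = window / 2). Within a
window, depth-normalized metacell accessibility is column-standardized and a
sparse precision matrix is estimated by a graphical lasso whose per-pair
penalty grows with genomic distance and becomes effectively infinite beyond
the distance constraint. The co-accessibility score of a pair is its partial
correlation, -P_ij / sqrt(P_ii * P_jj); pairs seen in several windows take
the mean score. With all penalties at zero the estimate reduces to the
inverse of the sample covariance, which is the module's oracle.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .types import GenomicInterval

logger = logging.getLogger("rootlink")

INFINITE_PENALTY = 1e12
DEFAULT_WINDOW = 500_000
DEFAULT_CONSTRAINT = 250_000
PENALTY_DISTANCE_SCALE = 50_000  # penalty weight = 1 + distance / this


@dataclass(frozen=True)
class CoaccessPair:
    """A scored unordered peak pair (canonical order peak_a < peak_b)."""

    peak_a: str
    peak_b: str
    score: float
    distance: float
    condition: str | None = None


def _soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def graphical_lasso_penalty_matrix(
    S: np.ndarray,
    penalty: np.ndarray,
    tol: float = 1e-9,
    max_sweeps: int = 500,
    inner_tol: float = 1e-10,
    max_inner: int = 1000,
) -> np.ndarray:
    """Penalized precision-matrix estimate with an element-wise L1 penalty.

    Block coordinate descent over columns: each column's off-diagonal block is
    a lasso sub-problem, solved exactly by a linear solve when its penalties
    are all zero and by cyclic coordinate descent otherwise. Returns the
    precision matrix Theta.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if S.shape != (p, p) or penalty.shape != (p, p):
        raise ValueError("S and penalty must be square and congruent")
    if p == 1:
        return np.array([[1.0 / S[0, 0]]])

    W = S + np.diag(np.diag(penalty))
    B = np.zeros((p, p))  # column j holds beta for block j
    idx_cache = [np.array([i for i in range(p) if i != j]) for j in range(p)]

    for _sweep in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            idx = idx_cache[j]
            W11 = W[np.ix_(idx, idx)]
            s12 = S[idx, j]
            rho = penalty[idx, j]
            beta = B[idx, j].copy()
            if not rho.any():
                beta = np.linalg.solve(W11, s12)
            else:
                diag = np.diag(W11).copy()
                for _it in range(max_inner):
                    delta = 0.0
                    for i in range(len(idx)):
                        r = s12[i] - W11[i] @ beta + diag[i] * beta[i]
                        new = _soft(r, rho[i]) / diag[i]
                        delta = max(delta, abs(new - beta[i]))
                        beta[i] = new
                    if delta < inner_tol:
                        break
            w12 = W11 @ beta
            max_delta = max(max_delta, float(np.max(np.abs(W[idx, j] - w12))))
            W[idx, j] = w12
            W[j, idx] = w12
            B[idx, j] = beta
        if max_delta < tol:
            break

    theta = np.zeros((p, p))
    for j in range(p):
        idx = idx_cache[j]
        beta = B[idx, j]
        denom = W[j, j] - W[idx, j] @ beta
        theta[j, j] = 1.0 / denom
        theta[idx, j] = -beta * theta[j, j]
    # symmetrize (block recovery is asymmetric only through round-off)
    return (theta + theta.T) / 2.0


def _window_scores(X: np.ndarray, distances: np.ndarray, alpha: float, constraint: float):
    """Partial-correlation scores for one window.

    X is metacell x peak, already depth-normalized; columns are standardized
    here. Returns (scores, nonzero_fraction_within_constraint).
    """
    n, p = X.shape
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    S = np.eye(p)
    if keep.sum() >= 2:
        Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        C = (Z.T @ Z) / (n - 1)
        S[np.ix_(keep, keep)] = C
    penalty = alpha * (1.0 + distances / PENALTY_DISTANCE_SCALE)
    penalty[distances > constraint] = INFINITE_PENALTY
    np.fill_diagonal(penalty, 0.0)
    if alpha == 0.0:
        # guard a singular covariance with a ridge jitter
        sub = S
        jitter = 0.0
        while True:
            try:
                np.linalg.cholesky(sub + jitter * np.eye(p))
                break
            except np.linalg.LinAlgError:
                jitter = max(jitter * 10, 1e-8)
                logger.info("coaccess: singular covariance, ridge jitter %.1e applied", jitter)
        S = S + jitter * np.eye(p)
    theta = graphical_lasso_penalty_matrix(S, penalty)
    d = np.sqrt(np.diag(theta))
    scores = -theta / np.outer(d, d)
    within = (distances <= constraint) & ~np.eye(p, dtype=bool)
    if within.any():
        nz = float((np.abs(theta[within]) > 1e-8).mean())
    else:
        nz = 0.0
    return scores, nz


def _iter_windows(peaks: Sequence[GenomicInterval], window: float, stride: float):
    mids = np.array([p.midpoint for p in peaks])
    chroms = np.array([p.chrom for p in peaks])
    for chrom in pd.unique(chroms):
        on = np.nonzero(chroms == chrom)[0]
        m = mids[on]
        lo, hi = m.min(), m.max()
        start = np.floor(lo / stride) * stride - stride
        w0 = start
        while w0 <= hi:
            sel = on[(m >= w0) & (m < w0 + window)]
            if len(sel) >= 2:
                yield sel
            w0 += stride


def _normalize_metacells(matrix: sp.spmatrix) -> np.ndarray:
    """Depth-normalize metacell columns and return metacell x peak floats."""
    dense = np.asarray(sp.csc_matrix(matrix).todense(), dtype=float)
    totals = dense.sum(axis=0)
    totals[totals == 0] = 1.0
    return (dense / totals[None, :] * 1e4).T


def tune_penalty(
    X: np.ndarray,
    peaks: Sequence[GenomicInterval],
    window: float,
    stride: float,
    constraint: float,
    target_nonzero: float = 0.1,
    n_sample_windows: int = 8,
    n_bisect: int = 12,
) -> float:
    """Choose the global penalty scalar so the mean fraction of nonzero
    within-constraint partial correlations over sampled windows is near the
    target. Deterministic: sample windows are evenly spaced in window order."""
    mids = np.array([p.midpoint for p in peaks])
    windows = list(_iter_windows(peaks, window, stride))
    if not windows:
        return 0.0
    take = windows[:: max(1, len(windows) // n_sample_windows)][:n_sample_windows]

    def mean_nonzero(alpha: float) -> float:
        fracs = []
        for sel in take:
            d = np.abs(mids[sel][:, None] - mids[sel][None, :])
            _, nz = _window_scores(X[:, sel], d, alpha, constraint)
            fracs.append(nz)
        return float(np.mean(fracs))

    lo, hi = 1e-4, 10.0
    if mean_nonzero(lo) <= target_nonzero:
        return lo
    if mean_nonzero(hi) >= target_nonzero:
        return hi
    for _ in range(n_bisect):
        mid = np.sqrt(lo * hi)
        if mean_nonzero(mid) > target_nonzero:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def coaccess_scores(
    metacell_matrix: sp.spmatrix,
    peaks: Sequence[GenomicInterval],
    window: float = DEFAULT_WINDOW,
    distance_constraint: float = DEFAULT_CONSTRAINT,
    alpha: float | None = None,
    target_nonzero: float = 0.1,
    condition: str | None = None,
) -> pd.DataFrame:
    """Score all within-constraint peak pairs on a peak x metacell matrix.

    Returns a DataFrame (peak_a, peak_b, score, distance, condition) with one
    row per unordered pair, peak ids in canonical (chrom, start) order, and
    scores averaged over the overlapping windows that contain the pair. When
    ``alpha`` is None the penalty scalar is tuned so that roughly
    ``target_nonzero`` of within-constraint pairs keep a nonzero partial
    correlation per window.
    """
    if metacell_matrix.shape[0] != len(peaks):
        raise ValueError("matrix rows must match peaks")
    stride = window / 2.0
    X = _normalize_metacells(metacell_matrix)
    if alpha is None:
        alpha = tune_penalty(X, peaks, window, stride, distance_constraint, target_nonzero)
        logger.info("coaccess: tuned penalty alpha=%.4g", alpha)
    mids = np.array([p.midpoint for p in peaks])
    names = [p.name if p.name else f"peak_{i}" for i, p in enumerate(peaks)]

    sums: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    for sel in _iter_windows(peaks, window, stride):
        d = np.abs(mids[sel][:, None] - mids[sel][None, :])
        scores, _ = _window_scores(X[:, sel], d, alpha, distance_constraint)
        p = len(sel)
        for a in range(p):
            for b in range(a + 1, p):
                if d[a, b] > distance_constraint:
                    continue
                key = (int(sel[a]), int(sel[b]))
                sums[key] = sums.get(key, 0.0) + float(scores[a, b])
                counts[key] = counts.get(key, 0) + 1

    rows = [
        {
            "peak_a": names[a],
            "peak_b": names[b],
            "score": sums[(a, b)] / counts[(a, b)],
            "distance": float(abs(mids[a] - mids[b])),
            "condition": condition,
        }
        for (a, b) in sorted(sums)
    ]
    return pd.DataFrame(rows, columns=["peak_a", "peak_b", "score", "distance", "condition"])


def threshold_pairs(pairs: pd.DataFrame, min_score: float = 0.1) -> pd.DataFrame:
    """Retain pairs with score strictly greater than ``min_score``."""
    return pairs[pairs["score"] > min_score].reset_index(drop=True)
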