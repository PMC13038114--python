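"""Gram-matrix coordinate-descent path kernel.

This is the numerical workhorse behind the bootstrap ensembles, where
hundreds of thousands of small penalized fits are required.  Working on
the Gram matrix ``G = X'X`` and correlation vector ``Xy = X'y`` lets the
Laplacian quadratic penalty be folded directly into ``G`` (the penalized
objective 1/2||y - Xb||^2 + l2 b'Mb + l1 sum w_j|b_j| has Gram form
1/2 b'(G + 2 l2 M)b - Xy'b + l1 sum w_j|b_j| up to a constant), so a
single weighted elastic-net kernel covers lasso, adaptive lasso, elastic
net and the network-constrained lasso.

The public single-fit API in :mod:`netrl.solvers` delegates standard
fits to scikit-learn; the test-suite cross-checks this kernel against
scikit-learn paths and a quadratic-programming oracle.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["cd_path", "lambda_grid"]


@njit(cache=True, fastmath=True)
def _cd_path_impl(G, Xy, lam_l1, ridges, l1w, tol, max_iter, df_cap, coefs):
    q = G.shape[0]
    beta = np.zeros(q)
    # residual correlations Rc[k] = Xy[k] - sum_j G[k, j] beta[j]
    Rc = Xy.copy()
    for a in range(lam_l1.shape[0]):
        if df_cap > 0:
            nnz = 0
            for j in range(q):
                if beta[j] != 0.0:
                    nnz += 1
            if nnz >= df_cap:
                # residual sum of squares is saturated: denser path points
                # cannot improve an information criterion, so freeze the path
                for j in range(q):
                    coefs[j, a] = beta[j]
                continue
        lam = lam_l1[a]
        ridge = ridges[a]
        for _ in range(max_iter):
            dmax = 0.0
            bmax = 1.0
            for j in range(q):
                denom = G[j, j] + ridge
                if denom <= 0.0:
                    continue
                bj = beta[j]
                cj = Rc[j] + G[j, j] * bj
                th = lam * l1w[j]
                if not np.isfinite(th):
                    nb = 0.0
                elif cj > th:
                    nb = (cj - th) / denom
                elif cj < -th:
                    nb = (cj + th) / denom
                else:
                    nb = 0.0
                d = nb - bj
                if d != 0.0:
                    beta[j] = nb
                    # G is symmetric: use the contiguous row G[j, :]
                    for k in range(q):
                        Rc[k] -= G[j, k] * d
                    ad = abs(d)
                    if ad > dmax:
                        dmax = ad
                ab = abs(nb)
                if ab > bmax:
                    bmax = ab
            if dmax <= tol * bmax:
                break
        for j in range(q):
            coefs[j, a] = beta[j]
    return coefs


def cd_path(
    G: np.ndarray,
    Xy: np.ndarray,
    lam_l1: np.ndarray,
    ridges: np.ndarray | None = None,
    l1_weights: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    df_cap: int = 0,
) -> np.ndarray:
    """Solve a descending path of penalized Gram problems.

    Parameters
    ----------
    G
        Penalized Gram matrix (q x q); any quadratic penalty is already
        folded in.
    Xy
        Predictor-response correlations ``X'y`` (length q).
    lam_l1
        Descending L1 penalty magnitudes (warm-started along the path).
    ridges
        Per-path-point diagonal (ridge) additions; zeros when omitted.
    l1_weights
        Per-coordinate L1 weight multipliers; ``inf`` excludes a
        coordinate entirely.
    tol
        Convergence threshold on the maximum coefficient change per
        sweep, relative to ``max(1, max|beta|)``.
    df_cap
        When positive, stop refining the path once the active set
        reaches ``df_cap`` coefficients (the remaining, denser path
        points repeat the frozen solution; useful when the caller
        selects by an information criterion that such points cannot
        win).

    Returns
    -------
    Array of shape ``(q, len(lam_l1))`` of coefficient vectors.
    """
    q = G.shape[0]
    lam_l1 = np.ascontiguousarray(lam_l1, dtype=float)
    if ridges is None:
        ridges = np.zeros_like(lam_l1)
    else:
        ridges = np.ascontiguousarray(ridges, dtype=float)
    if l1_weights is None:
        l1_weights = np.ones(q)
    coefs = np.zeros((q, lam_l1.shape[0]))
    _cd_path_impl(
        np.ascontiguousarray(G, dtype=float),
        np.ascontiguousarray(Xy, dtype=float),
        lam_l1,
        ridges,
        np.ascontiguousarray(l1_weights, dtype=float),
        tol,
        max_iter,
        df_cap,
        coefs,
    )
    return coefs


def lambda_grid(lam_max: float, count: int, min_ratio: float) -> np.ndarray:
    """Descending log-spaced L1 penalty grid from ``lam_max`` down."""
    if lam_max <= 0:
        return np.zeros(1)
    return np.geomspace(lam_max, lam_max * min_ratio, count)
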