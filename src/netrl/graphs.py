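"""Weighted gene graphs, the normalized Laplacian, and centrality scores.

A gene network is a weighted undirected graph G = (V, E, W) on the gene
universe, with symmetric nonnegative weights w_kj and node degrees
d_j = sum_k w_kj.  Two constructions are supported:

* from an averaged coefficient matrix of per-target regressions,
  ``w_kj = (|b_kj| + |b_jk|) / 2``;
* from the absolute gene-gene Pearson correlation matrix.

The normalized Laplacian of such a graph has unit diagonal on connected
nodes, off-diagonal entries ``-w_ij / sqrt(d_i d_j)``, and all-zero
rows/columns for isolated nodes; its spectrum lies in [0, 2].

Hubness (degree over maximum possible degree) and betweenness centrality
(fraction of all-pairs shortest paths through a node, normalized by the
ordered-pair count (|V|-1)(|V|-2)) are computed on a binary adjacency and
both live in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data import ExpressionMatrix

__all__ = [
    "WeightedGraph",
    "Laplacian",
    "CentralityScores",
    "adjacency_from_coefficients",
    "adjacency_from_correlation",
    "normalized_laplacian",
    "binarize",
    "hubness",
    "betweenness",
    "centrality_scores",
]

_SPECTRUM_TOL = 1e-8


@dataclass
class WeightedGraph:
    """Symmetric nonnegative weight matrix with zero diagonal."""

    gene_ids: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"weight matrix must be square, got shape {W.shape}")
        self.gene_ids = tuple(str(g) for g in self.gene_ids)
        if len(self.gene_ids) != W.shape[0]:
            raise ValueError("gene id count does not match weight matrix size")
        if not np.allclose(W, W.T, atol=1e-12, rtol=0.0):
            raise ValueError("weight matrix must be symmetric")
        W = 0.5 * (W + W.T)  # remove round-off asymmetry
        if np.any(W < 0):
            raise ValueError("edge weights must be nonnegative")
        np.fill_diagonal(W, 0.0)
        self.weights = W

    @property
    def n_genes(self) -> int:
        return self.weights.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        """Per-gene degree d_j = sum of incident edge weights."""
        return self.weights.sum(axis=1)


@dataclass
class Laplacian:
    """Normalized graph Laplacian together with its source graph."""

    matrix: np.ndarray
    source_graph: WeightedGraph

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return self.source_graph.gene_ids

    def submatrix(self, idx: np.ndarray) -> np.ndarray:
        """Rows/columns restricted to ``idx``; degrees are not recomputed."""
        idx = np.asarray(idx)
        return self.matrix[np.ix_(idx, idx)]


@dataclass
class CentralityScores:
    """Hubness and betweenness per gene plus the adjacency they used."""

    hubness: np.ndarray
    betweenness: np.ndarray
    adjacency_used: np.ndarray


def adjacency_from_coefficients(coef_matrix: np.ndarray, gene_ids=None) -> WeightedGraph:
    """Symmetrize an averaged coefficient matrix into edge weights.

    ``w_kj = (|b_kj| + |b_jk|) / 2``; the diagonal is ignored.
    """
    B = np.asarray(coef_matrix, dtype=float)
    if B.ndim != 2 or B.shape[0] != B.shape[1]:
        raise ValueError(f"coefficient matrix must be square, got shape {B.shape}")
    W = 0.5 * (np.abs(B) + np.abs(B.T))
    np.fill_diagonal(W, 0.0)
    if gene_ids is None:
        gene_ids = tuple(f"g{i}" for i in range(B.shape[0]))
    return WeightedGraph(gene_ids=tuple(gene_ids), weights=W)


def adjacency_from_correlation(X: ExpressionMatrix | np.ndarray, gene_ids=None) -> WeightedGraph:
    """Absolute Pearson correlation as edge weights, zero diagonal.

    Absolute values keep weights (hence degrees, hence the Laplacian's
    square roots) nonnegative.
    """
    if isinstance(X, ExpressionMatrix):
        vals = X.values
        gene_ids = X.gene_ids
    else:
        vals = np.asarray(X, dtype=float)
        if gene_ids is None:
            gene_ids = tuple(f"g{i}" for i in range(vals.shape[1]))
    if vals.shape[0] < 2:
        raise ValueError("at least two samples are required for correlations")
    sd = vals.std(axis=0)
    if np.any(sd == 0):
        bad = [gene_ids[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant expression column(s), correlation undefined: {bad}")
    W = np.abs(np.corrcoef(vals, rowvar=False))
    np.fill_diagonal(W, 0.0)
    return WeightedGraph(gene_ids=tuple(gene_ids), weights=W)


def normalized_laplacian(g: WeightedGraph) -> Laplacian:
    """L with l_ii = 1 on connected nodes, -w_ij/sqrt(d_i d_j) off-diagonal.

    Isolated nodes get all-zero rows and columns.
    """
    W = g.weights
    d = g.degrees
    connected = d > 0
    inv_sqrt = np.zeros_like(d)
    inv_sqrt[connected] = 1.0 / np.sqrt(d[connected])
    L = -(inv_sqrt[:, None] * W * inv_sqrt[None, :])
    np.fill_diagonal(L, np.where(connected, 1.0, 0.0))
    return Laplacian(matrix=L, source_graph=g)


def binarize(g: WeightedGraph | np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Binary adjacency ``a_jk = 1`` iff ``w_jk > threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    W = g.weights if isinstance(g, WeightedGraph) else np.asarray(g, dtype=float)
    A = (W > threshold).astype(float)
    A = np.maximum(A, A.T)
    np.fill_diagonal(A, 0.0)
    return A


def hubness(A: np.ndarray, p_star: int | None = None) -> np.ndarray:
    """Degree normalized by its maximum possible value ``p* - 1``."""
    A = np.asarray(A, dtype=float)
    if p_star is None:
        p_star = A.shape[0]
    if p_star < 2:
        raise ValueError("hubness requires a universe of at least 2 genes")
    return A.sum(axis=0) / (p_star - 1)


def betweenness(A: np.ndarray) -> np.ndarray:
    """Shortest-path betweenness on the symmetrized unweighted graph.

    Normalized by the ordered-pair count (|V|-1)(|V|-2); pairs with no
    connecting path contribute zero.  Fewer than three nodes yields zeros.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if n < 3:
        return np.zeros(n)
    G = nx.from_numpy_array((np.maximum(A, A.T) > 0).astype(int))
    # networkx's undirected normalization 2/((n-1)(n-2)) over unordered pairs
    # equals the ordered-pair convention used here.
    bc = nx.betweenness_centrality(G, normalized=True)
    return np.array([bc[i] for i in range(n)])


def centrality_scores(
    g: WeightedGraph | np.ndarray, threshold: float = 0.0, p_star: int | None = None
) -> CentralityScores:
    """Binarize a weighted graph and compute both centrality measures."""
    A = binarize(g, threshold)
    return CentralityScores(
        hubness=hubness(A, p_star=p_star),
        betweenness=betweenness(A),
        adjacency_used=A,
    )
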