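"""The three-stage network-constrained Random Lasso (netRL).

Stage 1 (gene importance): draw Omega bootstrap samples, fit a BIC-tuned
lasso of the target on a random subset of p1* regulators per replicate,
and combine the absolute averaged coefficient with graph centralities
into the importance C_j = ((H_j + B_j)/2) * |mean_omega beta_j|.

Stage 2 (network estimation): build the gene graph (from averaged
coefficients, correlations, or a prior network) and its normalized
Laplacian; draw a fresh bootstrap ensemble whose candidate sets of size
p2* are sampled with probability proportional to C_j; fit a BIC-tuned
network-constrained lasso per replicate on the candidate sub-Laplacian;
aggregate edge weights as the mean (or median) over all Omega replicates,
counting zeros for genes a replicate did not sample.

Stage 3 (edge significance): assess each regulator's replicate selection
count m_j by a permutation test (re-running stage 2 on response-permuted
data with the identical candidate stream), a hypergeometric tail test
against the random-subsampling null, or a percentile bootstrap interval.

All randomness flows from a single integer seed; repeated runs are
byte-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._cd import cd_path, lambda_grid
from .config import RunConfig
from .data import ExpressionMatrix
from .graphs import (
    Laplacian,
    WeightedGraph,
    adjacency_from_coefficients,
    adjacency_from_correlation,
    centrality_scores,
    normalized_laplacian,
)
from .solvers import DesignData, _one_se_index, estimate_sigma2

__all__ = [
    "BootstrapEnsemble",
    "ImportanceVector",
    "EdgeSignificance",
    "GeneNetwork",
    "TargetResult",
    "gene_importance",
    "stage1_ensemble",
    "stage1_sweep",
    "stage1_importance",
    "weighted_subset_sample",
    "stage2_estimate",
    "permutation_pvalues",
    "permutation_edge_test",
    "hypergeometric_pvalues",
    "hypergeometric_edge_test",
    "percentile_interval",
    "bootstrap_ci_filter",
    "infer_regulators",
    "infer_target_network",
    "infer_full_network",
    "derive_target_seed",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class BootstrapEnsemble:
    """Per-replicate candidate sets and coefficient vectors for one target."""

    target_id: str
    candidate_sets: list[np.ndarray]
    coefficients: np.ndarray  # (omega, q), zeros outside each candidate set
    sample_indices: list[np.ndarray]

    @property
    def omega(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_genes(self) -> int:
        return self.coefficients.shape[1]

    def mean_coefficients(self) -> np.ndarray:
        """Average over all Omega replicates, zeros included."""
        return self.coefficients.mean(axis=0)

    def median_coefficients(self) -> np.ndarray:
        return np.median(self.coefficients, axis=0)

    def selection_counts(self) -> np.ndarray:
        """m_j = number of replicates in which gene j got a nonzero weight."""
        return np.count_nonzero(self.coefficients, axis=0)

    def candidacy_counts(self) -> np.ndarray:
        """Number of replicates whose candidate set contains each gene."""
        counts = np.zeros(self.n_genes, dtype=int)
        for cand in self.candidate_sets:
            counts[cand] += 1
        return counts


@dataclass
class ImportanceVector:
    """Gene importance C_j = ((H_j + B_j)/2) * |mean bootstrap coefficient|."""

    C: np.ndarray
    H: np.ndarray
    B: np.ndarray
    mean_abs_beta: np.ndarray


@dataclass
class EdgeSignificance:
    """Per-regulator significance records for one target gene."""

    selection_count: np.ndarray
    candidacy_count: np.ndarray
    p_perm: np.ndarray | None = None
    p_hyper: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    permutation_counts: np.ndarray | None = None  # (pi, q)
    selected: np.ndarray | None = None


_EDGE_COLUMNS = [
    "regulator",
    "target",
    "weight",
    "m",
    "p_perm",
    "p_hyper",
    "ci_low",
    "ci_high",
    "selected",
]


@dataclass
class GeneNetwork:
    """Directed weighted edges (regulator -> target) with significance."""

    edges: pd.DataFrame
    gene_ids: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.edges.columns) != _EDGE_COLUMNS:
            self.edges = self.edges.reindex(columns=_EDGE_COLUMNS)
        if (self.edges["regulator"] == self.edges["target"]).any():
            raise ValueError("self-edges are not allowed")

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class TargetResult:
    """Everything netRL computed for one target gene."""

    target_id: str
    gene_ids: tuple[str, ...]
    beta: np.ndarray  # aggregated stage-2 coefficients (standardized scale)
    selected: np.ndarray
    importance: ImportanceVector
    significance: EdgeSignificance
    stage1: BootstrapEnsemble
    stage2: BootstrapEnsemble
    network: GeneNetwork


# ---------------------------------------------------------------------------
# BIC-tuned gram fits (hot path)


def _bic_best(G_pen, G_real, Xy, yty, lam1s, n_real, sigma2, cd_tol, max_iter):
    """Best fit along one L1 path by BIC; first minimum = largest lambda1."""
    coefs = cd_path(G_pen, Xy, lam1s, tol=cd_tol, max_iter=max_iter, df_cap=n_real)
    GB = G_real @ coefs
    rss = yty - 2.0 * (Xy @ coefs) + np.einsum("ja,ja->a", coefs, GB)
    df = np.count_nonzero(coefs, axis=0)
    bics = rss / (n_real * sigma2) + (np.log(n_real) / n_real) * df
    a = int(np.argmin(bics))
    return coefs[:, a], float(bics[a]), float(lam1s[a])


def _bic_best_over_lambda2(grams_pen, lambda2s, G_real, Xy, yty, lam1s, n_real, sigma2, cd_tol, max_iter):
    """Best (lambda1, lambda2) combination; ties favor larger penalties."""
    best = None
    for G_pen, lam2 in zip(grams_pen, lambda2s):
        beta, b, lam1 = _bic_best(G_pen, G_real, Xy, yty, lam1s, n_real, sigma2, cd_tol, max_iter)
        key = (b, -lam1, -lam2)
        if best is None or key < best[0]:
            best = (key, beta)
    return best[1]


# ---------------------------------------------------------------------------
# stage 1


def gene_importance(H: np.ndarray, B: np.ndarray, mean_beta: np.ndarray) -> np.ndarray:
    """C_j = ((H_j + B_j) / 2) * |mean bootstrap coefficient_j|.

    The centrality factor lies in [0, 1], so it modulates the
    statistical evidence without changing its scale.
    """
    H = np.asarray(H, dtype=float)
    B = np.asarray(B, dtype=float)
    return 0.5 * (H + B) * np.abs(np.asarray(mean_beta, dtype=float))


def stage1_ensemble(
    Xs: np.ndarray,
    y: np.ndarray,
    omega: int,
    p1_star: int,
    n_boot: int,
    rng: np.random.Generator,
    config: RunConfig,
    sigma2: float,
    target_id: str = "target",
) -> BootstrapEnsemble:
    """Bootstrap ensemble of BIC-tuned lasso fits on random regulator subsets."""
    n, q = Xs.shape
    if omega < 1:
        raise ValueError("omega must be at least 1")
    if p1_star > q:
        raise ValueError(f"p1_star={p1_star} exceeds the regulator universe ({q})")
    coefs = np.zeros((omega, q))
    cands: list[np.ndarray] = []
    rows_list: list[np.ndarray] = []
    for w in range(omega):
        rows = rng.integers(0, n, size=n_boot)
        cand = np.sort(rng.choice(q, size=p1_star, replace=False))
        Xb = Xs[rows][:, cand]
        yb = y[rows]
        G = Xb.T @ Xb
        Xy = Xb.T @ yb
        lam_max = float(np.max(np.abs(Xy), initial=0.0))
        if lam_max > 0.0:
            lam1s = lambda_grid(lam_max, config.lambda1_count, config.lambda1_min_ratio)
            beta, _, _ = _bic_best(
                G, G, Xy, float(yb @ yb), lam1s, n_boot, sigma2,
                config.cd_tol, config.max_iter,
            )
            coefs[w, cand] = beta
        cands.append(cand)
        rows_list.append(rows)
    return BootstrapEnsemble(
        target_id=target_id, candidate_sets=cands, coefficients=coefs,
        sample_indices=rows_list,
    )


def stage1_sweep(
    Xs: np.ndarray,
    omega: int,
    p1_star: int | None,
    n_boot: int,
    seed: int,
    config: RunConfig,
) -> np.ndarray:
    """Averaged stage-1 coefficient matrix with every gene as target.

    Row ``t`` holds the bootstrap-averaged lasso coefficients of gene t
    regressed on the remaining genes; the diagonal is zero.  This is the
    coefficient matrix behind the averaged-coefficient adjacency.
    """
    n, p = Xs.shape
    B = np.zeros((p, p))
    rng = np.random.default_rng(seed)
    for t in range(p):
        others = np.delete(np.arange(p), t)
        y_t = Xs[:, t] - Xs[:, t].mean()
        ps = min(p1_star or -(-(p - 1) // 2), p - 1)
        sigma2_t = estimate_sigma2(
            DesignData(X=Xs[:, others], y=y_t, column_ids=[str(j) for j in others],
                       standardized=False)
        )
        ens = stage1_ensemble(
            Xs[:, others], y_t, omega, ps, n_boot, rng, config, sigma2_t,
            target_id=str(t),
        )
        B[t, others] = ens.mean_coefficients()
    return B


def stage1_importance(
    Xs: np.ndarray,
    y: np.ndarray,
    omega: int,
    p1_star: int,
    n_boot: int,
    rng: np.random.Generator,
    config: RunConfig,
    sigma2: float,
    centrality: tuple[np.ndarray, np.ndarray] | None = None,
    prior: WeightedGraph | None = None,
    sweep_seed: int | None = None,
    target_id: str = "target",
) -> tuple[ImportanceVector, BootstrapEnsemble]:
    """Stage 1: bootstrap coefficients weighted by graph centralities.

    Centralities come from, in order of precedence: the ``centrality``
    pair (H, B) if precomputed, the binarized ``prior`` graph, or the
    binarized averaged-coefficient adjacency from an all-target sweep.
    """
    q = Xs.shape[1]
    ens = stage1_ensemble(Xs, y, omega, p1_star, n_boot, rng, config, sigma2, target_id)
    mean_beta = ens.mean_coefficients()
    mean_abs = np.abs(mean_beta)
    if centrality is not None:
        H, B = centrality
    elif prior is not None:
        cs = centrality_scores(prior, config.binarize_threshold)
        H, B = cs.hubness, cs.betweenness
    else:
        Bmat = stage1_sweep(
            Xs, config.adjacency_omega or omega, p1_star, n_boot,
            sweep_seed if sweep_seed is not None else 0, config,
        )
        W = adjacency_from_coefficients(Bmat)
        cs = centrality_scores(W, config.binarize_threshold)
        H, B = cs.hubness, cs.betweenness
    H = np.asarray(H, dtype=float)
    B = np.asarray(B, dtype=float)
    if H.shape != (q,) or B.shape != (q,):
        raise ValueError("centrality length does not match the regulator universe")
    C = gene_importance(H, B, mean_beta)
    imp = ImportanceVector(C=C, H=H, B=B, mean_abs_beta=mean_abs)
    return imp, ens


# ---------------------------------------------------------------------------
# stage 2


def weighted_subset_sample(
    C: np.ndarray | ImportanceVector,
    p2_star: int,
    rng: np.random.Generator,
    floor: float = 1e-6,
) -> np.ndarray:
    """Draw p2* distinct genes, successive probabilities proportional to C_j.

    Implemented with Gumbel-perturbed log-weights (Efraimidis-Spirakis
    keys), which is distributionally identical to successive draws
    without replacement.  Zero-importance genes get ``floor * max(C)``
    so the draw stays feasible; with ``floor=0`` and fewer than p2*
    positive weights an error is raised.
    """
    w = np.asarray(C.C if isinstance(C, ImportanceVector) else C, dtype=float)
    q = w.shape[0]
    if p2_star > q:
        raise ValueError(f"p2_star={p2_star} exceeds the regulator universe ({q})")
    if np.any(w < 0):
        raise ValueError("importance values must be nonnegative")
    cmax = w.max(initial=0.0)
    if cmax == 0.0:
        if floor <= 0.0:
            raise ValueError("all importances are zero and the floor is disabled")
        w = np.ones(q)
    elif floor > 0.0:
        w = np.where(w > 0.0, w, floor * cmax)
    elif np.count_nonzero(w) < p2_star:
        raise ValueError("fewer positive importances than p2_star with floor disabled")
    with np.errstate(divide="ignore"):
        keys = np.log(w) + rng.gumbel(size=q)
    idx = np.argpartition(-keys, p2_star - 1)[:p2_star]
    return np.sort(idx)


class Stage2Runner:
    """Stage-2 ensemble with a frozen bootstrap/candidate stream.

    The row draws, candidate sets and penalized Gram matrices are fixed
    at construction, so the same ensemble can be re-run on a permuted
    response (only the correlation vector X'y changes), which is exactly
    the permutation null the edge test requires.
    """

    def __init__(
        self,
        Xs: np.ndarray,
        omega: int,
        p2_star: int,
        n_boot: int,
        importance: np.ndarray,
        L_full: np.ndarray | None,
        sign_reference: np.ndarray | None,
        config: RunConfig,
        rng: np.random.Generator,
        target_id: str = "target",
    ) -> None:
        n, q = Xs.shape
        if p2_star > q:
            raise ValueError(f"p2_star={p2_star} exceeds the regulator universe ({q})")
        if importance.shape != (q,):
            raise ValueError("importance length does not match the regulator universe")
        self.config = config
        self.target_id = target_id
        self.n_genes = q
        self.omega = omega
        self.p2_star = p2_star
        if L_full is None:
            self.lambda2s = (0.0,)
            M = None
        else:
            if L_full.shape != (q, q):
                raise ValueError("Laplacian shape does not match the regulator universe")
            self.lambda2s = tuple(config.lambda2_values)
            s = np.sign(np.ones(q) if sign_reference is None else np.asarray(sign_reference, float))
            s[s == 0.0] = 1.0
            M = (s[:, None] * L_full) * s[None, :]
        self._replicates = []
        for _ in range(omega):
            rows = rng.integers(0, n, size=n_boot)
            cand = weighted_subset_sample(importance, p2_star, rng, config.importance_floor)
            Xb = Xs[rows][:, cand]
            G = Xb.T @ Xb
            grams = []
            for lam2 in self.lambda2s:
                if lam2 == 0.0 or M is None:
                    grams.append(G)
                else:
                    grams.append(G + 2.0 * lam2 * M[np.ix_(cand, cand)])
            self._replicates.append((rows, cand, Xb, G, grams))

    @property
    def candidate_sets(self) -> list[np.ndarray]:
        return [cand for _, cand, _, _, _ in self._replicates]

    @property
    def sample_indices(self) -> list[np.ndarray]:
        return [rows for rows, _, _, _, _ in self._replicates]

    def run(self, y: np.ndarray, sigma2: float) -> np.ndarray:
        """Fit every replicate on response ``y``; returns (omega, q) coefficients."""
        cfg = self.config
        out = np.zeros((self.omega, self.n_genes))
        n_boot = self._replicates[0][0].shape[0]
        for w, (rows, cand, Xb, G, grams) in enumerate(self._replicates):
            yb = y[rows]
            Xy = Xb.T @ yb
            lam_max = float(np.max(np.abs(Xy), initial=0.0))
            if lam_max == 0.0:
                continue
            lam1s = lambda_grid(lam_max, cfg.lambda1_count, cfg.lambda1_min_ratio)
            beta = _bic_best_over_lambda2(
                grams, self.lambda2s, G, Xy, float(yb @ yb), lam1s,
                n_boot, sigma2, cfg.cd_tol, cfg.max_iter,
            )
            out[w, cand] = beta
        return out

    def ensemble(self, y: np.ndarray, sigma2: float) -> BootstrapEnsemble:
        coefs = self.run(y, sigma2)
        return BootstrapEnsemble(
            target_id=self.target_id,
            candidate_sets=self.candidate_sets,
            coefficients=coefs,
            sample_indices=self.sample_indices,
        )


def stage2_estimate(
    Xs: np.ndarray,
    y: np.ndarray,
    omega: int,
    p2_star: int,
    importance: ImportanceVector | np.ndarray,
    L_full: Laplacian | np.ndarray | None,
    sign_reference: np.ndarray | None,
    n_boot: int,
    rng: np.random.Generator,
    config: RunConfig,
    sigma2: float,
    target_id: str = "target",
) -> tuple[np.ndarray, BootstrapEnsemble]:
    """Stage 2: importance-weighted network-constrained bootstrap ensemble.

    Returns the aggregated coefficient vector (mean or median over all
    Omega replicates, zeros counted) and the ensemble itself.
    """
    imp = importance.C if isinstance(importance, ImportanceVector) else np.asarray(importance, float)
    Lm = L_full.matrix if isinstance(L_full, Laplacian) else L_full
    runner = Stage2Runner(
        Xs, omega, p2_star, n_boot, imp, Lm, sign_reference, config, rng, target_id
    )
    ens = runner.ensemble(y, sigma2)
    agg = ens.median_coefficients() if config.aggregation == "median" else ens.mean_coefficients()
    return agg, ens


# ---------------------------------------------------------------------------
# stage 3: significance


def permutation_pvalues(m: np.ndarray, perm_counts: np.ndarray) -> np.ndarray:
    """p_j = #{phi : m_j^(phi) >= m_j} / Pi."""
    m = np.asarray(m)
    perm_counts = np.atleast_2d(perm_counts)
    return (perm_counts >= m[None, :]).mean(axis=0)


def permutation_edge_test(
    runner: Stage2Runner,
    y: np.ndarray,
    observed: BootstrapEnsemble,
    pi_reps: int,
    rng: np.random.Generator,
    sigma2_fn=None,
    sigma2: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation selection-frequency test for every regulator.

    Permutes the response across samples and re-runs the frozen stage-2
    ensemble; ``sigma2_fn(y_perm)`` supplies the per-permutation noise
    variance (a fixed ``sigma2`` may be passed instead).

    Returns ``(p_values, permutation_counts)`` with counts of shape
    ``(pi_reps, q)``.
    """
    if pi_reps < 1:
        raise ValueError("pi_reps must be at least 1")
    m = observed.selection_counts()
    counts = np.zeros((pi_reps, observed.n_genes), dtype=int)
    for phi in range(pi_reps):
        y_perm = y[rng.permutation(y.shape[0])]
        s2 = sigma2_fn(y_perm) if sigma2_fn is not None else sigma2
        coefs = runner.run(y_perm, s2)
        counts[phi] = np.count_nonzero(coefs, axis=0)
    return permutation_pvalues(m, counts), counts


def hypergeometric_pvalues(
    m: np.ndarray, candidacy: np.ndarray, omega: int, p2_star: int
) -> np.ndarray:
    """Upper-tail hypergeometric p-values against the subsampling null.

    Population: N = Omega * p2* candidate slots; successes: K = total
    nonzero selections for this target; draws: gene j's candidacy count
    n_j; observed: m_j.  p_j = P(Hypergeom(N, K, n_j) >= m_j).
    """
    m = np.asarray(m, dtype=int)
    candidacy = np.asarray(candidacy, dtype=int)
    if np.any(m > candidacy):
        raise ValueError("selection count exceeds candidacy count")
    N = omega * p2_star
    K = int(m.sum())
    return stats.hypergeom.sf(m - 1, N, K, candidacy)


def hypergeometric_edge_test(observed: BootstrapEnsemble, p2_star: int | None = None) -> np.ndarray:
    m = observed.selection_counts()
    candidacy = observed.candidacy_counts()
    if p2_star is None:
        p2_star = len(observed.candidate_sets[0])
    return hypergeometric_pvalues(m, candidacy, observed.omega, p2_star)


def percentile_interval(coefficients: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """(alpha/2, 1 - alpha/2) empirical quantiles per gene (linear interpolation)."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie strictly between 0 and 1")
    lo = np.quantile(coefficients, alpha / 2.0, axis=0)
    hi = np.quantile(coefficients, 1.0 - alpha / 2.0, axis=0)
    return lo, hi


def bootstrap_ci_filter(
    observed: BootstrapEnsemble, alpha: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Percentile bootstrap interval; a gene is kept iff 0 is outside it."""
    if observed.omega < 2:
        raise ValueError("at least 2 bootstrap replicates are required")
    lo, hi = percentile_interval(observed.coefficients, alpha)
    selected = (lo > 0.0) | (hi < 0.0)
    return lo, hi, selected


# ---------------------------------------------------------------------------
# orchestration


def derive_target_seed(master_seed: int, gene_id: str) -> int:
    """Stable per-target seed from the master seed and the gene identifier."""
    h = zlib.crc32(str(gene_id).encode("utf-8"))
    return int((h ^ (master_seed & 0xFFFFFFFF)) & 0x7FFFFFFF)


def _default_p_star(universe: int) -> int:
    return -(-universe // 2)  # ceil(universe / 2)


def _graph_and_centrality(
    Xs: np.ndarray,
    config: RunConfig,
    sweep_seed: int,
    prior: WeightedGraph | None,
    n_boot: int,
):
    """Gene graph, Laplacian and centrality weights for the universe."""
    q = Xs.shape[1]
    variant = config.adjacency_variant
    if variant == "none":
        return None, None, np.ones(q), np.ones(q)
    if variant == "prior":
        if prior is None:
            raise ValueError("adjacency_variant='prior' requires a prior network")
        W = prior
    elif variant == "corr":
        W = adjacency_from_correlation(Xs)
    else:  # beta
        omega_sweep = config.adjacency_omega or config.omega
        Bmat = stage1_sweep(Xs, omega_sweep, config.p1_star, n_boot, sweep_seed, config)
        W = adjacency_from_coefficients(Bmat)
    cs = centrality_scores(W, config.binarize_threshold)
    L = normalized_laplacian(W)
    needs_penalty = any(v > 0 for v in config.lambda2_values)
    return W, (L.matrix if needs_penalty else None), cs.hubness, cs.betweenness


def _sigma2_estimator(Xs: np.ndarray, k: int = 5, count: int = 30, min_ratio: float = 0.01):
    """Reusable per-response noise-variance estimator for a fixed design.

    ``q < n``: OLS residual variance.  ``q >= n``: the CV-lasso plug-in
    RSS(lambda_CV)/(n - df) with fold Gram matrices precomputed, so the
    permutation test can re-estimate sigma^2 cheaply for every permuted
    response.
    """
    n, q = Xs.shape
    if q < n:
        pinv = np.linalg.pinv(Xs)

        def est(y: np.ndarray) -> float:
            r = y - Xs @ (pinv @ y)
            return max(float(r @ r) / max(n - q, 1), 1e-12)

        return est
    k = min(k, n)
    idx = np.arange(n)
    folds = []
    for i in range(k):
        va = idx[i::k]
        tr = np.setdiff1d(idx, va)
        Xtr = Xs[tr]
        folds.append((tr, va, Xtr.T @ Xtr, Xtr, Xs[va]))
    G_full = Xs.T @ Xs

    def est(y: np.ndarray) -> float:
        Xy = Xs.T @ y
        lam_max = float(np.max(np.abs(Xy), initial=0.0))
        if lam_max == 0.0:
            return max(float(y @ y) / max(n - 1, 1), 1e-12)
        lams = lambda_grid(lam_max, count, min_ratio)
        fold_mse = np.zeros((len(folds), len(lams)))
        for i, (tr, va, Gtr, Xtr, Xva) in enumerate(folds):
            coefs = cd_path(Gtr, Xtr.T @ y[tr], lams, tol=1e-5, df_cap=tr.shape[0])
            R = y[va][:, None] - Xva @ coefs
            fold_mse[i] = np.mean(R * R, axis=0)
        li = _one_se_index(fold_mse)
        beta = cd_path(G_full, Xy, lams[: li + 1], tol=1e-6)[:, li]
        df = int(np.count_nonzero(beta))
        rss = float(y @ y) - 2.0 * float(Xy @ beta) + float(beta @ (G_full @ beta))
        return max(max(rss, 0.0) / max(n - df, 1), 1e-12)

    return est


def infer_regulators(
    X: np.ndarray | ExpressionMatrix,
    y: np.ndarray,
    config: RunConfig | None = None,
    seed: int = 0,
    gene_ids=None,
    target_id: str = "target",
    prior: WeightedGraph | None = None,
    graph_centrality=None,
) -> TargetResult:
    """Run the full netRL pipeline for one target with an external response.

    ``X`` holds the candidate regulators (raw scale; standardized
    internally) and ``y`` the target's expression.  ``graph_centrality``
    may carry a precomputed ``(W, L_matrix, H, B)`` tuple so that a
    shared graph is reused across targets.
    """
    config = config or RunConfig()
    if isinstance(X, ExpressionMatrix):
        gene_ids = X.gene_ids
        Xs = X.values if X.standardized else X.standardize().values
    else:
        X = np.asarray(X, dtype=float)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant regulator column(s)")
        Xs = (X - X.mean(axis=0)) / sd
    n, q = Xs.shape
    if gene_ids is None:
        gene_ids = tuple(f"g{j}" for j in range(q))
    gene_ids = tuple(map(str, gene_ids))
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    n_boot = config.n_boot or n
    p1 = config.p1_star or _default_p_star(q)
    p2 = config.p2_star or _default_p_star(q)
    if p1 > q or p2 > q:
        raise ValueError("candidate-set size exceeds the regulator universe")

    ss = np.random.SeedSequence(seed)
    s_stage1, s_sweep, s_stage2, s_perm = ss.spawn(4)
    sigma2_fn = _sigma2_estimator(Xs)
    sigma2 = config.sigma2 if config.sigma2 is not None else sigma2_fn(yc)

    if graph_centrality is None:
        _, Lm, H, B = _graph_and_centrality(
            Xs, config, int(s_sweep.generate_state(1)[0] >> 1), prior, n_boot
        )
    else:
        _, Lm, H, B = graph_centrality

    imp, ens1 = stage1_importance(
        Xs, yc, config.omega, p1, n_boot, np.random.default_rng(s_stage1),
        config, sigma2, centrality=(H, B), target_id=target_id,
    )
    sign_ref = np.sign(ens1.mean_coefficients())

    runner = Stage2Runner(
        Xs, config.omega, p2, n_boot, imp.C, Lm, sign_ref, config,
        np.random.default_rng(s_stage2), target_id,
    )
    ens2 = runner.ensemble(yc, sigma2)
    beta = (
        ens2.median_coefficients()
        if config.aggregation == "median"
        else ens2.mean_coefficients()
    )

    m = ens2.selection_counts()
    candidacy = ens2.candidacy_counts()
    p_hyper = hypergeometric_pvalues(m, candidacy, config.omega, p2)
    if config.omega >= 2:
        ci_low, ci_high, ci_sel = bootstrap_ci_filter(ens2, config.alpha)
    else:
        ci_low = ci_high = None
        ci_sel = None
    p_perm = perm_counts = None
    if config.criterion == "perm":
        p_perm, perm_counts = permutation_edge_test(
            runner, yc, ens2, config.pi_reps, np.random.default_rng(s_perm),
            sigma2_fn=None if config.sigma2 is not None else sigma2_fn,
            sigma2=config.sigma2,
        )

    if config.criterion == "perm":
        selected = p_perm <= config.alpha
    elif config.criterion == "hyper":
        selected = p_hyper <= config.alpha
    elif config.criterion == "ci":
        selected = ci_sel
    else:
        selected = np.abs(beta) > config.coef_threshold
    selected = selected & (beta != 0.0)

    sig = EdgeSignificance(
        selection_count=m,
        candidacy_count=candidacy,
        p_perm=p_perm,
        p_hyper=p_hyper,
        ci_low=ci_low,
        ci_high=ci_high,
        permutation_counts=perm_counts,
        selected=selected,
    )
    network = _edges_dataframe(target_id, gene_ids, beta, sig, config, seed)
    return TargetResult(
        target_id=target_id,
        gene_ids=gene_ids,
        beta=beta,
        selected=selected,
        importance=imp,
        significance=sig,
        stage1=ens1,
        stage2=ens2,
        network=network,
    )


def _edges_dataframe(
    target_id: str,
    gene_ids: tuple[str, ...],
    beta: np.ndarray,
    sig: EdgeSignificance,
    config: RunConfig,
    seed: int,
) -> GeneNetwork:
    idx = np.flatnonzero(sig.selected)
    df = pd.DataFrame(
        {
            "regulator": [gene_ids[j] for j in idx],
            "target": target_id,
            "weight": beta[idx],
            "m": sig.selection_count[idx],
            "p_perm": sig.p_perm[idx] if sig.p_perm is not None else np.nan,
            "p_hyper": sig.p_hyper[idx] if sig.p_hyper is not None else np.nan,
            "ci_low": sig.ci_low[idx] if sig.ci_low is not None else np.nan,
            "ci_high": sig.ci_high[idx] if sig.ci_high is not None else np.nan,
            "selected": True,
        },
        columns=_EDGE_COLUMNS,
    )
    meta = {
        "target": target_id,
        "criterion": config.criterion,
        "omega": config.omega,
        "pi_reps": config.pi_reps,
        "alpha": config.alpha,
        "adjacency_variant": config.adjacency_variant,
        "aggregation": config.aggregation,
        "seed": seed,
        "total_edges": len(df),
    }
    return GeneNetwork(edges=df, gene_ids=gene_ids, metadata=meta)


def infer_target_network(
    X: ExpressionMatrix,
    target: str,
    config: RunConfig | None = None,
    seed: int = 0,
    prior: WeightedGraph | None = None,
) -> tuple[GeneNetwork, EdgeSignificance]:
    """netRL for one target gene inside an expression matrix."""
    net = infer_full_network(X, [target], config=config, seed=seed, prior=prior)
    sig = net.metadata.pop("_significance")[target]
    return net, sig


def infer_full_network(
    X: ExpressionMatrix,
    targets,
    config: RunConfig | None = None,
    seed: int = 0,
    prior: WeightedGraph | None = None,
) -> GeneNetwork:
    """Per-target netRL over a list of targets; edges are unioned.

    The gene graph (and hence the Laplacian and centralities) is built
    once over the full gene universe and shared across targets; each
    target then runs with its own seed derived from the master seed and
    the gene identifier, making the result independent of target order.
    """
    config = config or RunConfig()
    targets = list(targets)
    if not targets:
        raise ValueError("empty target list")
    unknown = [t for t in targets if t not in X.gene_ids]
    if unknown:
        raise KeyError(f"targets not in the expression matrix: {unknown}")
    Xstd = X if X.standardized else X.standardize()
    p = Xstd.n_genes
    n_boot = config.n_boot or Xstd.n_samples
    _, Lm_full, H_full, B_full = _graph_and_centrality(
        Xstd.values, config, derive_target_seed(seed, "__sweep__"), prior, n_boot
    )

    frames = []
    sigs: dict[str, EdgeSignificance] = {}
    all_ids = Xstd.gene_ids
    for target in targets:
        t_idx = all_ids.index(target)
        others = np.delete(np.arange(p), t_idx)
        sub_ids = tuple(all_ids[j] for j in others)
        Lm = Lm_full[np.ix_(others, others)] if Lm_full is not None else None
        H = H_full[others] if H_full is not None else None
        B = B_full[others] if B_full is not None else None
        res = infer_regulators(
            ExpressionMatrix(
                Xstd.values[:, others], sub_ids, Xstd.sample_ids, standardized=True
            ),
            Xstd.values[:, t_idx],
            config=config,
            seed=derive_target_seed(seed, target),
            target_id=target,
            graph_centrality=(None, Lm, H, B),
        )
        frames.append(res.network.edges)
        sigs[target] = res.significance
    edges = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=_EDGE_COLUMNS)
    meta = {
        "targets": targets,
        "criterion": config.criterion,
        "omega": config.omega,
        "alpha": config.alpha,
        "adjacency_variant": config.adjacency_variant,
        "seed": seed,
        "target_seeds": {t: derive_target_seed(seed, t) for t in targets},
        "total_edges": len(edges),
        "_significance": sigs,
    }
    return GeneNetwork(edges=edges, gene_ids=all_ids, metadata=meta)
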