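"""Penalized regressions for edge-weight estimation and BIC tuning.

Every fit minimizes, over the coefficient vector b of a centered
response y on standardized predictors X,

    1/2 ||y - X b||^2 + penalty(b)

with penalty

* lasso:            l1 * sum |b_j|
* adaptive lasso:   l1 * sum w_j |b_j|,  w_j = 1/|b_init,j|
* elastic net:      l1 * sum { (1-delta)/2 b_j^2 + delta |b_j| }
* network lasso:    l1 * sum |b_j| + l2 * (S b)' L (S b)

where L is a normalized graph Laplacian, S = diag(s) carries the signs
of a preliminary estimate (so negatively related neighbors are smoothed
toward equal magnitude rather than equal value), and the quadratic term
is solved through the augmented-data lasso reformulation.

Hyperparameters are chosen by minimizing

    BIC = ||y - yhat||^2 / (n sigma^2) + (log n / n) * df

with df the number of nonzero coefficients and sigma^2 a plug-in noise
variance estimated once per dataset (OLS residual variance when q < n,
GCV-tuned ridge residual variance otherwise).

Standard single fits delegate to scikit-learn's coordinate descent; the
ensemble machinery in :mod:`netrl.pipeline` uses the Gram-path kernel in
:mod:`netrl._cd`, and the two routes are cross-checked in the tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNet, Lasso

from ._cd import cd_path, lambda_grid
from .graphs import Laplacian

__all__ = [
    "DesignData",
    "FitResult",
    "PenaltyGrid",
    "fit_lasso",
    "fit_adaptive_lasso",
    "fit_elastic_net",
    "fit_network_lasso",
    "bic",
    "estimate_sigma2",
    "select_by_bic",
]

_PSD_TOL = 1e-8


@dataclass
class DesignData:
    """Centered response and standardized predictors for one target."""

    X: np.ndarray
    y: np.ndarray
    column_ids: tuple[str, ...]
    standardized: bool = True

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must match the number of rows of X")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("design data contain NaN or infinite values")
        self.column_ids = tuple(str(c) for c in self.column_ids)
        if len(self.column_ids) != self.X.shape[1]:
            raise ValueError("column id count does not match X")
        if self.standardized:
            if np.max(np.abs(self.X.mean(axis=0)), initial=0.0) > 1e-8:
                raise ValueError("standardized X must have zero-mean columns")
            if self.X.shape[0] > 1:
                sd = self.X.std(axis=0, ddof=1)
                if np.max(np.abs(sd - 1.0), initial=0.0) > 1e-6:
                    raise ValueError("standardized X must have unit-sd columns")
            if abs(self.y.mean()) > 1e-8:
                raise ValueError("y must be centered")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def q(self) -> int:
        return self.X.shape[1]

    @classmethod
    def build(cls, X, y, column_ids=None, standardize: bool = True) -> "DesignData":
        """Standardize raw predictors (ddof=1) and center the response."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if column_ids is None:
            column_ids = tuple(f"g{j}" for j in range(X.shape[1]))
        if not standardize:
            return cls(X=X, y=y, column_ids=tuple(column_ids), standardized=False)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [column_ids[j] for j in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant predictor column(s): {bad}")
        Xs = (X - X.mean(axis=0)) / sd
        return cls(X=Xs, y=y - y.mean(), column_ids=tuple(column_ids), standardized=True)


@dataclass
class FitResult:
    """One penalized fit: coefficients plus the penalty that produced it."""

    coefficients: np.ndarray
    lambda1: float
    lambda2: float = 0.0
    delta: float = 1.0
    df_hat: int = 0
    rss: float = 0.0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.df_hat = int(np.count_nonzero(self.coefficients))


@dataclass
class PenaltyGrid:
    """Hyperparameter grid searched by BIC.

    ``lambda1_values=None`` means a data-driven descending log grid of
    ``lambda1_count`` values from the critical lambda_max down to
    ``lambda1_min_ratio * lambda_max``.
    """

    lambda1_values: np.ndarray | None = None
    lambda2_values: tuple[float, ...] = (0.0, 0.01, 0.1, 1.0, 10.0)
    delta_values: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    lambda1_count: int = 50
    lambda1_min_ratio: float = 0.001

    def __post_init__(self) -> None:
        if self.lambda1_values is not None:
            v = np.asarray(self.lambda1_values, dtype=float)
            if v.size == 0 or np.any(~np.isfinite(v)) or np.any(v < 0):
                raise ValueError("lambda1 values must be finite and nonnegative")
            self.lambda1_values = np.sort(v)[::-1]
        if any((not math.isfinite(v)) or v < 0 for v in self.lambda2_values):
            raise ValueError("lambda2 values must be finite and nonnegative")
        if any(not (0.0 <= dv <= 1.0) for dv in self.delta_values):
            raise ValueError("delta values must lie in [0, 1]")

    def lambda1_for(self, d: DesignData, l1_weights: np.ndarray | None = None) -> np.ndarray:
        if self.lambda1_values is not None:
            return self.lambda1_values
        corr = np.abs(d.X.T @ d.y)
        if l1_weights is not None:
            with np.errstate(divide="ignore", invalid="ignore"):
                corr = np.where(np.isfinite(l1_weights), corr / l1_weights, 0.0)
        lam_max = float(np.max(corr, initial=0.0))
        if lam_max == 0.0:
            lam_max = 1.0
        return lambda_grid(lam_max, self.lambda1_count, self.lambda1_min_ratio)


def _check_clean(d: DesignData) -> None:
    if not (np.all(np.isfinite(d.X)) and np.all(np.isfinite(d.y))):
        raise ValueError("NaN or infinite values in design data")


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def _rss(d: DesignData, beta: np.ndarray) -> float:
    r = d.y - d.X @ beta
    return float(r @ r)


def _sklearn_lasso(X, y, lambda1, l1_weights=None, tol=1e-12) -> np.ndarray:
    """Minimize 1/2||y-Xb||^2 + lambda1 sum w_j |b_j| via scikit-learn."""
    n = X.shape[0]
    q = X.shape[1]
    if l1_weights is None:
        l1_weights = np.ones(q)
    keep = np.flatnonzero(np.isfinite(l1_weights))
    beta = np.zeros(q)
    if keep.size == 0:
        return beta
    w = l1_weights[keep]
    # rescale columns so the weighted problem becomes a plain lasso
    scale = np.where(w > 0, 1.0 / w, 1.0)
    Xw = X[:, keep] * scale
    if lambda1 == 0.0:
        beta[keep] = scale * _ols(Xw, y)
        return beta
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = Lasso(
            alpha=lambda1 / n, fit_intercept=False, tol=tol, max_iter=1_000_000
        ).fit(Xw, y)
    beta[keep] = scale * model.coef_
    return beta


def fit_lasso(d: DesignData, lambda1: float) -> FitResult:
    """L1-penalized least squares at a single penalty value."""
    _check_clean(d)
    if lambda1 < 0:
        raise ValueError("lambda1 must be nonnegative")
    beta = _sklearn_lasso(d.X, d.y, lambda1)
    return FitResult(coefficients=beta, lambda1=lambda1, rss=_rss(d, beta))


def fit_adaptive_lasso(
    d: DesignData,
    lambda1: float,
    weight_source: str = "ridge",
    init_coef: np.ndarray | None = None,
) -> FitResult:
    """Weighted lasso with w_j = 1/|b_init,j|.

    The initial estimate is OLS when ``q < n`` or ridge (GCV-tuned)
    otherwise; predictors with a zero initial coefficient receive an
    infinite weight and are excluded.
    """
    _check_clean(d)
    if lambda1 < 0:
        raise ValueError("lambda1 must be nonnegative")
    if init_coef is None:
        if weight_source == "ols":
            if d.q >= d.n:
                raise ValueError("OLS initial weights require q < n; use ridge")
            init_coef = _ols(d.X, d.y)
        elif weight_source == "ridge":
            init_coef = _ridge_gcv(d.X, d.y)[0]
        else:
            raise ValueError(f"unknown weight_source {weight_source!r}")
    init_coef = np.asarray(init_coef, dtype=float)
    with np.errstate(divide="ignore"):
        w = np.where(init_coef != 0.0, 1.0 / np.abs(init_coef), np.inf)
    beta = _sklearn_lasso(d.X, d.y, lambda1, l1_weights=w)
    return FitResult(coefficients=beta, lambda1=lambda1, rss=_rss(d, beta))


def fit_elastic_net(d: DesignData, lambda1: float, delta: float) -> FitResult:
    """Minimize 1/2 RSS + lambda1 * sum{(1-delta)/2 b^2 + delta |b|}."""
    _check_clean(d)
    if lambda1 < 0:
        raise ValueError("lambda1 must be nonnegative")
    if not (0.0 <= delta <= 1.0):
        raise ValueError("delta must lie in [0, 1]")
    if delta == 1.0 or lambda1 == 0.0:
        fit = fit_lasso(d, lambda1)
        return FitResult(
            coefficients=fit.coefficients, lambda1=lambda1, delta=delta, rss=fit.rss
        )
    if delta == 0.0:
        # ridge closed form: (X'X + lambda1 I)^-1 X'y
        q = d.q
        beta = np.linalg.solve(d.X.T @ d.X + lambda1 * np.eye(q), d.X.T @ d.y)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = ElasticNet(
                alpha=lambda1 / d.n,
                l1_ratio=delta,
                fit_intercept=False,
                tol=1e-12,
                max_iter=1_000_000,
            ).fit(d.X, d.y)
        beta = model.coef_
    return FitResult(coefficients=beta, lambda1=lambda1, delta=delta, rss=_rss(d, beta))


def _signed_penalty_matrix(L: np.ndarray, sign_reference: np.ndarray) -> np.ndarray:
    s = np.sign(np.asarray(sign_reference, dtype=float))
    s[s == 0.0] = 1.0
    return (s[:, None] * L) * s[None, :]


def fit_network_lasso(
    d: DesignData,
    lambda1: float,
    lambda2: float,
    L: Laplacian | np.ndarray,
    sign_reference: np.ndarray | None = None,
) -> FitResult:
    """Network-constrained lasso via the augmented-data reformulation.

    Minimizes 1/2 RSS + lambda1 ||b||_1 + lambda2 (Sb)'L(Sb) where S
    flips coordinates to the signs of ``sign_reference`` (zeros treated
    as +1).  The reported ``rss`` covers the real observations only.
    """
    _check_clean(d)
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("penalty weights must be nonnegative")
    Lm = L.matrix if isinstance(L, Laplacian) else np.asarray(L, dtype=float)
    q = d.q
    if Lm.shape != (q, q):
        raise ValueError(f"Laplacian shape {Lm.shape} does not match q={q}")
    if sign_reference is None:
        sign_reference = np.ones(q)
    if np.asarray(sign_reference).shape != (q,):
        raise ValueError("sign_reference length must match q")
    evals = np.linalg.eigvalsh(0.5 * (Lm + Lm.T))
    if evals.min(initial=0.0) < -_PSD_TOL:
        raise ValueError("Laplacian is not positive semidefinite")
    if lambda2 == 0.0 or not np.any(Lm):
        fit = fit_lasso(d, lambda1)
        return FitResult(
            coefficients=fit.coefficients, lambda1=lambda1, lambda2=lambda2, rss=fit.rss
        )
    M = _signed_penalty_matrix(0.5 * (Lm + Lm.T), sign_reference)
    vals, vecs = np.linalg.eigh(M)
    vals = np.clip(vals, 0.0, None)
    root = (vecs * np.sqrt(vals)) @ vecs.T
    X_aug = np.vstack([d.X, math.sqrt(2.0 * lambda2) * root])
    y_aug = np.concatenate([d.y, np.zeros(q)])
    beta = _sklearn_lasso(X_aug, y_aug, lambda1)
    return FitResult(
        coefficients=beta, lambda1=lambda1, lambda2=lambda2, rss=_rss(d, beta)
    )


def bic(fit: FitResult, d: DesignData, sigma2: float) -> float:
    """BIC = RSS / (n sigma^2) + (log n / n) df."""
    if d.n == 0:
        raise ValueError("empty design")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    n = d.n
    return fit.rss / (n * sigma2) + (math.log(n) / n) * fit.df_hat


def _ridge_gcv(X: np.ndarray, y: np.ndarray, n_grid: int = 40):
    """Ridge fit with penalty chosen by generalized cross-validation.

    Returns ``(beta, rss, df_eff)`` at the GCV-optimal penalty, computed
    through the SVD of X.
    """
    n = X.shape[0]
    U, sv, Vt = np.linalg.svd(X, full_matrices=False)
    uy = U.T @ y
    yty = float(y @ y)
    d2 = sv**2
    scale = float(np.mean(d2)) if d2.size else 1.0
    lams = np.geomspace(scale * 1e-4, scale * 1e2, n_grid)
    best = None
    for lam in lams:
        shrink = d2 / (d2 + lam)
        rss = yty - float(((2.0 - shrink) * shrink) @ (uy**2))
        df = float(np.sum(shrink))
        denom = max(n - df, 1e-8)
        gcv = n * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, lam, rss, df)
    _, lam, rss, df = best
    beta = Vt.T @ ((sv / (d2 + lam)) * uy)
    return beta, max(rss, 0.0), df


def _one_se_index(fold_mse: np.ndarray) -> int:
    """Largest penalty whose CV error is within one standard error of the
    minimum (the usual conservative cross-validation rule)."""
    mean = fold_mse.mean(axis=0)
    k = fold_mse.shape[0]
    best = int(np.argmin(mean))
    se = fold_mse[:, best].std(ddof=1) / np.sqrt(k) if k > 1 else 0.0
    for i in range(len(mean)):  # lambdas are descending
        if mean[i] <= mean[best] + se:
            return i
    return best


def _cv_lasso_sigma2(
    X: np.ndarray, y: np.ndarray, k: int = 5, count: int = 30, min_ratio: float = 0.01
) -> float:
    """Degrees-of-freedom-corrected residual variance at the CV-chosen
    lasso penalty (the Reid-Tibshirani-Friedman plug-in with the
    one-standard-error rule): pick lambda by k-fold cross-validated
    prediction error, then return RSS(lambda) / (n - df(lambda)) on the
    full data.  Under a pure-noise
    response this approaches var(y); under strong signal it approaches
    the residual noise scale, which is what the BIC (and the permutation
    null behind the edge test) require.
    """
    n, q = X.shape
    Xy = X.T @ y
    lam_max = float(np.max(np.abs(Xy), initial=0.0))
    if lam_max == 0.0:
        return max(float(y @ y) / max(n - 1, 1), 1e-12)
    lams = lambda_grid(lam_max, count, min_ratio)
    k = min(k, n)
    fold_mse = np.zeros((k, len(lams)))
    idx = np.arange(n)
    for i in range(k):
        va = idx[i::k]
        tr = np.setdiff1d(idx, va)
        Xtr = X[tr]
        coefs = cd_path(Xtr.T @ Xtr, Xtr.T @ y[tr], lams, tol=1e-5, df_cap=tr.shape[0])
        R = y[va][:, None] - X[va] @ coefs
        fold_mse[i] = np.mean(R * R, axis=0)
    li = _one_se_index(fold_mse)
    G = X.T @ X
    beta = cd_path(G, Xy, lams[: li + 1], tol=1e-6)[:, li]
    df = int(np.count_nonzero(beta))
    rss = float(y @ y) - 2.0 * float(Xy @ beta) + float(beta @ (G @ beta))
    return max(max(rss, 0.0) / max(n - df, 1), 1e-12)


def estimate_sigma2(d: DesignData, method: str = "auto", value: float | None = None) -> float:
    """Plug-in noise variance for the BIC, estimated once per dataset.

    ``q < n``: OLS residual variance RSS/(n-q).  ``q >= n``: the
    cross-validated-lasso plug-in RSS(lambda_CV)/(n - df) (Reid-style),
    since residual-based estimates degenerate toward zero when the
    design can interpolate.  ``method`` may force ``"ols"``,
    ``"cv-lasso"`` or ``"ridge-gcv"``; an explicit ``value`` overrides
    estimation.
    """
    if value is not None:
        if value <= 0:
            raise ValueError("sigma2 override must be positive")
        return float(value)
    n, q = d.n, d.q
    if method == "ols" or (method == "auto" and q < n):
        if q >= n:
            raise ValueError("OLS variance estimate requires q < n")
        beta = _ols(d.X, d.y)
        rss = _rss(d, beta)
        return max(rss / max(n - q, 1), 1e-12)
    if method == "ridge-gcv":
        _, rss, df = _ridge_gcv(d.X, d.y)
        return max(rss / max(n - df, 1.0), 1e-12)
    return _cv_lasso_sigma2(d.X, d.y)


_FITTERS = {"lasso", "adaptive-lasso", "elastic-net", "network-lasso"}


def select_by_bic(
    d: DesignData,
    grid: PenaltyGrid,
    method: str = "lasso",
    sigma2: float | None = None,
    L: Laplacian | np.ndarray | None = None,
    sign_reference: np.ndarray | None = None,
    weight_source: str = "ridge",
    init_coef: np.ndarray | None = None,
) -> FitResult:
    """Exhaustive BIC grid search over the penalty combinations.

    Ties are broken toward larger lambda1, then larger lambda2 (the
    sparser, smoother model).
    """
    if method not in _FITTERS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_FITTERS)}")
    if sigma2 is None:
        sigma2 = estimate_sigma2(d)
    lam1s = grid.lambda1_for(d)
    if method == "lasso":
        combos = [dict(lambda1=l1) for l1 in lam1s]
        fitter = lambda d, lambda1: fit_lasso(d, lambda1)
    elif method == "adaptive-lasso":
        if init_coef is None:
            if weight_source == "ols" and d.q < d.n:
                init_coef = _ols(d.X, d.y)
            else:
                init_coef = _ridge_gcv(d.X, d.y)[0]
        combos = [dict(lambda1=l1) for l1 in lam1s]
        fitter = lambda d, lambda1: fit_adaptive_lasso(d, lambda1, init_coef=init_coef)
    elif method == "elastic-net":
        combos = [
            dict(lambda1=l1, delta=dv) for l1 in lam1s for dv in grid.delta_values
        ]
        fitter = lambda d, lambda1, delta: fit_elastic_net(d, lambda1, delta)
    else:
        if L is None:
            raise ValueError("network-lasso requires a Laplacian")
        combos = [
            dict(lambda1=l1, lambda2=l2) for l1 in lam1s for l2 in grid.lambda2_values
        ]
        fitter = lambda d, lambda1, lambda2: fit_network_lasso(
            d, lambda1, lambda2, L, sign_reference
        )
    if not combos:
        raise ValueError("empty penalty grid")
    best: tuple[float, float, float, FitResult] | None = None
    failures: list[str] = []
    for combo in combos:
        try:
            fit = fitter(d, **combo)
        except Exception as exc:  # noqa: BLE001 - collected and reported
            failures.append(f"{combo}: {exc}")
            continue
        score = bic(fit, d, sigma2)
        key = (score, -fit.lambda1, -fit.lambda2)
        if best is None or key < (best[0], -best[3].lambda1, -best[3].lambda2):
            best = (score, fit.lambda1, fit.lambda2, fit)
    if best is None:
        raise RuntimeError("all grid fits failed: " + "; ".join(failures))
    return best[3]
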