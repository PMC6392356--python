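"""Fast maximum-likelihood fitting of Gaussian linear mixed models with
random intercepts.

The model is

    y = X beta + sum_k Z_k b_k + e,     b_k ~ N(0, s2_k I),  e ~ N(0, s2 I)

with each ``Z_k`` the indicator matrix of a grouping factor (taxonomic
levels, ocean basin, spatial structure...).  Fits use full ML (never REML)
so that log-likelihoods and AICc are comparable across fixed-effect
structures during all-subsets model selection.

Writing ``theta_k = s2_k / s2`` and ``W = I + sum_k theta_k Z_k Z_k'``, the
profiled deviance depends only on theta: beta and s2 have closed-form GLS
solutions given theta.  All n-dimensional algebra is reduced once to
cross-products (Z'Z, Z'X, Z'y, X'X, X'y, y'y); each likelihood evaluation
then costs O(q^3) in q = total number of random-effect levels via the
Woodbury identity, which makes thousands of refits (all-subsets selection
inside resampling loops) affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = ["MixedLMResult", "fit_ml", "RandomFactor", "CrossProducts"]

_LOG_THETA_BOUNDS = (-15.0, 8.0)


@dataclass
class RandomFactor:
    """A random-intercept grouping factor: integer level codes per row."""

    name: str
    codes: np.ndarray  # shape (n,), values 0..n_levels-1
    n_levels: int


@dataclass
class MixedLMResult:
    """Result of a single ML mixed-model fit."""

    params: np.ndarray          # fixed-effect estimates
    bse: np.ndarray             # fixed-effect standard errors
    names: list[str]            # fixed-effect column names
    sigma2: float               # residual variance (ML)
    vc: dict[str, float]        # variance component per random factor
    theta: np.ndarray           # variance ratios s2_k / s2 at the optimum
    loglik: float
    nobs: int
    n_fixed: int
    n_vc: int
    converged: bool

    @property
    def k_params(self) -> int:
        """Parameter count for information criteria: fixed effects +
        variance components + residual variance."""
        return self.n_fixed + self.n_vc + 1

    @property
    def aicc(self) -> float:
        k, n = self.k_params, self.nobs
        if n - k - 1 <= 0:
            return np.inf
        return -2.0 * self.loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k_params


class CrossProducts:
    """Precomputed cross-products shared by every submodel fit on one dataset.

    X_full holds the union of all candidate fixed-effect columns; submodels
    select column subsets, so Z'X etc. are sliced rather than recomputed.
    """

    def __init__(self, y: np.ndarray, X_full: np.ndarray, factors: list[RandomFactor]):
        y = np.asarray(y, dtype=float)
        X_full = np.asarray(X_full, dtype=float)
        n = y.shape[0]
        if X_full.shape[0] != n:
            raise ValueError("X and y have different lengths")
        self.n = n
        self.factors = factors
        # block sizes per factor in the concatenated Z
        self.block = []
        cols = []
        for f in factors:
            if f.codes.shape[0] != n:
                raise ValueError(f"random factor {f.name!r} has wrong length")
            Z = np.zeros((n, f.n_levels))
            Z[np.arange(n), f.codes] = 1.0
            cols.append(Z)
            self.block.append(f.n_levels)
        if cols:
            Z = np.concatenate(cols, axis=1)
        else:
            Z = np.zeros((n, 0))
        self.q = Z.shape[1]
        self.A = Z.T @ Z                 # q x q
        self.B_full = Z.T @ X_full       # q x P
        self.c = Z.T @ y                 # q
        self.G_full = X_full.T @ X_full  # P x P
        self.h_full = X_full.T @ y       # P
        self.yy = float(y @ y)

    def subset(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        B = self.B_full[:, idx]
        G = self.G_full[np.ix_(idx, idx)]
        h = self.h_full[idx]
        return B, G, h


def _expand_theta(theta: np.ndarray, block: list[int]) -> np.ndarray:
    """Per-factor theta -> per-Z-column theta."""
    return np.repeat(theta, block)


def _profiled_nll(log_theta, cp: CrossProducts, B, G, h, want_fit=False):
    """Negative profiled log-likelihood at variance ratios exp(log_theta).

    With s = sqrt(theta) per Z column and M = I + S A S (S = diag(s)),
    W^{-1} = I - Z S M^{-1} S Z'  and  log|W| = log|M|.
    """
    n = cp.n
    theta = np.exp(np.asarray(log_theta, dtype=float))
    s = np.sqrt(_expand_theta(theta, cp.block))
    q = cp.q
    if q:
        M = s[:, None] * cp.A * s[None, :]
        M[np.diag_indices_from(M)] += 1.0
        try:
            L = linalg.cholesky(M, lower=True)
        except linalg.LinAlgError:
            return (np.inf, None) if want_fit else np.inf
        Bs = s[:, None] * B
        cs = s * cp.c
        U = linalg.solve_triangular(L, np.column_stack([Bs, cs]), lower=True)
        UB, uc = U[:, :-1], U[:, -1]
        XWX = G - UB.T @ UB
        XWy = h - UB.T @ uc
        yWy = cp.yy - float(uc @ uc)
        logdet = 2.0 * float(np.log(np.diag(L)).sum())
    else:
        XWX, XWy, yWy, logdet = G, h, cp.yy, 0.0
    try:
        cf = linalg.cho_factor(XWX)
    except linalg.LinAlgError:
        raise np.linalg.LinAlgError("fixed-effect design is singular")
    beta = linalg.cho_solve(cf, XWy)
    rss = yWy - float(beta @ XWy)
    rss = max(rss, 1e-300)
    sigma2 = rss / n
    nll = 0.5 * (n * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet)
    if not want_fit:
        return nll
    cov = linalg.cho_solve(cf, np.eye(len(beta))) * sigma2
    return nll, (beta, cov, sigma2)


def fit_ml(
    y: np.ndarray,
    X: np.ndarray,
    factors: list[RandomFactor],
    names: list[str] | None = None,
    theta0: np.ndarray | None = None,
    cross_products: CrossProducts | None = None,
    col_idx: np.ndarray | None = None,
) -> MixedLMResult:
    """Fit the random-intercept LMM by full ML.

    Parameters
    ----------
    y, X
        Response and fixed-effect design (X should include the intercept).
    factors
        Random-intercept grouping factors; may be empty (model reduces to
        OLS, and the fit is then exact and non-iterative).
    theta0
        Optional warm-start variance ratios (e.g. from a wider model).
    cross_products, col_idx
        Fast path for all-subsets selection: reuse precomputed
        cross-products, taking fixed-effect columns ``col_idx`` of the
        full design the cross-products were built from.
    """
    if cross_products is None:
        cross_products = CrossProducts(np.asarray(y, float), np.asarray(X, float), factors)
        col_idx = np.arange(cross_products.B_full.shape[1])
    cp = cross_products
    if col_idx is None:
        col_idx = np.arange(cp.B_full.shape[1])
    col_idx = np.asarray(col_idx)
    B, G, h = cp.subset(col_idx)
    K = len(cp.factors)
    if names is None:
        names = [f"x{j}" for j in col_idx]

    if K == 0:
        nll, (beta, cov, sigma2) = _profiled_nll(np.empty(0), cp, B, G, h, want_fit=True)
        return MixedLMResult(
            params=beta, bse=np.sqrt(np.diag(cov)), names=list(names),
            sigma2=sigma2, vc={}, theta=np.empty(0), loglik=-nll,
            nobs=cp.n, n_fixed=len(beta), n_vc=0, converged=True,
        )

    x0 = np.log(theta0) if theta0 is not None else np.full(K, np.log(0.1))
    x0 = np.clip(x0, *_LOG_THETA_BOUNDS)
    opts = {"maxfun": 400, "ftol": 1e-11, "gtol": 1e-7}
    res = optimize.minimize(
        _profiled_nll, x0, args=(cp, B, G, h),
        method="L-BFGS-B", bounds=[_LOG_THETA_BOUNDS] * K, options=opts,
    )
    converged = bool(res.success)
    if not converged:
        # a warm start sitting on the optimum makes the first line search
        # "fail"; confirm (or improve) from a neutral cold start
        cold = np.full(K, np.log(0.1))
        res2 = optimize.minimize(
            _profiled_nll, cold, args=(cp, B, G, h),
            method="L-BFGS-B", bounds=[_LOG_THETA_BOUNDS] * K, options=opts,
        )
        agree = abs(res.fun - res2.fun) <= 1e-6 * max(1.0, abs(min(res.fun, res2.fun)))
        if res2.fun < res.fun:
            res = res2
        converged = bool(res2.success) and (agree or res is res2)
    if not np.isfinite(res.fun):
        converged = False
    nll, fit = _profiled_nll(res.x, cp, B, G, h, want_fit=True)
    if fit is None:
        raise np.linalg.LinAlgError("mixed-model covariance factorization failed")
    beta, cov, sigma2 = fit
    theta = np.exp(res.x)
    # ratios driven to the lower bound are numerically zero variance
    theta = np.where(theta <= np.exp(_LOG_THETA_BOUNDS[0]) * 1.01, 0.0, theta)
    vc = {f.name: float(t * sigma2) for f, t in zip(cp.factors, theta)}
    return MixedLMResult(
        params=beta, bse=np.sqrt(np.diag(cov)), names=list(names),
        sigma2=sigma2, vc=vc, theta=theta, loglik=-nll,
        nobs=cp.n, n_fixed=len(beta), n_vc=K, converged=converged,
    )
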