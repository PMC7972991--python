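"""Restricted maximum likelihood (REML) engine for single-kernel mixed models.

Fits models of the form ``y = X beta + g + e`` with ``g ~ N(0, sigma_g^2 K)``
and ``e ~ N(0, sigma_e^2 I)``, where K is a symmetric positive semi-definite
kernel: a genomic relationship matrix over individuals (GREML heritability) or
a gene-gene correlation matrix of predicted expression (competitive gene-set
enrichment).  A bivariate extension estimates the genetic covariance between
two traits sharing the same kernel, from which the genetic correlation rho_g
is obtained.

The univariate fit exploits the eigendecomposition ``K = U S U'``: rotating y
and X by U' diagonalizes the covariance, so the REML criterion can be profiled
over the single variance ratio ``delta = sigma_e^2 / sigma_g^2`` and
maximized by bounded scalar minimization on ``log delta``.  The bivariate fit
optimizes the full REML likelihood over Cholesky-parameterized 2x2 genetic
and environmental covariance matrices, again in the rotated basis where
observations decouple into independent 2-vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "LmmFit",
    "BivariateFit",
    "reml_fit",
    "wald_one_sided",
    "nearest_pd",
    "bivariate_reml",
    "kernel_eig",
]

# Search bounds for log(delta); an optimum at an edge is a boundary fit
# (sigma_g^2 -> 0 at the upper edge, sigma_e^2 -> 0 at the lower edge).
_LOG_DELTA_BOUNDS = (-10.0, 10.0)
_LOG_DELTA_TOL = 1e-8
_BOUNDARY_MARGIN = 1e-3

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class LmmFit:
    """Result of a univariate REML fit.

    ``beta``/``beta_se`` are generalized-least-squares fixed effects and
    standard errors; ``sigma_g2``/``sigma_e2`` are the variance components in
    squared units of the dependent variable.  ``boundary`` marks an optimum at
    the edge of the variance-ratio search interval, where only the sum of the
    components is effectively identified.
    """

    beta: np.ndarray
    beta_se: np.ndarray
    sigma_g2: float
    sigma_e2: float
    loglik_reml: float
    converged: bool
    boundary: bool
    n: int
    vc_cov: np.ndarray | None = None  # 2x2 covariance of (sigma_g2, sigma_e2)
    beta_cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


@dataclass
class BivariateFit:
    """Bivariate REML result: per-trait variance components, the genetic and
    environmental covariances, and the derived correlations with SEs."""

    sigma_g2: tuple[float, float]
    sigma_e2: tuple[float, float]
    sigma_g12: float
    sigma_e12: float
    rho_g: float
    rho_e: float
    rho_g_se: float
    h2: tuple[float, float]
    loglik_reml: float
    converged: bool
    boundary: bool
    n: int


def kernel_eig(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a symmetric kernel with negatives clipped to 0.

    Precompute once when fitting many models against the same kernel.
    """
    s, U = np.linalg.eigh(np.asarray(K, dtype=float))
    return np.clip(s, 0.0, None), U


def _as_kernel_values(K) -> np.ndarray:
    # accept bare arrays or KernelMatrix-like objects with .values
    vals = getattr(K, "values", K)
    return np.asarray(vals, dtype=float)


def _profile(log_delta, s, yr, Xr, n, p):
    """Profiled REML criterion at a fixed variance ratio delta = se2/sg2.

    Returns (-2 loglik without constants, beta, sigma_g2, XtWX).
    """
    delta = np.exp(log_delta)
    w = 1.0 / (s + delta)
    Xw = Xr * w[:, None]
    XtWX = Xr.T @ Xw
    XtWy = Xw.T @ yr
    beta = np.linalg.solve(XtWX, XtWy)
    r = yr - Xr @ beta
    rss = float(np.sum(w * r * r))
    sg2 = rss / (n - p)
    sign, logdet_xtwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'WX not positive definite")
    neg2ll = (
        (n - p) * np.log(sg2)
        + float(np.sum(np.log(s + delta)))
        + logdet_xtwx
        + (n - p)
    )
    return neg2ll, beta, sg2, XtWX


def _reml_loglik(sg2, se2, s, yr, Xr, n, p):
    """Unprofiled REML log-likelihood at given variance components."""
    d = sg2 * s + se2
    if np.any(d <= 0):
        return -np.inf
    w = 1.0 / d
    Xw = Xr * w[:, None]
    XtWX = Xr.T @ Xw
    sign, logdet_xtwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtWX, Xw.T @ yr)
    r = yr - Xr @ beta
    quad = float(np.sum(w * r * r))
    return -0.5 * (
        float(np.sum(np.log(d))) + logdet_xtwx + quad + (n - p) * _LOG_2PI
    )


def _vc_covariance(sg2, se2, s, yr, Xr, n, p):
    """Covariance of (sigma_g2, sigma_e2) from the numerically estimated
    observed information (negative Hessian of the REML log-likelihood)."""

    def f(theta):
        return _reml_loglik(theta[0], theta[1], s, yr, Xr, n, p)

    theta0 = np.array([sg2, se2])
    h = np.maximum(1e-5, 1e-3 * np.abs(theta0))
    H = np.empty((2, 2))
    for i in range(2):
        for j in range(i, 2):
            ei = np.zeros(2)
            ej = np.zeros(2)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(theta0 + ei + ej)
            fpm = f(theta0 + ei - ej)
            fmp = f(theta0 - ei + ej)
            fmm = f(theta0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    if not np.all(np.isfinite(H)):
        return None
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return None
    if np.any(np.diag(cov) < 0):
        return None
    return cov


def reml_fit(
    y,
    X,
    K,
    *,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    compute_vc_cov: bool = False,
) -> LmmFit:
    """REML fit of ``y = X beta + g + e`` with ``g ~ N(0, sigma_g2 K)``.

    Parameters
    ----------
    y : (n,) response.
    X : (n, p) fixed-effect design, full column rank (include the intercept).
    K : (n, n) symmetric PSD kernel, or an object exposing ``.values``.
    eig : optional precomputed ``kernel_eig(K)``, reused across many fits
        against the same kernel.
    compute_vc_cov : also estimate the covariance of the variance components
        (needed for heritability standard errors).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("y and X have incompatible shapes")
    n, p = X.shape
    if n <= p:
        raise ValueError("more fixed effects than observations")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design X is rank deficient")
    if eig is None:
        Kv = _as_kernel_values(K)
        if Kv.shape != (n, n):
            raise ValueError("kernel dimension does not match data")
        if not np.allclose(Kv, Kv.T, atol=1e-8):
            raise ValueError("kernel is not symmetric")
        s, U = kernel_eig(Kv)
        if np.min(np.linalg.eigvalsh(Kv)) < -1e-6:
            raise ValueError("kernel is not PSD; regularize with nearest_pd")
    else:
        s, U = eig
    yr = U.T @ y
    Xr = U.T @ X

    res = optimize.minimize_scalar(
        lambda t: _profile(t, s, yr, Xr, n, p)[0],
        bounds=_LOG_DELTA_BOUNDS,
        method="bounded",
        options={"xatol": _LOG_DELTA_TOL, "maxiter": 200},
    )
    converged = bool(res.success)
    log_delta = float(res.x)
    boundary = (
        log_delta <= _LOG_DELTA_BOUNDS[0] + _BOUNDARY_MARGIN
        or log_delta >= _LOG_DELTA_BOUNDS[1] - _BOUNDARY_MARGIN
    )
    if not boundary:
        # a profile this flat out to an edge means the variance ratio is not
        # identified (e.g. K proportional to I): flag it as a boundary fit
        opt_val = float(res.fun)
        for edge in _LOG_DELTA_BOUNDS:
            if abs(_profile(edge, s, yr, Xr, n, p)[0] - opt_val) < 1e-6:
                boundary = True
                break
    if not converged:
        warnings.warn("REML scalar optimization did not converge", RuntimeWarning)
    _, beta, sg2, XtWX = _profile(log_delta, s, yr, Xr, n, p)
    delta = np.exp(log_delta)
    se2 = sg2 * delta
    beta_cov = sg2 * np.linalg.inv(XtWX)
    beta_se = np.sqrt(np.diag(beta_cov))
    loglik = _reml_loglik(sg2, se2, s, yr, Xr, n, p)
    vc_cov = None
    if compute_vc_cov:
        vc_cov = _vc_covariance(sg2, se2, s, yr, Xr, n, p)
    return LmmFit(
        beta=beta,
        beta_se=beta_se,
        sigma_g2=float(sg2),
        sigma_e2=float(se2),
        loglik_reml=float(loglik),
        converged=converged,
        boundary=boundary,
        n=n,
        vc_cov=vc_cov,
        beta_cov=beta_cov,
    )


def wald_one_sided(fit: LmmFit, coefficient: int, *, two_sided: bool = False):
    """Wald test for one fixed-effect coefficient.

    Returns ``(t, p)`` with ``t = beta/SE`` and, by default, the one-sided
    upper-tail p-value under the normal approximation; ``two_sided=True``
    doubles the tail of ``|t|``.
    """
    se = float(fit.beta_se[coefficient])
    if se == 0 or not np.isfinite(se):
        raise ValueError("coefficient has zero or undefined standard error")
    t = float(fit.beta[coefficient]) / se
    if two_sided:
        p = 2.0 * stats.norm.sf(abs(t))
    else:
        p = stats.norm.sf(t)
    return t, float(p)


def nearest_pd(M: np.ndarray, epsilon: float = 1e-6, *, unit_diagonal: bool = False):
    """Project a symmetric matrix to the PD cone by eigenvalue clipping.

    Eigenvalues below ``epsilon`` are raised to ``epsilon`` and the matrix is
    rebuilt; for correlation-kind kernels ``unit_diagonal=True`` restores a
    unit diagonal afterwards.  Idempotent, and the identity on PD input.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("nearest_pd requires a square matrix")
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("nearest_pd requires a symmetric matrix")
    s, U = np.linalg.eigh(M)
    if s[0] >= epsilon:
        out = M.copy()
    else:
        out = (U * np.clip(s, epsilon, None)) @ U.T
        out = 0.5 * (out + out.T)
    if unit_diagonal:
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        np.fill_diagonal(out, 1.0)
    return out


# ---------------------------------------------------------------------------
# Bivariate REML
# ---------------------------------------------------------------------------


def _chol_from_params(a, b, c):
    # lower-triangular with positive diagonal via exp
    return np.array([[np.exp(a), 0.0], [b, np.exp(c)]])


def _bivariate_neg2ll_natural(G, E, s, y1r, y2r, X1r, X2r):
    """-2 REML loglik (with constant) at natural covariance matrices G, E.

    After rotation, each eigen-index i contributes an independent 2-vector
    with covariance C_i = s_i G + E.
    """
    n = s.size
    p1 = X1r.shape[1]
    p2 = X2r.shape[1]
    p = p1 + p2
    c11 = s * G[0, 0] + E[0, 0]
    c12 = s * G[0, 1] + E[0, 1]
    c22 = s * G[1, 1] + E[1, 1]
    det = c11 * c22 - c12 * c12
    if np.any(det <= 0) or np.any(c11 <= 0):
        return np.inf, None
    i11 = c22 / det
    i12 = -c12 / det
    i22 = c11 / det
    # accumulate X' V^-1 X (block form), X' V^-1 y
    A11 = X1r.T @ (X1r * i11[:, None])
    A12 = X1r.T @ (X2r * i12[:, None])
    A22 = X2r.T @ (X2r * i22[:, None])
    A = np.block([[A11, A12], [A12.T, A22]])
    b1 = X1r.T @ (i11 * y1r + i12 * y2r)
    b2 = X2r.T @ (i12 * y1r + i22 * y2r)
    b = np.concatenate([b1, b2])
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf, None
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.inf, None
    r1 = y1r - X1r @ beta[:p1]
    r2 = y2r - X2r @ beta[p1:]
    quad = float(np.sum(i11 * r1 * r1 + 2 * i12 * r1 * r2 + i22 * r2 * r2))
    neg2ll = float(np.sum(np.log(det))) + logdetA + quad + (2 * n - p) * _LOG_2PI
    return neg2ll, beta


def bivariate_reml(
    y1,
    y2,
    X1,
    X2,
    K,
    *,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    n_max: int = 1000,
    maxiter: int = 4000,
) -> BivariateFit:
    """Bivariate REML on two traits measured on the same individuals.

    Maximizes the REML criterion over the 2x2 genetic and environmental
    covariance matrices (Cholesky-parameterized, hence positive definite by
    construction) with a derivative-free simplex search, then derives
    ``rho_g = sigma_g12 / sqrt(sigma_g1^2 sigma_g2^2)`` and its SE from a
    numerically estimated information matrix.  Designed for desk-scale n
    (default cap 1000): each likelihood evaluation is O(n) after one
    eigendecomposition of the kernel.
    """
    y1 = np.asarray(y1, dtype=float).ravel()
    y2 = np.asarray(y2, dtype=float).ravel()
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    n = y1.size
    if y2.size != n:
        raise ValueError("traits must be measured on the same individuals")
    if n > n_max:
        raise ValueError(f"n={n} exceeds the desk-scale cap n_max={n_max}")
    if eig is None:
        Kv = _as_kernel_values(K)
        s, U = kernel_eig(Kv)
    else:
        s, U = eig
    y1r = U.T @ y1
    y2r = U.T @ y2
    X1r = U.T @ X1
    X2r = U.T @ X2

    # starts from univariate fits; cross-covariances from phenotypic correlation
    f1 = reml_fit(y1, X1, None, eig=(s, U))
    f2 = reml_fit(y2, X2, None, eig=(s, U))
    sg1 = max(f1.sigma_g2, 1e-3 * np.var(y1))
    sg2_ = max(f2.sigma_g2, 1e-3 * np.var(y2))
    se1 = max(f1.sigma_e2, 1e-3 * np.var(y1))
    se2_ = max(f2.sigma_e2, 1e-3 * np.var(y2))
    r_ph = float(np.corrcoef(y1, y2)[0, 1]) if n > 2 else 0.0
    r0 = np.clip(r_ph, -0.5, 0.5)

    def pack(G, E):
        Lg = np.linalg.cholesky(G)
        Le = np.linalg.cholesky(E)
        return np.array(
            [np.log(Lg[0, 0]), Lg[1, 0], np.log(Lg[1, 1]),
             np.log(Le[0, 0]), Le[1, 0], np.log(Le[1, 1])]
        )

    G0 = np.array([[sg1, r0 * np.sqrt(sg1 * sg2_)], [r0 * np.sqrt(sg1 * sg2_), sg2_]])
    E0 = np.array([[se1, r0 * np.sqrt(se1 * se2_)], [r0 * np.sqrt(se1 * se2_), se2_]])
    # nudge away from exact singularity for the Cholesky start
    G0 += 1e-6 * np.eye(2) * np.trace(G0)
    E0 += 1e-6 * np.eye(2) * np.trace(E0)

    def unpack(theta):
        Lg = _chol_from_params(theta[0], theta[1], theta[2])
        Le = _chol_from_params(theta[3], theta[4], theta[5])
        return Lg @ Lg.T, Le @ Le.T

    def objective(theta):
        G, E = unpack(theta)
        val, _ = _bivariate_neg2ll_natural(G, E, s, y1r, y2r, X1r, X2r)
        return val

    res = optimize.minimize(
        objective,
        pack(G0, E0),
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-7, "fatol": 1e-9},
    )
    converged = bool(res.success) and np.isfinite(res.fun)
    G, E = unpack(res.x)
    neg2ll, _ = _bivariate_neg2ll_natural(G, E, s, y1r, y2r, X1r, X2r)

    sg12 = G[0, 1]
    se12 = E[0, 1]
    denom_g = np.sqrt(G[0, 0] * G[1, 1])
    denom_e = np.sqrt(E[0, 0] * E[1, 1])
    rho_g = sg12 / denom_g if denom_g > 0 else np.nan
    rho_e = se12 / denom_e if denom_e > 0 else np.nan
    boundary = bool(abs(rho_g) > 0.995) if np.isfinite(rho_g) else True

    rho_g_se = _rho_g_se(G, E, s, y1r, y2r, X1r, X2r)
    h2_1 = G[0, 0] / (G[0, 0] + E[0, 0])
    h2_2 = G[1, 1] / (G[1, 1] + E[1, 1])
    if not converged:
        warnings.warn("bivariate REML optimizer did not converge", RuntimeWarning)
    return BivariateFit(
        sigma_g2=(float(G[0, 0]), float(G[1, 1])),
        sigma_e2=(float(E[0, 0]), float(E[1, 1])),
        sigma_g12=float(sg12),
        sigma_e12=float(se12),
        rho_g=float(rho_g),
        rho_e=float(rho_e),
        rho_g_se=float(rho_g_se),
        h2=(float(h2_1), float(h2_2)),
        loglik_reml=float(-0.5 * neg2ll),
        converged=converged,
        boundary=boundary,
        n=n,
    )


def _rho_g_se(G, E, s, y1r, y2r, X1r, X2r):
    """Delta-method SE of rho_g from a numeric information matrix over the
    six natural parameters (sg1, sg12, sg2, se1, se12, se2)."""

    def ll(theta):
        Gm = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
        Em = np.array([[theta[3], theta[4]], [theta[4], theta[5]]])
        val, _ = _bivariate_neg2ll_natural(Gm, Em, s, y1r, y2r, X1r, X2r)
        return -0.5 * val

    theta0 = np.array([G[0, 0], G[0, 1], G[1, 1], E[0, 0], E[0, 1], E[1, 1]])
    scale = max(np.abs(theta0).max(), 1e-3)
    h = np.maximum(1e-5 * scale, 1e-3 * np.abs(theta0))
    k = theta0.size
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = ll(theta0 + ei + ej)
            fpm = ll(theta0 + ei - ej)
            fmp = ll(theta0 - ei + ej)
            fmm = ll(theta0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    if not np.all(np.isfinite(H)):
        return np.nan
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return np.nan
    sg1, sg12, sg2 = theta0[0], theta0[1], theta0[2]
    denom = np.sqrt(sg1 * sg2)
    if denom <= 0:
        return np.nan
    grad = np.zeros(k)
    grad[0] = -0.5 * sg12 / (denom * sg1)
    grad[1] = 1.0 / denom
    grad[2] = -0.5 * sg12 / (denom * sg2)
    var = float(grad @ cov @ grad)
    return np.sqrt(var) if var > 0 else np.nan
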