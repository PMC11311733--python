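"""Profiled-REML solver for Gaussian variance-components models.

Fits models of the form

    y = X beta + sum_f Z_f b_f + eps,   b_f ~ N(0, sigma_f^2 I),  eps ~ N(0, sigma^2 I)

where each ``Z_f`` is the one-hot indicator matrix of a categorical factor
(plate, nanoparticle, plate x nanoparticle, subject, ...).  The relative
variances gamma_f = sigma_f^2 / sigma^2 are profiled: for fixed gamma the GLS
estimate of beta and the residual variance have closed forms, so only the
gamma vector is optimised numerically.

All REML quantities are evaluated in random-effect space via the Woodbury
identity, and the factor with the most levels is absorbed analytically (its
indicator columns are orthogonal, so the corresponding block inverse is
diagonal).  This keeps the per-evaluation cost at O(q^3) with q the number of
*remaining* random-effect columns, independent of the number of observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = ["VCFit", "fit_variance_components", "random_intercept_blups"]

# log-scale bounds on the relative variances; gamma below exp(-12) is a
# boundary (zero-variance) fit for any practical data scale
_THETA_BOUNDS = (-12.0, 8.0)


@dataclass
class VCFit:
    """Result of a variance-components REML fit."""

    beta: np.ndarray
    se: np.ndarray
    sigma2: float
    vcomp: dict[str, float]
    n_obs: int
    converged: bool
    loglike_m2: float
    fixed_names: list[str] = field(default_factory=list)

    def wald_p(self, idx: int) -> float:
        """Two-sided Wald p-value (normal reference) for coefficient ``idx``."""
        if self.se[idx] == 0:
            return 0.0 if self.beta[idx] != 0 else 1.0
        z = self.beta[idx] / self.se[idx]
        return float(2.0 * norm.sf(abs(z)))


def _one_hot_codes(values: np.ndarray) -> tuple[np.ndarray, int]:
    _, codes = np.unique(values, return_inverse=True)
    return codes.astype(np.intp), int(codes.max()) + 1


def fit_variance_components(
    y: np.ndarray,
    X: np.ndarray,
    factors: dict[str, np.ndarray],
    fixed_names: list[str] | None = None,
) -> VCFit:
    """REML fit of a crossed variance-components model.

    Parameters
    ----------
    y : observation vector, length n.
    X : fixed-effects design matrix, n x p (include the intercept column).
    factors : mapping factor name -> length-n array of level labels (any
        hashable dtype); each factor contributes an independent variance
        component.  Factors with a single level are dropped (their effect is
        confounded with the intercept).
    fixed_names : optional names for the columns of ``X``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p_full = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X have incompatible shapes")

    # drop linearly dependent fixed-effect columns (pivoted QR); their
    # coefficients are reported as 0 with infinite standard error
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > max(n, p_full) * np.finfo(float).eps * (diag.max() or 1.0)).sum())
    keep_cols = np.sort(piv[:rank])
    dropped_cols = np.setdiff1d(np.arange(p_full), keep_cols)
    X = X[:, keep_cols]
    p = X.shape[1]

    def _expand(fit: "VCFit") -> "VCFit":
        if not len(dropped_cols):
            return fit
        beta = np.zeros(p_full)
        se = np.full(p_full, np.inf)
        beta[keep_cols] = fit.beta
        se[keep_cols] = fit.se
        fit.beta, fit.se = beta, se
        return fit

    coded: dict[str, tuple[np.ndarray, int]] = {}
    for name, vals in factors.items():
        codes, k = _one_hot_codes(np.asarray(vals))
        if k >= 2:
            coded[name] = (codes, k)

    names = list(coded)
    if not names:
        # pure OLS fallback
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = max(n - p, 1)
        s2 = float(resid @ resid / dof)
        cov = s2 * np.linalg.pinv(X.T @ X)
        return _expand(VCFit(beta, np.sqrt(np.diag(cov)), s2, {}, n, True,
                             float(dof * np.log(s2)), fixed_names or []))

    # absorb the factor with the most levels: its one-hot columns are
    # orthogonal, so (I + gamma_a Z_a Z_a')^{-1} is closed-form
    absorb = max(names, key=lambda f: coded[f][1])
    rest = [f for f in names if f != absorb]
    a_codes, qa = coded[absorb]
    nk = np.bincount(a_codes, minlength=qa).astype(float)

    U = np.zeros((qa, p))
    np.add.at(U, a_codes, X)
    uy = np.bincount(a_codes, weights=y, minlength=qa)

    sizes = [coded[f][1] for f in rest]
    offs = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
    qr = int(offs[-1])
    if qr:
        Zr = np.zeros((n, qr))
        for f, o in zip(rest, offs[:-1]):
            Zr[np.arange(n), coded[f][0] + o] = 1.0
        G = Zr.T @ Zr
        H = np.zeros((qr, qa))
        for f, o in zip(rest, offs[:-1]):
            np.add.at(H, (coded[f][0] + o, a_codes), 1.0)
        J = Zr.T @ X
        jy = Zr.T @ y
        colfac = np.repeat(np.arange(len(rest)), sizes)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    order = [absorb] + rest

    def _quantities(theta: np.ndarray):
        g = np.exp(theta)
        ga = g[0]
        c = ga / (1.0 + ga * nk)
        XVX = XtX - (U.T * c) @ U
        XVy = Xty - (U.T * c) @ uy
        yVy = yty - float(uy @ (c * uy))
        logdet0 = float(np.log1p(ga * nk).sum())
        if qr:
            s = np.sqrt(g[1:][colfac])
            Gt = G - (H * c) @ H.T
            A = np.eye(qr) + (s[:, None] * Gt) * s[None, :]
            L = np.linalg.cholesky(A)
            T = sla.solve_triangular(L, s[:, None] * (J - (H * c) @ U), lower=True)
            ty = sla.solve_triangular(L, s * (jy - (H * c) @ uy), lower=True)
            XWX = XVX - T.T @ T
            XWy = XVy - T.T @ ty
            yWy = yVy - float(ty @ ty)
            logdet0 += 2.0 * float(np.log(np.diag(L)).sum())
        else:
            XWX, XWy, yWy = XVX, XVy, yVy
        return XWX, XWy, yWy, logdet0

    def crit(theta: np.ndarray) -> float:
        try:
            XWX, XWy, yWy, logdet = _quantities(theta)
            beta = np.linalg.solve(XWX, XWy)
            rss = yWy - float(beta @ XWy)
            if rss <= 0:
                return np.inf
            s2 = rss / (n - p)
            sign, logdetX = np.linalg.slogdet(XWX)
            if sign <= 0:
                return np.inf
            return (n - p) * np.log(s2) + logdet + logdetX
        except np.linalg.LinAlgError:
            return np.inf

    x0 = np.full(len(order), -1.0)
    res = minimize(
        crit, x0, method="Nelder-Mead",
        bounds=[_THETA_BOUNDS] * len(order),
        options=dict(xatol=1e-4, fatol=1e-7, maxiter=4000),
    )
    theta = np.clip(res.x, *_THETA_BOUNDS)
    XWX, XWy, yWy, _ = _quantities(theta)
    beta = np.linalg.solve(XWX, XWy)
    rss = yWy - float(beta @ XWy)
    s2 = rss / (n - p)
    cov = s2 * np.linalg.inv(XWX)
    g = np.exp(theta)
    vcomp = {f: float(gi * s2) for f, gi in zip(order, g)}
    for name in factors:
        vcomp.setdefault(name, 0.0)
    return _expand(VCFit(
        beta=beta,
        se=np.sqrt(np.diag(cov)),
        sigma2=float(s2),
        vcomp=vcomp,
        n_obs=n,
        converged=bool(res.success and np.isfinite(res.fun)),
        loglike_m2=float(res.fun),
        fixed_names=fixed_names or [],
    ))


def random_intercept_blups(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    fit: VCFit,
    factor: str,
) -> dict:
    """BLUPs of a single random-intercept factor given a fitted model.

    For a one-factor model u_k = gamma / (1 + gamma n_k) * sum of marginal
    residuals in level k, with gamma the fitted relative variance.
    """
    levels, codes = np.unique(np.asarray(groups), return_inverse=True)
    gamma = fit.vcomp.get(factor, 0.0) / fit.sigma2 if fit.sigma2 > 0 else 0.0
    resid = np.asarray(y, float) - np.asarray(X, float) @ fit.beta
    nk = np.bincount(codes, minlength=len(levels)).astype(float)
    sums = np.bincount(codes, weights=resid, minlength=len(levels))
    u = gamma / (1.0 + gamma * nk) * sums
    return dict(zip(levels.tolist(), u.tolist()))
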