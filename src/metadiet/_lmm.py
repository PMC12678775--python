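"""Fast restricted-maximum-likelihood engine for family random-intercept models.

The association scans fit tens of thousands of models of the form

    y = X beta + u_family + e,   u_f ~ N(0, s2_u),  e ~ N(0, s2_e),

where families are twin pairs or singletons. Because every model shares the
same grouping structure, the covariance V = s2_e (I + theta Z Z') with
theta = s2_u / s2_e admits a closed-form inverse per family block:

    V^-1 = I - diag_f[ theta / (1 + m_f theta) ] J_f

with m_f the family size and J_f the within-family all-ones block. All
cross-products needed for the profiled REML criterion can therefore be
assembled from per-family column sums, which lets a single X be scanned
against a whole outcome matrix Y at once over a grid of theta values.

The profiled criterion minimised here (constants dropped) is

    (n - p) log RSS(theta) + log|V(theta)| + log|X' V^-1 X|,

the standard REML profile for a single variance ratio.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, optimize, stats

__all__ = ["FamilyDesign", "reml_scan", "fit_reml"]

# theta = s2_u/s2_e grid; 0 plus log-spaced up to ICC ~0.98
_DEFAULT_GRID = np.concatenate([[0.0], np.geomspace(1e-3, 50.0, 60)])


class FamilyDesign:
    """Pre-computed family aggregation for a fixed sample ordering."""

    def __init__(self, families):
        families = np.asarray(families)
        codes, inverse = np.unique(families, return_inverse=True)
        self.n = families.shape[0]
        self.n_families = codes.shape[0]
        self.codes = inverse
        self.sizes = np.bincount(inverse).astype(float)

    def group_sum(self, M):
        """Per-family column sums of a (n, k) matrix."""
        M = np.atleast_2d(np.asarray(M, dtype=float))
        if M.shape[0] != self.n:
            M = M.T
        out = np.zeros((self.n_families, M.shape[1]))
        np.add.at(out, self.codes, M)
        return out


def _crit_components(theta, XtX, XtY, yty, SX, SY, sizes, n, p):
    """REML criterion pieces for one theta, vectorised over outcomes."""
    c = theta / (1.0 + sizes * theta)  # (F,)
    A = XtX - (SX * c[:, None]).T @ SX  # (p, p)
    B = XtY - (SX * c[:, None]).T @ SY  # (p, K)
    quad = yty - (c[:, None] * SY * SY).sum(axis=0)  # (K,)
    cho = linalg.cho_factor(A, lower=True)
    Binv = linalg.cho_solve(cho, B)
    rss = np.maximum(quad - (B * Binv).sum(axis=0), 1e-300)
    logdet_V = np.sum(np.log1p(sizes * theta))
    logdet_A = 2.0 * np.sum(np.log(np.diag(cho[0])))
    crit = (n - p) * np.log(rss) + logdet_V + logdet_A
    return crit, Binv, rss, cho


def reml_scan(Y, X, design, grid=None, refine=True, coef_index=-1):
    """Fit y_k = X beta + u_family + e for every column of Y by profiled REML.

    Parameters
    ----------
    Y : (n, K) outcome matrix.
    X : (n, p) design including intercept; ``coef_index`` selects the
        coefficient whose Wald statistics are reported.
    design : FamilyDesign built on the same sample ordering.
    refine : when True, the grid optimum of each outcome is polished with a
        bounded scalar search between its neighbouring grid points.

    Returns dict of arrays (beta, se, z, p, theta, icc, sigma2_e, sigma2_u).
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    n, p = X.shape
    K = Y.shape[1]
    if grid is None:
        grid = _DEFAULT_GRID
    sizes = design.sizes
    XtX = X.T @ X
    XtY = X.T @ Y
    yty = (Y * Y).sum(axis=0)
    SX = design.group_sum(X)
    SY = design.group_sum(Y)

    crits = np.empty((grid.size, K))
    for i, th in enumerate(grid):
        crits[i], _, _, _ = _crit_components(th, XtX, XtY, yty, SX, SY, sizes, n, p)
    best = np.argmin(crits, axis=0)

    theta_hat = grid[best].astype(float)
    if refine:
        for k in range(K):
            b = best[k]
            lo = grid[max(b - 1, 0)]
            hi = grid[min(b + 1, grid.size - 1)]
            if hi <= lo:
                continue
            yk = Y[:, k : k + 1]

            def _obj(th, _yk=yk, _k=k):
                c, _, _, _ = _crit_components(
                    th, XtX, XtY[:, _k : _k + 1], yty[_k : _k + 1],
                    SX, SY[:, _k : _k + 1], sizes, n, p,
                )
                return float(c[0])

            res = optimize.minimize_scalar(
                _obj, bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-4 * (1 + hi)},
            )
            if res.fun <= crits[b, k]:
                theta_hat[k] = res.x

    # final per-outcome fits at theta_hat (grouped to reuse identical thetas)
    beta = np.empty(K)
    se = np.empty(K)
    sigma2_e = np.empty(K)
    betas_full = np.empty((p, K))
    for th in np.unique(theta_hat):
        sel = np.where(theta_hat == th)[0]
        crit, Binv, rss, cho = _crit_components(
            th, XtX, XtY[:, sel], yty[sel], SX, SY[:, sel], sizes, n, p
        )
        s2 = rss / (n - p)
        Ainv_jj = linalg.cho_solve(cho, np.eye(p))[coef_index, coef_index]
        beta[sel] = Binv[coef_index]
        se[sel] = np.sqrt(s2 * Ainv_jj)
        sigma2_e[sel] = s2
        betas_full[:, sel] = Binv

    z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    sigma2_u = theta_hat * sigma2_e
    icc = sigma2_u / (sigma2_u + sigma2_e)
    return {
        "beta": beta, "se": se, "z": z, "p": pval,
        "theta": theta_hat, "icc": icc,
        "sigma2_e": sigma2_e, "sigma2_u": sigma2_u,
        "betas_full": betas_full,
    }


def fit_reml(y, X, families, grid=None):
    """Single-outcome REML fit returning the full coefficient covariance.

    Used by the mediation engine, which needs joint draws of several fixed
    effects. Returns (beta, cov, theta, sigma2_e).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    design = FamilyDesign(families)
    res = reml_scan(y, X, design, grid=grid, refine=True)
    th = float(res["theta"][0])
    n, p = X.shape
    sizes = design.sizes
    c = th / (1.0 + sizes * th)
    SX = design.group_sum(X)
    A = X.T @ X - (SX * c[:, None]).T @ SX
    cov = np.linalg.inv(A) * res["sigma2_e"][0]
    return res["betas_full"][:, 0], cov, th, float(res["sigma2_e"][0])
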