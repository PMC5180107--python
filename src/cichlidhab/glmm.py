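"""Poisson generalized linear mixed model with a year random intercept.

Per-cell, per-year adult counts are modelled as

    y_ij ~ Poisson(mu_ij),   log mu_ij = x_ij' beta + b_j,   b_j ~ N(0, sigma^2)

with one random intercept b_j per census year j.  The marginal likelihood
factorises over years; each year's one-dimensional integral is evaluated
by adaptive Gauss-Hermite quadrature centred on the conditional mode, so
the fit is exact up to quadrature error (21 nodes by default).

Because the linear predictor enters each group only through
S_j = sum_i y_ij and T_j(beta) = sum_i exp(x_ij' beta), each marginal
log-likelihood evaluation costs one pass over the data plus O(groups)
work, which keeps replicate simulations cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import gammaln

_MIN_LOG_SIGMA = np.log(1e-4)


@dataclass
class GlmmFit:
    params: np.ndarray          # fixed-effect coefficients beta
    se: np.ndarray              # standard errors of beta
    param_names: list[str]
    sigma_year: float           # random-intercept SD
    sigma_year_se: float | None
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int
    message: str = ""

    def summary_frame(self):
        import pandas as pd

        z = self.params / self.se
        from scipy.stats import norm

        return pd.DataFrame(
            {
                "term": self.param_names,
                "estimate": self.params,
                "std_error": self.se,
                "z": z,
                "p": 2 * norm.sf(np.abs(z)),
            }
        )

    def confint(self, level: float = 0.95) -> np.ndarray:
        from scipy.stats import norm

        q = norm.ppf(0.5 + level / 2)
        return np.column_stack([self.params - q * self.se, self.params + q * self.se])


class _MarginalLoglik:
    def __init__(self, y, X, groups, n_quad=21):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        groups = np.asarray(groups)
        order = np.argsort(groups, kind="stable")
        self.y = y[order]
        self.X = X[order]
        g = groups[order]
        _, self.starts = np.unique(g, return_index=True)
        self.n_groups = len(self.starts)
        self.S = np.add.reduceat(self.y, self.starts)          # sum of counts per group
        self.const = float(-np.sum(gammaln(self.y + 1.0)))
        self.xq, self.wq = hermgauss(n_quad)

    def _modes(self, T, sigma2):
        """Per-group conditional modes of b via Newton on a scalar equation."""
        # f'(b) = S - e^b T - b/sigma2
        b = np.log(np.maximum(self.S, 0.5) / T)  # good starting point
        b = np.clip(b, -5, 5)
        for _ in range(50):
            eb = np.exp(b)
            g1 = self.S - eb * T - b / sigma2
            g2 = -eb * T - 1.0 / sigma2
            step = g1 / g2
            b = b - step
            if np.max(np.abs(step)) < 1e-10:
                break
        return b

    def __call__(self, theta) -> float:
        beta = theta[:-1]
        log_sigma = theta[-1]
        sigma = np.exp(log_sigma)
        sigma2 = sigma * sigma
        eta = self.X @ beta
        eta = np.clip(eta, -50, 50)
        exp_eta = np.exp(eta)
        T = np.add.reduceat(exp_eta, self.starts)
        Cg = np.add.reduceat(self.y * eta, self.starts)

        bhat = self._modes(T, sigma2)
        curv = np.exp(bhat) * T + 1.0 / sigma2        # -f''(bhat)
        s = 1.0 / np.sqrt(curv)
        # adaptive Gauss-Hermite: integral = sqrt(2) s sum_k w_k e^{x_k^2} e^{f(bhat+sqrt2 s x_k)}
        nodes = bhat[:, None] + np.sqrt(2.0) * s[:, None] * self.xq[None, :]
        f = (
            self.S[:, None] * nodes
            - np.exp(nodes) * T[:, None]
            - nodes**2 / (2 * sigma2)
        )
        fmax = f.max(axis=1, keepdims=True)
        integ = np.sqrt(2.0) * s * np.sum(
            self.wq[None, :] * np.exp(self.xq[None, :] ** 2 + f - fmax), axis=1
        )
        ll_groups = np.log(integ) + fmax[:, 0] - 0.5 * np.log(2 * np.pi * sigma2)
        return float(np.sum(ll_groups) + np.sum(Cg) + self.const)


def _numerical_hessian(fun, x, eps=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            H[i, j] = H[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (4 * eps * eps)
    return H


def fit_poisson_glmm(
    y,
    X,
    groups,
    param_names: list[str] | None = None,
    n_quad: int = 21,
) -> GlmmFit:
    """Fit the Poisson random-intercept GLMM by maximum marginal likelihood.

    Parameters
    ----------
    y : counts, one per (cell, year) observation
    X : design matrix including the intercept column
    groups : grouping labels (census year) for the random intercept
    param_names : column names for reporting
    n_quad : Gauss-Hermite nodes for the 1D year integrals

    Non-convergence is reported through the ``converged`` flag, never as an
    exception.  A rank-deficient design raises, naming the aliased columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    if X.ndim != 2 or len(y) != len(X) or len(groups) != len(y):
        raise ValueError("y, X and groups must have matching first dimensions")
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least two grouping levels (years)")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = param_names or [f"x{i}" for i in range(X.shape[1])]
        _, R = np.linalg.qr(X)
        aliased = [names[i] for i in range(X.shape[1]) if abs(R[i, i]) < 1e-8]
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")
    if param_names is None:
        param_names = [f"x{i}" for i in range(X.shape[1])]

    nll_obj = _MarginalLoglik(y, X, groups, n_quad=n_quad)

    def nll(theta):
        return -nll_obj(theta)

    # start from a plain Poisson GLM (IRLS)
    beta0 = _poisson_glm_start(y, X)
    theta0 = np.append(beta0, np.log(0.3))
    bounds = [(None, None)] * X.shape[1] + [(_MIN_LOG_SIGMA, 3.0)]
    res = minimize(nll, theta0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    theta = res.x
    converged = bool(res.success)
    message = str(res.message)

    p = X.shape[1]
    H = _numerical_hessian(nll, theta)
    se = np.full(p, np.nan)
    sigma_se = None
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if np.all(d[:p] > 0):
            se = np.sqrt(d[:p])
        else:
            converged = False
            message += "; Hessian not positive definite"
        if d[p] > 0:
            # delta method: sd(sigma) = sigma * sd(log sigma)
            sigma_se = float(np.exp(theta[p]) * np.sqrt(d[p]))
    except np.linalg.LinAlgError:
        converged = False
        message += "; Hessian singular"

    return GlmmFit(
        params=theta[:p],
        se=se,
        param_names=list(param_names),
        sigma_year=float(np.exp(theta[p])),
        sigma_year_se=sigma_se,
        loglik=float(-res.fun),
        converged=converged,
        n_obs=len(y),
        n_groups=nll_obj.n_groups,
        message=message,
    )


def _poisson_glm_start(y, X, n_iter: int = 25) -> np.ndarray:
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-3))
    for _ in range(n_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        W = mu
        zresp = eta + (y - mu) / np.maximum(mu, 1e-10)
        WX = X * W[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX + 1e-10 * np.eye(X.shape[1]), WX.T @ zresp)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    return beta


def build_ecomorph_design(counts: "pd.DataFrame", min_occurrence: int = 30):
    """Design matrix for one ecomorph's density GLMM.

    ``counts`` must have columns: count, species, depth, substratum,
    inclination, year — one row per (cell, year, species).  Species with
    fewer than ``min_occurrence`` total adults are dropped with a notice
    (too rare to estimate).  Substratum uses treatment contrasts with
    'rock' as the reference class; the first species (alphabetically) is
    the species reference level.

    Returns (y, X, groups, names, excluded_species).
    """
    import logging

    import pandas as pd

    log = logging.getLogger(__name__)
    df = counts.copy()
    totals = df.groupby("species")["count"].sum()
    excluded = sorted(totals[totals < min_occurrence].index.tolist())
    if excluded:
        log.info("GLMM: excluding rare species %s (< %d adults)", excluded, min_occurrence)
        df = df[~df["species"].isin(excluded)]
    if df.empty or df["species"].nunique() < 1:
        raise ValueError("no species left after rare-species exclusion")

    species_levels = sorted(df["species"].unique())
    sub_levels = ["rock"] + [s for s in ("stone", "rubble", "gravel", "sand")
                             if s in set(df["substratum"])]
    n = len(df)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    for sp in species_levels[1:]:
        cols.append((df["species"] == sp).to_numpy(float))
        names.append(f"species[{sp}]")
    cols.append(df["depth"].to_numpy(float))
    names.append("depth")
    for sub in sub_levels[1:]:
        cols.append((df["substratum"] == sub).to_numpy(float))
        names.append(f"substratum[{sub}]")
    cols.append(df["inclination"].to_numpy(float))
    names.append("inclination")
    X = np.column_stack(cols)
    y = df["count"].to_numpy(float)
    groups = df["year"].to_numpy()
    return y, X, groups, names, excluded
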