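"""Maximum-likelihood random-intercept linear models.

Both structural equations share one computational core: a Gaussian linear
model with a single random intercept per level-2 unit (participant),

    y_it = x_it' beta + gamma_i + eps_it,
    gamma_i ~ N(0, sigma2_level2),  eps_it ~ N(0, sigma2_level1),

whose marginal covariance is compound-symmetric within each group. The fit
profiles the likelihood: for a fixed variance ratio lambda =
sigma2_level2 / sigma2_level1 the GLS coefficients and sigma2_level1 have
closed forms (the per-group inverse (I + lambda J)^-1 = I - lambda/(1 +
lambda k) J needs only group sums), leaving a one-dimensional search over
lambda >= 0. The search scans a geometric grid spanning [1e-8, 1e8], admits
the OLS boundary lambda = 0, and polishes the best bracket with bounded
Brent on log(lambda).

ML is the default (matching large-sample z inference on the fixed effects);
REML is available via a flag. Fixed-effect covariance is the inverse GLS
information at the optimum, without small-sample correction.

A second entry point, :func:`fit_nested_intercepts`, adds one nested
random intercept (sessions within participants) for the pooled two-site
stacked model; it maximizes the same profiled likelihood over two variance
ratios with a dense per-group factorization (groups are tiny).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

logger = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)


class DesignError(ValueError):
    """The design matrix is rank deficient (collinear columns)."""


class ConvergenceError(RuntimeError):
    pass


@dataclass
class MixedFitResult:
    """Fixed effects, their covariance and the two variance components."""

    coefficients: pd.Series
    coefficient_covariance: pd.DataFrame
    var_level2: float  # random-intercept variance (participant)
    var_level1: float  # residual variance
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    method: str = "ML"
    var_session: float | None = None  # extra nested component (stacked fits only)

    @property
    def se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.coefficient_covariance.to_numpy())),
            index=self.coefficients.index,
        )

    @property
    def icc(self) -> float:
        extra = self.var_session or 0.0
        return self.var_level2 / (self.var_level2 + extra + self.var_level1)

    def to_json(self, path=None) -> str:
        payload = {
            "coefficients": self.coefficients.to_dict(),
            "se": self.se.to_dict(),
            "coefficient_covariance": self.coefficient_covariance.to_numpy().tolist(),
            "var_level2": self.var_level2,
            "var_level1": self.var_level1,
            "var_session": self.var_session,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "converged": self.converged,
            "method": self.method,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _coerce_design(y, X, groups, names):
    yv = np.asarray(y, dtype=float).ravel()
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        if names is None:
            names = [f"x{j}" for j in range(Xv.shape[1])]
    g = np.asarray(groups)
    if not (len(yv) == len(Xv) == len(g)):
        raise ValueError("y, X and groups must be row-aligned")
    if np.isnan(yv).any() or np.isnan(Xv).any():
        raise ValueError("complete cases only: drop rows with nulls before fitting")
    return yv, Xv, g, list(names)


def _check_rank(Xv, names):
    _, R, piv = linalg.qr(Xv, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xv.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < Xv.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise DesignError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_random_intercept(
    y,
    X,
    groups,
    reml: bool = False,
    names: Sequence[str] | None = None,
) -> MixedFitResult:
    """ML (or REML) fit of the one-random-intercept model.

    Rows of ``y``, ``X`` and ``groups`` must be aligned complete cases; ``X``
    must include its own intercept column if one is wanted. Output is
    invariant (to ~1e-12) under row permutations, and the boundary
    ``var_level2 = 0`` (plain OLS) is admitted.
    """
    yv, Xv, g, names = _coerce_design(y, X, groups, names)
    _check_rank(Xv, names)
    n, p = Xv.shape

    # canonical content-based ordering: group label, then response and
    # design values, so summation order (and hence bit-level output) does
    # not depend on the input row order
    codes, _ = pd.factorize(g, sort=True)
    keys = tuple(Xv[:, j] for j in reversed(range(Xv.shape[1]))) + (yv, codes)
    order = np.lexsort(keys)
    yv, Xv, codes = yv[order], Xv[order], codes[order]
    G = codes.max() + 1
    starts = np.searchsorted(codes, np.arange(G))
    k = np.diff(np.append(starts, n)).astype(float)

    Sx = np.add.reduceat(Xv, starts, axis=0)  # per-group column sums
    Sy = np.add.reduceat(yv, starts)

    # within/between split: X'V0^-1 X = Xc'Xc + sum_g SxSx'/(k(1+lam k)).
    # All terms stay positive as lam grows, so no catastrophic cancellation
    # on the lam -> infinity ridge (unlike XtX - c SxSx').
    Xc = Xv - np.repeat(Sx / k[:, None], k.astype(int), axis=0)
    yc = yv - np.repeat(Sy / k, k.astype(int))
    W = Xc.T @ Xc
    Wxy = Xc.T @ yc

    df_resid = n - p if reml else n

    def profile(lam: float):
        w = 1.0 / (k * (1.0 + lam * k))
        A = W + (Sx * w[:, None]).T @ Sx
        b = Wxy + Sx.T @ (w * Sy)
        beta = linalg.solve(A, b, assume_a="pos")
        rc = yc - Xc @ beta
        Sr = Sy - Sx @ beta
        rss = float(rc @ rc + w @ (Sr**2))
        sigma2 = rss / df_resid
        ld = float(np.sum(np.log1p(lam * k)))
        ll = -0.5 * (df_resid * (_LOG2PI + math.log(sigma2) + 1.0) + ld)
        if reml:
            ll -= 0.5 * float(np.linalg.slogdet(A)[1])
        return ll, beta, sigma2, A

    def objective(u: float) -> float:
        return -profile(math.exp(u))[0]

    # geometric bracket scan, boundary lambda = 0 included
    grid_u = np.linspace(math.log(1e-8), math.log(1e8), 81)
    vals = np.array([objective(u) for u in grid_u])
    ll0 = profile(0.0)[0]
    best = int(np.argmin(vals))
    lo = grid_u[max(best - 1, 0)]
    hi = grid_u[min(best + 1, len(grid_u) - 1)]
    res = optimize.minimize_scalar(
        objective, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
    )
    converged = bool(res.success)
    lam_hat = math.exp(res.x)
    # boundary admitted; ties (e.g. the unidentified one-obs-per-group
    # ridge) break toward the OLS solution lambda = 0
    if ll0 >= -res.fun - 1e-8 * (1.0 + abs(ll0)):
        lam_hat = 0.0
        converged = True
    ll, beta, sigma2, A = profile(lam_hat)
    cov = sigma2 * linalg.inv(A)
    cov = (cov + cov.T) / 2.0

    if not converged:
        logger.warning("fit_random_intercept: lambda search did not converge")
    return MixedFitResult(
        coefficients=pd.Series(beta, index=names),
        coefficient_covariance=pd.DataFrame(cov, index=names, columns=names),
        var_level2=lam_hat * sigma2,
        var_level1=sigma2,
        loglik=ll,
        n_obs=n,
        n_groups=int(G),
        converged=converged,
        method="REML" if reml else "ML",
    )


def fit_nested_intercepts(
    y,
    X,
    groups,
    subgroups,
    reml: bool = False,
    names: Sequence[str] | None = None,
) -> MixedFitResult:
    """ML fit with participant and nested session random intercepts.

    Marginal covariance per participant: sigma2 * (I + lam1 * J_participant
    + lam2 * blockdiag(J_session)). Used by the pooled two-site stacked
    model, where the shared session intercept induces exchangeable
    cross-outcome correlation within a session. The 2-D profiled likelihood
    is maximized by a coarse log-grid followed by Nelder-Mead, with both
    boundaries (either component zero) admitted.
    """
    yv, Xv, g, names = _coerce_design(y, X, groups, names)
    _check_rank(Xv, names)
    n, p = Xv.shape
    sub = np.asarray(subgroups)

    codes, _ = pd.factorize(g, sort=True)
    order = np.lexsort((np.arange(n), pd.factorize(sub, sort=True)[0], codes))
    yv, Xv, codes, sub = yv[order], Xv[order], codes[order], sub[order]
    G = codes.max() + 1
    starts = np.append(np.searchsorted(codes, np.arange(G)), n)

    blocks = []
    for gi in range(G):
        sl = slice(starts[gi], starts[gi + 1])
        k = starts[gi + 1] - starts[gi]
        scodes = pd.factorize(sub[sl], sort=True)[0]
        Zs = np.eye(len(np.unique(scodes)))[scodes]  # session indicator within group
        blocks.append((yv[sl], Xv[sl], np.ones((k, 1)), Zs))

    df_resid = n - p if reml else n

    def profile(lam1: float, lam2: float):
        A = np.zeros((p, p))
        b = np.zeros(p)
        q = 0.0
        ld = 0.0
        for yg, Xg, Zg1, Zg2 in blocks:
            k = len(yg)
            C = np.eye(k) + lam1 * (Zg1 @ Zg1.T) + lam2 * (Zg2 @ Zg2.T)
            cf = linalg.cho_factor(C, lower=True)
            ld += 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            Xs = linalg.cho_solve(cf, Xg)
            ys = linalg.cho_solve(cf, yg)
            A += Xg.T @ Xs
            b += Xg.T @ ys
            q += float(yg @ ys)
        beta = linalg.solve(A, b, assume_a="pos")
        rss = q - float(beta @ b)
        sigma2 = rss / df_resid
        ll = -0.5 * (df_resid * (_LOG2PI + math.log(sigma2) + 1.0) + ld)
        if reml:
            ll -= 0.5 * float(np.linalg.slogdet(A)[1])
        return ll, beta, sigma2, A

    def objective(u):
        return -profile(math.exp(u[0]), math.exp(u[1]))[0]

    coarse = [-25.0, -6.0, -3.0, -1.5, 0.0, 1.5, 3.0, 6.0]
    best_u, best_val = None, np.inf
    for u1 in coarse:
        for u2 in coarse:
            v = objective((u1, u2))
            if v < best_val:
                best_u, best_val = (u1, u2), v
    res = optimize.minimize(
        objective,
        np.array(best_u),
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 600},
    )
    u_hat = res.x if res.fun <= best_val else np.array(best_u)
    lam1, lam2 = math.exp(u_hat[0]), math.exp(u_hat[1])
    # snap vanishing components to the boundary exactly
    if lam1 < 1e-9:
        lam1 = 0.0
    if lam2 < 1e-9:
        lam2 = 0.0
    ll, beta, sigma2, A = profile(lam1, lam2)
    cov = sigma2 * linalg.inv(A)
    cov = (cov + cov.T) / 2.0
    return MixedFitResult(
        coefficients=pd.Series(beta, index=names),
        coefficient_covariance=pd.DataFrame(cov, index=names, columns=names),
        var_level2=lam1 * sigma2,
        var_level1=sigma2,
        loglik=ll,
        n_obs=n,
        n_groups=int(G),
        converged=bool(res.success or res.fun >= best_val),
        method="REML" if reml else "ML",
        var_session=lam2 * sigma2,
    )


def wald_z(estimate: float, se: float) -> tuple[float, float]:
    """Large-sample Wald statistic and two-sided normal p-value."""
    if se <= 0:
        raise ValueError("se must be strictly positive")
    z = estimate / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def p_stars(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
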