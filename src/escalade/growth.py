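"""Latent growth curve model with covariate-dependent coefficients.

Fits the marginal mixed model

    y_i ~ N(X_i beta, Z_i G Z_i' + sigma^2 I)

per rat, where the mean is a polynomial in time (day 1 coded t = 0)
whose coefficients depend linearly on a per-rat covariate (the sucrose
PR z-score): X_i = [1, t, t^2, z_i, z_i t, z_i t^2] for the default
quadratic, and Z_i = [1, t, t^2] carries rat-specific random
adjustments to the coefficients with an unstructured covariance G.

Estimation maximizes the (restricted) Gaussian likelihood over
(chol(G), log sigma^2) with beta profiled out in closed form (GLS), via
quasi-Newton with seeded random restarts.  Hypothesis tests on the
covariate terms are Wald chi-square: the full (c0, c1, c2) block for
the "overall" association, c0 alone for the initial level, and
(c1, c2) for the change over sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

_LOGS2_BOUNDS = (-30.0, 30.0)


@dataclass
class GrowthFit:
    """Maximum-likelihood latent growth curve fit.

    ``beta`` stacks the time-polynomial coefficients (b0..b_q) followed
    by the covariate-interaction coefficients (c0..c_q) when a
    covariate is present.  ``G`` is the random-coefficient covariance
    (PSD by Cholesky construction) and ``sigma2`` the residual
    variance.
    """

    beta: np.ndarray
    G: np.ndarray
    sigma2: float
    vcov_beta: np.ndarray
    loglik: float
    n_rats: int
    n_obs: int
    order: int
    has_covariate: bool
    reml: bool = False
    converged: bool = True
    theta: np.ndarray = field(default=None, repr=False)

    @property
    def b(self) -> np.ndarray:
        return self.beta[: self.order + 1]

    @property
    def c(self) -> np.ndarray:
        if not self.has_covariate:
            raise ValueError("model was fit without covariate terms")
        return self.beta[self.order + 1 :]


def _panel_arrays(panel: pd.DataFrame, outcome: str):
    sub = panel[panel["outcome"] == outcome]
    if sub.empty:
        raise ValueError(f"panel has no rows for outcome {outcome!r}")
    by_rat = {}
    for rat, g in sub.groupby("rat_id", sort=True):
        g = g.sort_values("day")
        by_rat[rat] = (g["day"].to_numpy(dtype=float) - 1.0, g["value"].to_numpy(dtype=float))
    return by_rat


def _theta_unpack(theta: np.ndarray, q: int):
    L = np.zeros((q, q))
    idx = np.tril_indices(q)
    L[idx] = theta[:-1]
    return L, float(np.exp(theta[-1]))


def _nll_profiled(theta, patterns, q, p, reml):
    """Negative profiled loglik; returns (nll, beta, A_inv, quad_stats)."""
    L, s2 = _theta_unpack(theta, q)
    G = L @ L.T
    A = np.zeros((p, p))
    bvec = np.zeros(p)
    logdet_sum = 0.0
    n_obs = 0
    cache = []
    for (T, Y, Z) in patterns:
        m = T.shape[0]
        V = T @ G @ T.T + s2 * np.eye(m)
        try:
            cf = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf, None, None, None
        Vinv = np.linalg.inv(V)  # m small (<= n_days)
        logdetV = 2.0 * np.log(np.diag(cf)).sum()
        n_r = Y.shape[1]
        C = T.T @ Vinv @ T  # (q+? ) block on time columns
        P = T.T @ Vinv @ Y  # (ncol_T, n_r)
        if Z is None:
            A += n_r * C
            bvec += P.sum(axis=1)
        else:
            z1 = Z.sum()
            z2 = (Z * Z).sum()
            k = C.shape[0]
            A[:k, :k] += n_r * C
            A[:k, k:] += z1 * C
            A[k:, :k] += z1 * C
            A[k:, k:] += z2 * C
            bvec[:k] += P.sum(axis=1)
            bvec[k:] += (P * Z[None, :]).sum(axis=1)
        logdet_sum += n_r * logdetV
        n_obs += n_r * m
        cache.append((T, Y, Z, Vinv))
    try:
        beta = np.linalg.solve(A, bvec)
    except np.linalg.LinAlgError:
        return np.inf, None, None, None
    quad = 0.0
    for (T, Y, Z, Vinv) in cache:
        k = T.shape[1]
        fit_b = T @ beta[:k]
        R = Y - fit_b[:, None]
        if Z is not None:
            fit_c = T @ beta[k:]
            R = R - fit_c[:, None] * Z[None, :]
        quad += float(np.sum(R * (Vinv @ R)))
    nll = 0.5 * (logdet_sum + quad + n_obs * np.log(2.0 * np.pi))
    if reml:
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf, None, None, None
        nll += 0.5 * logdetA - 0.5 * p * np.log(2.0 * np.pi)
    return nll, beta, A, quad


def fit_lgcm(
    panel: pd.DataFrame,
    covariate: pd.Series | None,
    order: int = 2,
    outcome: str = "reinforced",
    reml: bool = False,
    n_restarts: int = 5,
    seed: int = 0,
    max_restarts_on_failure: int = 3,
) -> GrowthFit:
    """Fit the latent growth curve model by (RE)ML.

    Parameters
    ----------
    panel
        Long-format behavior table (``rat_id, day, outcome, value``);
        partially observed rats are included as-is.
    covariate
        Per-rat real covariate (e.g. sucrose z-score), indexed by
        rat_id.  ``None`` — or a constant column, dropped with a
        warning — yields the covariate-free growth model.
    order
        Polynomial order of the time trajectory (default quadratic).
    reml
        Use restricted ML instead of plain ML.
    """
    by_rat = _panel_arrays(panel, outcome)
    rats = list(by_rat)
    q = order + 1
    use_cov = covariate is not None
    if use_cov:
        missing = [r for r in rats if r not in covariate.index]
        if missing:
            raise ValueError(f"covariate missing for rats: {missing[:5]}")
        zvals = np.array([float(covariate.loc[r]) for r in rats])
        if np.ptp(zvals) == 0:
            warnings.warn("covariate is constant; dropping covariate terms", stacklevel=2)
            use_cov = False
    p = 2 * q if use_cov else q

    # group rats sharing an observation-day pattern for vectorized algebra
    patterns = {}
    for i, r in enumerate(rats):
        t, y = by_rat[r]
        key = tuple(t)
        patterns.setdefault(key, []).append(i)
    packed = []
    for key, idxs in patterns.items():
        t = np.asarray(key)
        T = np.vander(t, q, increasing=True)
        Y = np.column_stack([by_rat[rats[i]][1] for i in idxs])
        Z = zvals[idxs] if use_cov else None
        packed.append((T, Y, Z))

    # moment-based start: per-rat OLS polynomial fits
    coefs = []
    resid_var = []
    for r in rats:
        t, y = by_rat[r]
        if len(t) >= q + 1:
            T = np.vander(t, q, increasing=True)
            cf, res, *_ = np.linalg.lstsq(T, y, rcond=None)
            coefs.append(cf)
            dof = len(t) - q
            if dof > 0 and len(res):
                resid_var.append(res[0] / dof)
    if len(coefs) >= 2:
        G0 = np.cov(np.array(coefs).T)
        G0 = np.atleast_2d(G0) + 1e-6 * np.eye(q)
    else:
        G0 = np.eye(q)
    s2_0 = float(np.mean(resid_var)) if resid_var else 1.0
    s2_0 = max(s2_0, 1e-8)
    try:
        L0 = np.linalg.cholesky(G0)
    except np.linalg.LinAlgError:
        L0 = np.diag(np.sqrt(np.maximum(np.diag(G0), 1e-6)))
    tril = np.tril_indices(q)
    theta0 = np.concatenate([L0[tril], [np.log(s2_0)]])

    rng = np.random.default_rng(seed)
    n_theta = len(theta0)
    bounds = [(None, None)] * (n_theta - 1) + [_LOGS2_BOUNDS]

    def objective(th):
        return _nll_profiled(th, packed, q, p, reml)[0]

    best = None
    starts = [theta0] + [
        theta0 + rng.standard_normal(n_theta) * np.maximum(0.3 * np.abs(theta0), 0.1)
        for _ in range(n_restarts - 1)
    ]
    for th_start in starts:
        res = optimize.minimize(objective, th_start, method="L-BFGS-B", bounds=bounds)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("latent growth curve fit failed to converge from all starts")

    nll, beta, A, _ = _nll_profiled(best.x, packed, q, p, reml)
    L, s2 = _theta_unpack(best.x, q)
    vcov = np.linalg.inv(A)
    return GrowthFit(
        beta=beta,
        G=L @ L.T,
        sigma2=s2,
        vcov_beta=vcov,
        loglik=-nll,
        n_rats=len(rats),
        n_obs=sum(len(by_rat[r][0]) for r in rats),
        order=order,
        has_covariate=use_cov,
        reml=reml,
        converged=bool(best.success),
        theta=best.x,
    )


def test_covariate(fit: GrowthFit, which: str = "overall") -> tuple[float, int, float]:
    """Wald chi-square test on the covariate-interaction coefficients.

    ``which`` selects the hypothesis: ``"overall"`` tests all covariate
    terms jointly (df = order+1); ``"initial"`` tests the covariate
    effect on the day-1 level c0 (df = 1); ``"change"`` tests the
    effect on the change across sessions, (c1, .., c_q) (df = order).

    Returns ``(statistic, df, p)``.
    """
    if not fit.has_covariate:
        raise ValueError("fit has no covariate terms to test")
    q = fit.order + 1
    blocks = {
        "overall": list(range(q, 2 * q)),
        "initial": [q],
        "change": list(range(q + 1, 2 * q)),
    }
    if which not in blocks:
        raise ValueError(f"unknown hypothesis {which!r}; choose from {sorted(blocks)}")
    idx = blocks[which]
    c = fit.beta[idx]
    vc = fit.vcov_beta[np.ix_(idx, idx)]
    stat = float(c @ np.linalg.solve(vc, c))
    df = len(idx)
    pval = float(stats.chi2.sf(stat, df))
    return stat, df, pval


def predict_trajectory(fit: GrowthFit, z: float, days: np.ndarray) -> np.ndarray:
    """Expected-outcome curve for a hypothetical rat with covariate z.

    Evaluates ``(b0 + c0 z) + (b1 + c1 z) t + ...`` at t = day - 1, so a
    curve at z = +1 minus one at z = -1 differs by twice the covariate
    polynomial.
    """
    t = np.asarray(days, dtype=float) - 1.0
    T = np.vander(t, fit.order + 1, increasing=True)
    coef = fit.b.copy()
    if fit.has_covariate:
        coef = coef + z * fit.c
    return T @ coef
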