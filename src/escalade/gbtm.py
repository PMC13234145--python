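"""Multi-outcome group-based trajectory modeling (censored-normal mixture).

Rats are clustered into latent groups with distinct polynomial mean
trajectories, fit jointly over the three daily operant outcomes
(reinforced, futile, inactive presses).  The per-observation likelihood
is censored normal (Tobit): an ordinary Gaussian density in the
interior, replaced by the corresponding tail probability for values
recorded at a censor limit.  Heavily skewed outcomes are log(x+1)
transformed before modeling.  Estimation is EM with seeded k-means
initializations; group labels are ordered by ascending fitted
reinforced pressing so that higher group numbers mean higher intake.

Model selection across group counts reports log-likelihood, BIC and
AIC per candidate G.  Cross-classification of two independent
groupings is tested with a Fisher-type exact test (full enumeration
for small tables, seeded Monte-Carlo otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp
from sklearn.cluster import KMeans

from escalade.synthetic import OUTCOMES

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def censored_normal_loglik(y, mu, sigma, lower=-np.inf, upper=np.inf):
    """Log-likelihood of a censored-normal (Tobit) observation.

    Interior values contribute the normal log-density; a value recorded
    at the lower limit contributes log Phi((lower - mu)/sigma), at the
    upper limit log(1 - Phi((upper - mu)/sigma)).  Accepts scalars or
    broadcastable arrays.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    if np.any(lower >= upper):
        raise ValueError("lower must be < upper")
    if np.any((y < lower) | (y > upper)):
        raise ValueError("y outside [lower, upper]")
    r = (y - mu) / sigma
    interior = -0.5 * r * r - np.log(sigma) - _LOG_SQRT_2PI
    out = interior
    if np.isfinite(lower):
        at_lo = y <= lower
        out = np.where(at_lo, stats.norm.logcdf((lower - mu) / sigma), out)
    if np.isfinite(upper):
        at_hi = y >= upper
        out = np.where(at_hi, stats.norm.logsf((upper - mu) / sigma), out)
    return out if out.ndim else float(out)


@dataclass
class TrajModelSpec:
    """Settings for a multi-outcome trajectory mixture fit.

    ``censor`` bounds and ``poly_order`` are per outcome and apply on
    the modeling scale — after log(x+1) for outcomes flagged in
    ``log_transform``.  Defaults mirror a 21-day extended-access phase:
    reinforced presses censored at (0, 500) on the raw scale, futile
    and inactive log-transformed and censored at (0, 10).
    """

    n_groups: int = 3
    poly_order: tuple = (2, 2, 2)
    censor: tuple = ((0.0, 500.0), (0.0, 10.0), (0.0, 10.0))
    log_transform: tuple = (False, True, True)
    per_group_sigma: bool = False
    max_iter: int = 300
    n_starts: int = 3
    seed: int = 0
    tol: float = 1e-7

    def __post_init__(self):
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if any(lo >= hi for lo, hi in self.censor):
            raise ValueError("censor bounds need lower < upper")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")

    @classmethod
    def escalation(cls, **kw) -> "TrajModelSpec":
        """21-day extended-access settings (log-transformed futile/inactive)."""
        return cls(**kw)

    @classmethod
    def acquisition(cls, **kw) -> "TrajModelSpec":
        """7-day short-access settings: raw scale, limits (30, 70, 40)."""
        kw.setdefault("censor", ((0.0, 30.0), (0.0, 70.0), (0.0, 40.0)))
        kw.setdefault("log_transform", (False, False, False))
        kw.setdefault("n_groups", 5)
        return cls(**kw)


@dataclass
class TrajFit:
    """Fitted trajectory mixture."""

    pi: np.ndarray
    coefs: list  # per outcome: (n_groups, order_k+1)
    sigma: np.ndarray  # (3,) shared, or (n_groups, 3) with per_group_sigma
    posterior: pd.DataFrame
    assignment: pd.Series
    loglik: float
    bic: float
    aic: float
    n_params: int
    converged: bool
    spec: TrajModelSpec = field(repr=False, default=None)
    loglik_trace: list = field(repr=False, default_factory=list)

    @property
    def n_groups(self) -> int:
        return len(self.pi)


def _prepare(panel: pd.DataFrame, spec: TrajModelSpec):
    """Wide arrays on the modeling scale: Y (rats, days, 3), masks."""
    rats = sorted(panel["rat_id"].unique())
    days = sorted(panel["day"].unique())
    n, d = len(rats), len(days)
    Y = np.full((n, d, 3), np.nan)
    for k, name in enumerate(OUTCOMES):
        sub = panel[panel["outcome"] == name].pivot_table(
            index="rat_id", columns="day", values="value", aggfunc="mean"
        )
        sub = sub.reindex(index=rats, columns=days)
        Y[:, :, k] = sub.values
    for k in range(3):
        if spec.log_transform[k]:
            Y[:, :, k] = np.log1p(Y[:, :, k])
    obs = ~np.isnan(Y)
    at_lo = np.zeros_like(obs)
    at_hi = np.zeros_like(obs)
    for k in range(3):
        lo, hi = spec.censor[k]
        with np.errstate(invalid="ignore"):
            at_lo[:, :, k] = obs[:, :, k] & (Y[:, :, k] <= lo)
            at_hi[:, :, k] = obs[:, :, k] & (Y[:, :, k] >= hi)
        Y[:, :, k] = np.clip(Y[:, :, k], lo, hi)
    t = np.asarray(days, dtype=float) - 1.0
    return rats, t, Y, obs, at_lo, at_hi


def _cell_loglik(Yk, obs_k, lo_k, hi_k, mu, sigma, bounds):
    """(rats, days) -> summed loglik per rat for one outcome and one group."""
    lo, hi = bounds
    r = (Yk - mu[None, :]) / sigma
    ll = -0.5 * r * r - np.log(sigma) - _LOG_SQRT_2PI
    if np.isfinite(lo) and lo_k.any():
        ll = np.where(lo_k, stats.norm.logcdf((lo - mu[None, :]) / sigma), ll)
    if np.isfinite(hi) and hi_k.any():
        ll = np.where(hi_k, stats.norm.logsf((hi - mu[None, :]) / sigma), ll)
    return np.where(obs_k, ll, 0.0).sum(axis=1)


def _group_loglik_matrix(t, Y, obs, at_lo, at_hi, coefs, sigma, spec):
    n = Y.shape[0]
    G = coefs[0].shape[0]
    ll = np.zeros((n, G))
    per_group = sigma.ndim == 2
    for k in range(3):
        Tk = np.vander(t, coefs[k].shape[1], increasing=True)
        Yk = np.where(obs[:, :, k], Y[:, :, k], 0.0)
        for g in range(G):
            mu = Tk @ coefs[k][g]
            sg = sigma[g, k] if per_group else sigma[k]
            ll[:, g] += _cell_loglik(
                Yk, obs[:, :, k], at_lo[:, :, k], at_hi[:, :, k], mu, sg, spec.censor[k]
            )
    return ll


def _mstep_closed_form(t, Y, obs, w, order, per_group_sigma):
    """Weighted polynomial LS for one uncensored outcome; returns coefs, sigma."""
    q = order + 1
    X = np.vander(t, q, increasing=True)  # (d, q)
    M = obs.astype(float)  # (n, d)
    Yf = np.where(obs, Y, 0.0)
    S = np.einsum("dq,nd,dp->nqp", X, M, X)  # per-rat X'X on observed days
    v = np.einsum("dq,nd->nq", X, M * Yf)
    A = np.einsum("ng,nqp->gqp", w, S)
    b = np.einsum("ng,nq->gq", w, v)
    coefs = np.linalg.solve(A + 1e-10 * np.eye(q)[None], b[:, :, None])[:, :, 0]  # (G, q)
    F = coefs @ X.T  # (G, d)
    R2 = np.einsum("nd,gnd->ng", M, (Yf[None, :, :] - F[:, None, :]) ** 2)
    if per_group_sigma:
        denom = np.einsum("ng,nd->g", w, M)
        s2 = (w * R2).sum(axis=0) / np.maximum(denom, 1e-12)
    else:
        s2 = (w * R2).sum() / M.sum()
    return coefs, np.sqrt(np.maximum(s2, 1e-12))


def _mstep_censored(t, Y, obs, at_lo, at_hi, w, order, bounds, coefs0, sigma0, per_group_sigma):
    """Weighted censored-normal ML for one outcome via quasi-Newton."""
    q = order + 1
    G = w.shape[1]
    X = np.vander(t, q, increasing=True)
    Yk = np.where(obs, Y, 0.0)
    n_sig = G if per_group_sigma else 1

    def unpack(p):
        coefs = p[: G * q].reshape(G, q)
        logsig = p[G * q :]
        return coefs, np.exp(logsig)

    def negQ(p):
        coefs, sig = unpack(p)
        total = 0.0
        for g in range(G):
            mu = X @ coefs[g]
            sg = sig[g] if per_group_sigma else sig[0]
            llg = _cell_loglik(Yk, obs, at_lo, at_hi, mu, sg, bounds)
            total += float(w[:, g] @ llg)
        return -total

    sig0 = sigma0 if per_group_sigma else np.atleast_1d(sigma0)[:1]
    p0 = np.concatenate([coefs0.ravel(), np.log(np.maximum(sig0, 1e-8))])
    res = optimize.minimize(negQ, p0, method="L-BFGS-B", options={"maxiter": 60})
    p_best = res.x if res.fun <= negQ(p0) else p0
    coefs, sig = unpack(p_best)
    return coefs, (sig if per_group_sigma else sig[0])


def _init_posteriors(t, Y, obs, n_groups, rng, jitter):
    """k-means on per-rat (mean, slope) features per outcome, softened."""
    n = Y.shape[0]
    feats = []
    tc = t - t.mean()
    for k in range(3):
        M = obs[:, :, k].astype(float)
        Yf = np.where(obs[:, :, k], Y[:, :, k], 0.0)
        cnt = np.maximum(M.sum(axis=1), 1.0)
        mean_k = (Yf * M).sum(axis=1) / cnt
        den = np.maximum((M * tc[None, :] ** 2).sum(axis=1), 1e-9)
        slope_k = (M * tc[None, :] * (Yf - mean_k[:, None])).sum(axis=1) / den
        feats.extend([mean_k, slope_k])
    F = np.column_stack(feats)
    F = (F - F.mean(axis=0)) / np.maximum(F.std(axis=0), 1e-9)
    km = KMeans(n_clusters=n_groups, n_init=3, random_state=int(rng.integers(2**31 - 1)))
    labels = km.fit_predict(F)
    post = np.full((n, n_groups), 0.1 / max(n_groups - 1, 1))
    post[np.arange(n), labels] = 0.9
    if jitter > 0:
        post = post + rng.uniform(0, jitter, size=post.shape)
    return post / post.sum(axis=1, keepdims=True)


def _count_params(spec: TrajModelSpec) -> int:
    G = spec.n_groups
    p = (G - 1) + G * sum(o + 1 for o in spec.poly_order)
    p += 3 * (G if spec.per_group_sigma else 1)
    return p


def fit_gbtm(panel: pd.DataFrame, spec: TrajModelSpec) -> TrajFit:
    """Fit the censored-normal trajectory mixture by EM.

    Maximizes ``sum_i log sum_g pi_g prod_{k,t} f_cens(y_ikt |
    poly_gk(t), sigma_k)`` over mixing proportions, per-group
    polynomial coefficients and per-outcome noise scales.  The E-step
    computes posterior group memberships; the M-step updates pi in
    closed form and the trajectory parameters by weighted least squares
    (exact when no observation sits at a censor limit) or weighted
    censored-normal ML otherwise.  The best of ``spec.n_starts`` seeded
    initializations is returned, with groups relabeled in ascending
    order of fitted reinforced pressing.
    """
    rats, t, Y, obs, at_lo, at_hi = _prepare(panel, spec)
    n = len(rats)
    if n < spec.n_groups:
        raise ValueError(f"need at least n_groups={spec.n_groups} rats, got {n}")
    G = spec.n_groups
    rng = np.random.default_rng(spec.seed)
    any_censored = [bool(at_lo[:, :, k].any() or at_hi[:, :, k].any()) for k in range(3)]

    best = None
    failures = []
    for start in range(spec.n_starts):
        jitter = 0.0 if start == 0 else 0.2
        post = (
            np.ones((n, G)) / G
            if G == 1
            else _init_posteriors(t, Y, obs, G, rng, jitter)
        )
        pi = post.mean(axis=0)
        coefs = [None] * 3
        sigma_shared = np.ones(3)
        sigma_pg = np.ones((G, 3))
        # initial M-step from soft labels, censoring ignored for the warm start
        for k in range(3):
            c, s = _mstep_closed_form(t, Y[:, :, k], obs[:, :, k], post, spec.poly_order[k], spec.per_group_sigma)
            coefs[k] = c
            if spec.per_group_sigma:
                sigma_pg[:, k] = np.maximum(s, 1e-4)
            else:
                sigma_shared[k] = max(float(s), 1e-4)
        sigma = sigma_pg if spec.per_group_sigma else sigma_shared

        prev_ll = -np.inf
        ok = True
        trace = []
        for it in range(spec.max_iter):
            ll_mat = _group_loglik_matrix(t, Y, obs, at_lo, at_hi, coefs, sigma, spec)
            logw = np.log(np.maximum(pi, 1e-300))[None, :] + ll_mat
            norm = logsumexp(logw, axis=1)
            loglik = float(norm.sum())
            trace.append(loglik)
            post = np.exp(logw - norm[:, None])
            pi = post.mean(axis=0)
            if np.any(pi < 1e-6):
                ok = False
                break
            for k in range(3):
                if any_censored[k]:
                    s0 = sigma[:, k] if spec.per_group_sigma else sigma[k]
                    c, s = _mstep_censored(
                        t, Y[:, :, k], obs[:, :, k], at_lo[:, :, k], at_hi[:, :, k],
                        post, spec.poly_order[k], spec.censor[k], coefs[k], s0,
                        spec.per_group_sigma,
                    )
                else:
                    c, s = _mstep_closed_form(
                        t, Y[:, :, k], obs[:, :, k], post, spec.poly_order[k], spec.per_group_sigma
                    )
                coefs[k] = c
                if spec.per_group_sigma:
                    sigma[:, k] = np.maximum(s, 1e-4)
                else:
                    sigma[k] = max(float(s), 1e-4)
            if abs(loglik - prev_ll) < spec.tol * max(1.0, abs(loglik)):
                prev_ll = loglik
                break
            prev_ll = loglik
        if not ok:
            failures.append(f"start {start}: group emptied")
            continue
        # final E-step at the last parameters for a consistent loglik/posterior
        ll_mat = _group_loglik_matrix(t, Y, obs, at_lo, at_hi, coefs, sigma, spec)
        logw = np.log(np.maximum(pi, 1e-300))[None, :] + ll_mat
        norm = logsumexp(logw, axis=1)
        loglik = float(norm.sum())
        post = np.exp(logw - norm[:, None])
        trace.append(loglik)
        converged = it < spec.max_iter - 1
        if best is None or loglik > best[0]:
            best = (loglik, pi.copy(), [c.copy() for c in coefs], np.array(sigma, copy=True),
                    post.copy(), converged, list(trace))

    if best is None:
        raise RuntimeError("all EM starts failed: " + "; ".join(failures))

    loglik, pi, coefs, sigma, post, converged, trace = best
    # order groups by ascending mean fitted reinforced presses over the phase
    T0 = np.vander(t, coefs[0].shape[1], increasing=True)
    intake = (coefs[0] @ T0.T).mean(axis=1)
    order = np.argsort(intake, kind="stable")
    pi = pi[order]
    coefs = [c[order] for c in coefs]
    if sigma.ndim == 2:
        sigma = sigma[order]
    post = post[:, order]

    assignment = post.argmax(axis=1) + 1  # argmax takes the lowest index on ties
    n_params = _count_params(spec)
    posterior = pd.DataFrame(
        post, index=pd.Index(rats, name="rat_id"), columns=[f"group_{g+1}" for g in range(G)]
    )
    return TrajFit(
        pi=pi,
        coefs=coefs,
        sigma=sigma,
        posterior=posterior,
        assignment=pd.Series(assignment, index=posterior.index, name="group"),
        loglik=loglik,
        bic=-2.0 * loglik + n_params * np.log(n),
        aic=-2.0 * loglik + 2.0 * n_params,
        n_params=n_params,
        converged=converged,
        spec=spec,
        loglik_trace=trace,
    )


def select_groups(panel: pd.DataFrame, base_spec: TrajModelSpec, g_range) -> tuple[pd.DataFrame, int, dict]:
    """Fit the mixture for each candidate group count and tabulate fit.

    Returns ``(table, chosen_g, fits)`` where the table lists
    log-likelihood, BIC and AIC per G (with raw log-likelihood kept
    alongside for likelihood-based comparison) and ``chosen_g``
    minimizes BIC among successful fits.
    """
    g_range = list(g_range)
    if not g_range:
        raise ValueError("g_range must be non-empty")
    rows = []
    fits = {}
    for g in g_range:
        spec_g = replace(base_spec, n_groups=g)
        try:
            fit = fit_gbtm(panel, spec_g)
        except Exception as exc:  # recorded, not fatal
            rows.append({"n_groups": g, "loglik": np.nan, "bic": np.nan, "aic": np.nan,
                         "n_params": _count_params(spec_g), "error": str(exc)})
            continue
        fits[g] = fit
        rows.append({"n_groups": g, "loglik": fit.loglik, "bic": fit.bic, "aic": fit.aic,
                     "n_params": fit.n_params, "error": ""})
    table = pd.DataFrame(rows).set_index("n_groups")
    if table["bic"].isna().all():
        raise RuntimeError("every candidate G failed to fit")
    chosen = int(table["bic"].idxmin())
    return table, chosen, fits


def rank_test_by_group(values: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """Kruskal-Wallis rank test of a per-rat score across assigned groups.

    Convenience wrapper for post-hoc checks such as whether sucrose PR
    z-scores differ by trajectory group.  Returns ``(H, p)``.
    """
    common = values.index.intersection(groups.index)
    by_group = [values.loc[common][groups.loc[common] == g].values
                for g in sorted(groups.loc[common].unique())]
    by_group = [g for g in by_group if len(g) > 0]
    if len(by_group) < 2:
        raise ValueError("need at least 2 non-empty groups")
    stat, p = stats.kruskal(*by_group)
    return float(stat), float(p)


def _table_logprob(tbl: np.ndarray) -> float:
    """Log multivariate hypergeometric probability of an r x c table."""
    n = tbl.sum()
    lp = gammaln(tbl.sum(axis=1) + 1).sum() + gammaln(tbl.sum(axis=0) + 1).sum()
    lp -= gammaln(n + 1) + gammaln(tbl + 1).sum()
    return float(lp)


def _enumerate_tables(row_sums, col_sums, cap):
    """Yield all tables with the given margins; None if more than `cap`."""
    r, c = len(row_sums), len(col_sums)
    out = []

    def rec(i, remaining_cols, rows_acc):
        if len(out) > cap:
            raise OverflowError
        if i == r - 1:
            last = np.asarray(remaining_cols)
            if (last >= 0).all():
                out.append(np.vstack(rows_acc + [last]))
            return

        def fill(j, left, row_acc):
            if j == c - 1:
                if 0 <= left <= remaining_cols[j]:
                    rec(i + 1,
                        [remaining_cols[k] - (row_acc + [left])[k] for k in range(c)],
                        rows_acc + [np.asarray(row_acc + [left])])
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                fill(j + 1, left - v, row_acc + [v])

        fill(0, row_sums[i], [])

    try:
        rec(0, list(col_sums), [])
    except OverflowError:
        return None
    return out


@dataclass
class CrosstabResult:
    table: pd.DataFrame
    p: float
    method: str
    se: float | None = None

    def __iter__(self):  # allows `table, p = crosstab_exact_test(...)`
        return iter((self.table, self.p))


def crosstab_exact_test(
    assignA: pd.Series,
    assignB: pd.Series,
    min_group_n: int = 3,
    n_mc: int = 100_000,
    seed: int = 0,
    enumeration_cap: int = 200_000,
) -> CrosstabResult:
    """Fisher-type exact test of association between two groupings.

    Groups with fewer than ``min_group_n`` members on either margin are
    excluded before tabulation.  For 2x2 tables the classic two-sided
    Fisher test is used; larger tables are handled by full enumeration
    of tables with the observed margins (Freeman-Halton: p sums the
    probabilities of tables no more probable than the observed one) or,
    when enumeration exceeds ``enumeration_cap`` tables, by seeded
    Monte-Carlo permutation with ``n_mc`` draws, reported with its
    binomial standard error.
    """
    common = assignA.index.intersection(assignB.index)
    a = assignA.loc[common]
    b = assignB.loc[common]
    ka = a.value_counts()
    kb = b.value_counts()
    keep = a.isin(ka[ka >= min_group_n].index) & b.isin(kb[kb >= min_group_n].index)
    a, b = a[keep], b[keep]
    table = pd.crosstab(a, b)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("fewer than 2 retained levels on a margin; association test undefined")
    tbl = table.values.astype(int)

    if tbl.shape == (2, 2):
        _, p = stats.fisher_exact(tbl, alternative="two-sided")
        return CrosstabResult(table=table, p=float(p), method="fisher_2x2")

    lp_obs = _table_logprob(tbl)
    tables = _enumerate_tables(tbl.sum(axis=1), tbl.sum(axis=0), enumeration_cap)
    if tables is not None:
        lps = np.array([_table_logprob(x) for x in tables])
        p = float(np.exp(lps[lps <= lp_obs + 1e-10]).sum())
        return CrosstabResult(table=table, p=min(p, 1.0), method="exact_enumeration")

    rng = np.random.default_rng(seed)
    bvals = b.values.copy()
    hits = 0
    la = a.values
    cats_a = np.unique(la)
    cats_b = np.unique(bvals)
    ia = np.searchsorted(cats_a, la)
    for _ in range(n_mc):
        perm = rng.permutation(bvals)
        ib = np.searchsorted(cats_b, perm)
        tb = np.zeros((len(cats_a), len(cats_b)), dtype=int)
        np.add.at(tb, (ia, ib), 1)
        if _table_logprob(tb) <= lp_obs + 1e-10:
            hits += 1
    p = (1 + hits) / (n_mc + 1)
    se = math.sqrt(p * (1 - p) / n_mc)
    return CrosstabResult(table=table, p=float(p), method="monte_carlo", se=se)
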