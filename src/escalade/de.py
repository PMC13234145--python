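"""Count filtering, normalization and differential expression.

The core is a negative-binomial log-link GLM per gene with
median-of-ratios size factors as offsets and sex as an additive
covariate, giving Wald statistics per contrast.  On top of the
parametric test sits a permutation layer: sample group labels are
shuffled and the chosen statistic (pairwise Wald or an omnibus
likelihood ratio across groups) is recomputed, yielding unadjusted
permutation p-values that are robust to misspecified dispersion.
Benjamini-Hochberg step-up adjustment controls the FDR.

Dispersion is a per-gene moment estimator floored at 1e-8; no
empirical-Bayes shrinkage is applied — the permutation reference, not
the parametric one, carries the inferential weight here, and the null
behavior of both is covered by calibration tests.

All gene-wise GLM fits are vectorized across genes (shared design
matrix, batched weighted least squares), which keeps thousands of
label permutations tractable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

_MIN_DISP = 1e-8
_ETA_CLIP = 30.0


@dataclass
class CountMatrix:
    """Integer gene x sample counts with sample metadata.

    ``counts`` is genes x samples; ``meta`` is indexed by sample id and
    carries at least a ``group`` column (``sex`` optional).
    ``size_factors`` are per-sample scale factors with geometric mean 1
    once computed.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    size_factors: pd.Series | None = None

    def __post_init__(self):
        vals = self.counts.values
        if np.any(vals < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        missing = [s for s in self.counts.columns if s not in self.meta.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing[:5]}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def samples(self) -> list:
        return list(self.counts.columns)

    def normalized(self) -> pd.DataFrame:
        """Counts divided by size factors (computing factors if needed)."""
        sf = self.size_factors
        if sf is None:
            sf = size_factors_median_ratios(self)
        return self.counts / sf.reindex(self.counts.columns).values


@dataclass
class DEResult:
    """Per-gene differential expression table for one contrast."""

    table: pd.DataFrame
    contrast: tuple
    design_columns: list
    n_perm_used: int = 0
    notes: dict = field(default_factory=dict)


def filter_low_counts(cm: CountMatrix, min_total: int = 10) -> CountMatrix:
    """Drop genes whose total count across samples falls below ``min_total``.

    A gene with row sum exactly ``min_total`` is kept; strictly smaller
    sums are removed.
    """
    keep = cm.counts.sum(axis=1) >= min_total
    if not keep.any():
        raise ValueError("no genes pass the count filter")
    return CountMatrix(counts=cm.counts.loc[keep], meta=cm.meta, size_factors=cm.size_factors)


def size_factors_median_ratios(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The pseudo-reference for each gene is its geometric mean across
    samples, computed over genes positive in every sample; each
    sample's factor is the median of its count-to-reference ratios.
    """
    counts = cm.counts.values.astype(float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene is positive in all samples; median-of-ratios undefined "
            "(consider filtering or a pseudo-reference fallback)"
        )
    lc = np.log(counts[all_pos])
    log_ref = lc.mean(axis=1)
    log_sf = np.median(lc - log_ref[:, None], axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=cm.counts.columns, name="size_factor")


def _design_matrix(meta: pd.DataFrame, samples, with_sex: bool = True):
    """Intercept + treatment-coded group (+ sex) design; returns (X, cols, group_levels)."""
    m = meta.loc[samples]
    groups = m["group"].astype(str)
    levels = sorted(groups.unique(), key=lambda v: (len(v), v))
    X_cols = [np.ones(len(m))]
    names = ["intercept"]
    for lev in levels[1:]:
        X_cols.append((groups == lev).to_numpy(dtype=float))
        names.append(f"group_{lev}")
    if with_sex and "sex" in m.columns and m["sex"].nunique() > 1:
        sex_levels = sorted(m["sex"].astype(str).unique())
        X_cols.append((m["sex"].astype(str) == sex_levels[1]).to_numpy(dtype=float))
        names.append(f"sex_{sex_levels[1]}")
    return np.column_stack(X_cols), names, levels


def _irls_nb(Y, X, offset, alpha, max_iter=50, tol=1e-8, B0=None):
    """Batched IRLS for NB log-link GLMs sharing a design matrix.

    Y: (n_samples, n_genes); X: (n, p); offset: (n,); alpha: (n_genes,).
    Returns (B, mu, ok) with B (n_genes, p).
    """
    n, p = X.shape
    n_genes = Y.shape[1]
    if B0 is None:
        # log-linear start on pseudo counts
        z0 = np.log((Y + 0.5)) - offset[:, None]
        B = np.linalg.lstsq(X, z0, rcond=None)[0].T  # (genes, p)
    else:
        B = B0.copy()
    ok = np.ones(n_genes, dtype=bool)
    for _ in range(max_iter):
        eta = np.clip(X @ B.T + offset[:, None], -_ETA_CLIP, _ETA_CLIP)  # (n, genes)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[None, :] * mu)
        z = (eta - offset[:, None]) + (Y - mu) / mu
        XtWX = np.einsum("np,ng,nq->gpq", X, W, X)
        XtWz = np.einsum("np,ng,ng->gp", X, W, z)
        XtWX += 1e-10 * np.eye(p)[None]
        try:
            B_new = np.linalg.solve(XtWX, XtWz[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            B_new = np.stack([
                np.linalg.lstsq(XtWX[g], XtWz[g], rcond=None)[0] for g in range(n_genes)
            ])
        bad = ~np.isfinite(B_new).all(axis=1)
        if bad.any():
            ok &= ~bad
            B_new[bad] = B[bad]
        delta = np.abs(B_new - B).max(axis=1)
        B = B_new
        if delta.max() < tol:
            break
    eta = np.clip(X @ B.T + offset[:, None], -_ETA_CLIP, _ETA_CLIP)
    return B, np.exp(eta), ok


def _moment_dispersion(Y, mu, n_params):
    """Per-gene NB dispersion matching the Pearson chi-square statistic.

    Solves sum_s (y - mu)^2 / (mu (1 + alpha mu)) = n - p for alpha by
    bisection (the left side is decreasing in alpha); floored at 1e-8.
    """
    n = Y.shape[0]
    dof = max(n - n_params, 1)
    mu = np.maximum(mu, 1e-12)
    sq = (Y - mu) ** 2

    def pearson(alpha):
        return (sq / (mu * (1.0 + alpha[None, :] * mu))).sum(axis=0) - dof

    lo = np.full(Y.shape[1], _MIN_DISP)
    hi = np.full(Y.shape[1], 100.0)
    under = pearson(lo) <= 0  # under-dispersed relative to Poisson
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        too_low = pearson(mid) > 0
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    alpha = 0.5 * (lo + hi)
    return np.where(under, _MIN_DISP, np.maximum(alpha, _MIN_DISP))


def _nb_deviance(Y, mu, alpha):
    """Per-gene NB deviance (saturated minus fitted, times 2)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(Y > 0, Y * np.log(np.maximum(Y, 1e-300) / mu), 0.0)
        t2 = (Y + 1.0 / alpha[None, :]) * np.log((1.0 + alpha[None, :] * Y) / (1.0 + alpha[None, :] * mu))
    return 2.0 * (t1 - t2).sum(axis=0)


def _contrast_vector(names: list, levels: list, contrast: tuple) -> np.ndarray:
    """Contrast ('group', num, den) -> coefficient-combination vector."""
    factor, num, den = contrast
    if factor != "group":
        raise ValueError("only 'group' contrasts are supported")
    num, den = str(num), str(den)
    c = np.zeros(len(names))
    ref = levels[0]
    if num not in levels or den not in levels:
        raise ValueError(f"contrast levels {num!r}/{den!r} not among groups {levels}")
    if num != ref:
        c[names.index(f"group_{num}")] += 1.0
    if den != ref:
        c[names.index(f"group_{den}")] -= 1.0
    return c


def fit_nb_wald(
    cm: CountMatrix,
    contrast: tuple = ("group", "3", "1"),
    with_sex: bool = True,
    alpha_disp: np.ndarray | None = None,
) -> DEResult:
    """Per-gene NB Wald test for a group contrast, sex as covariate.

    Fits ``log mu = X beta + log(size factor)`` per gene with a shared
    design (intercept, treatment-coded group, sex), dispersion from a
    moment estimator on the Poisson fit, and reports the Wald statistic
    ``(c'beta)/se(c'beta)`` for the requested contrast with a two-sided
    normal p-value, plus BH-adjusted q-values.
    """
    sf = cm.size_factors if cm.size_factors is not None else size_factors_median_ratios(cm)
    samples = cm.samples
    Y = cm.counts.values.T.astype(float)  # (n_samples, n_genes)
    offset = np.log(sf.reindex(samples).values)
    X, names, levels = _design_matrix(cm.meta, samples, with_sex=with_sex)
    n, p = X.shape
    if n <= p:
        raise ValueError("more design columns than samples")

    if alpha_disp is None:
        _, mu_pois, _ = _irls_nb(Y, X, offset, np.zeros(Y.shape[1]), max_iter=30)
        alpha_disp = _moment_dispersion(Y, mu_pois, p)
    B, mu, ok = _irls_nb(Y, X, offset, alpha_disp)

    W = mu / (1.0 + alpha_disp[None, :] * mu)
    XtWX = np.einsum("np,ng,nq->gpq", X, W, X) + 1e-10 * np.eye(p)[None]
    cov = np.linalg.inv(XtWX)
    cvec = _contrast_vector(names, levels, contrast)
    if not cvec.any():  # a group contrasted with itself
        est = np.zeros(Y.shape[1])
        se = np.full(Y.shape[1], np.nan)
        wald = np.zeros(Y.shape[1])
        pvals = np.ones(Y.shape[1])
    else:
        est = B @ cvec  # natural-log scale
        se = np.sqrt(np.einsum("p,gpq,q->g", cvec, cov, cvec))
        with np.errstate(divide="ignore", invalid="ignore"):
            wald = est / se
        pvals = 2.0 * stats.norm.sf(np.abs(wald))
        pvals = np.where(ok & np.isfinite(wald), pvals, np.nan)

    ln2 = math.log(2.0)
    table = pd.DataFrame(
        {
            "baseMean": (Y / np.exp(offset)[:, None]).mean(axis=0),
            "log2fc": est / ln2,
            "se": se / ln2,
            "wald_stat": wald,
            "dispersion": alpha_disp,
            "p_param": pvals,
            "q": bh_adjust(pd.Series(pvals)).values,
        },
        index=cm.counts.index,
    )
    return DEResult(table=table, contrast=contrast, design_columns=names)


def _distinct_label_permutations(labels: np.ndarray):
    """All distinct orderings of a label multiset (lexicographic)."""
    values, counts = np.unique(labels, return_counts=True)
    n = len(labels)
    out = []
    cur = np.empty(n, dtype=labels.dtype)

    def rec(pos, cnt):
        if pos == n:
            out.append(cur.copy())
            return
        for i, v in enumerate(values):
            if cnt[i]:
                cnt[i] -= 1
                cur[pos] = v
                rec(pos + 1, cnt)
                cnt[i] += 1

    rec(0, list(counts))
    return out


def _log_n_distinct_perms(labels) -> float:
    _, counts = np.unique(labels, return_counts=True)
    return math.lgamma(len(labels) + 1) - sum(math.lgamma(c + 1) for c in counts)


def permutation_pvalues(
    cm: CountMatrix,
    statistic: str = "wald",
    contrast: tuple = ("group", "3", "1"),
    B: int = 10_000,
    seed: int = 0,
    with_sex: bool = True,
    strata: str | None = None,
) -> pd.Series:
    """Permutation p-values for group-related differential expression.

    Group labels are permuted across samples B times (optionally within
    ``strata``, e.g. sex) and the chosen statistic is recomputed with
    dispersions held fixed at their observed-data estimates:

    - ``"wald"`` — absolute Wald statistic of ``contrast``;
    - ``"lrt"`` — omnibus NB likelihood-ratio (deviance drop) of the
      group factor against the no-group model.

    p = (1 + #{|T_b| >= |T_obs|}) / (B + 1); when fewer than B distinct
    label arrangements exist they are enumerated exactly and the exact
    p-value (including the identity arrangement) is returned.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    sf = cm.size_factors if cm.size_factors is not None else size_factors_median_ratios(cm)
    samples = cm.samples
    Y = cm.counts.values.T.astype(float)
    offset = np.log(sf.reindex(samples).values)
    meta = cm.meta.loc[samples]
    labels = meta["group"].astype(str).to_numpy()
    if len(np.unique(labels)) < 2:
        return pd.Series(1.0, index=cm.counts.index, name="p_perm")

    # dispersion from the observed-data fit, fixed across permutations
    X_obs, names, levels = _design_matrix(meta, samples, with_sex=with_sex)
    p_full = X_obs.shape[1]
    _, mu_pois, _ = _irls_nb(Y, X_obs, offset, np.zeros(Y.shape[1]), max_iter=30)
    alpha = _moment_dispersion(Y, mu_pois, p_full)

    sex_col = None
    if with_sex and "sex" in meta.columns and meta["sex"].nunique() > 1:
        sex_levels = sorted(meta["sex"].astype(str).unique())
        sex_col = (meta["sex"].astype(str) == sex_levels[1]).to_numpy(dtype=float)

    def stat_for(perm_labels: np.ndarray) -> np.ndarray:
        cols = [np.ones(len(samples))]
        nm = ["intercept"]
        for lev in levels[1:]:
            cols.append((perm_labels == lev).astype(float))
            nm.append(f"group_{lev}")
        if sex_col is not None:
            cols.append(sex_col)
            nm.append("sex")
        X = np.column_stack(cols)
        Bc, mu, _ = _irls_nb(Y, X, offset, alpha, max_iter=25, tol=1e-6)
        if statistic == "wald":
            W = mu / (1.0 + alpha[None, :] * mu)
            XtWX = np.einsum("np,ng,nq->gpq", X, W, X) + 1e-10 * np.eye(X.shape[1])[None]
            cov = np.linalg.inv(XtWX)
            cvec = _contrast_vector(nm, levels, contrast)
            est = Bc @ cvec
            se = np.sqrt(np.einsum("p,gpq,q->g", cvec, cov, cvec))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.abs(est / se)
            return np.where(np.isfinite(t), t, 0.0)
        elif statistic == "lrt":
            dev_full = _nb_deviance(Y, mu, alpha)
            keep = [0] + ([X.shape[1] - 1] if sex_col is not None else [])
            X0 = X[:, keep]
            _, mu0, _ = _irls_nb(Y, X0, offset, alpha, max_iter=25, tol=1e-6)
            dev_red = _nb_deviance(Y, mu0, alpha)
            return np.maximum(dev_red - dev_full, 0.0)
        raise ValueError(f"unknown statistic {statistic!r}")

    t_obs = stat_for(labels)
    rng = np.random.default_rng(seed)

    if strata is not None:
        strata_vals = meta[strata].astype(str).to_numpy()
        idx_by_stratum = [np.flatnonzero(strata_vals == s) for s in np.unique(strata_vals)]

        def draw():
            perm = labels.copy()
            for idx in idx_by_stratum:
                perm[idx] = rng.permutation(perm[idx])
            return perm
    else:

        def draw():
            return rng.permutation(labels)

    exact = strata is None and _log_n_distinct_perms(labels) <= math.log(B)
    if exact:
        perms = _distinct_label_permutations(labels)
        count = np.zeros(Y.shape[1])
        for perm in perms:
            count += stat_for(np.asarray(perm)) >= t_obs - 1e-12
        pvals = count / len(perms)
    else:
        count = np.zeros(Y.shape[1])
        for _ in range(B):
            count += stat_for(draw()) >= t_obs - 1e-12
        pvals = (1.0 + count) / (B + 1.0)
    return pd.Series(pvals, index=cm.counts.index, name="p_perm")


def bh_adjust(p: pd.Series | np.ndarray) -> pd.Series:
    """Benjamini-Hochberg step-up q-values; missing entries propagate."""
    s = pd.Series(np.asarray(p, dtype=float)) if not isinstance(p, pd.Series) else p.astype(float)
    q = pd.Series(np.nan, index=s.index, name="q")
    mask = s.notna()
    if mask.any():
        q.loc[mask] = multipletests(s[mask].values, method="fdr_bh")[1]
    return q
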