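"""Signed weighted gene co-expression network analysis.

Builds a signed adjacency ``a_ij = ((1 + cor_ij)/2)^beta`` (so
anti-correlated genes get near-zero weight), converts it to the
topological overlap measure (TOM), detects modules by average-linkage
clustering of 1 - TOM with a static height cut, a minimum module size,
and iterative merging of modules with similar eigengenes, then relates
module eigengenes to sample traits and computes intramodular
connectivity for hub-gene ranking.

Module detection here uses a quantile-based static tree cut rather
than dynamic branch cutting; it is deterministic and recovers planted
block structure well, which is what the downstream priority scoring
requires.  Modules are named by the conventional color sequence in
descending size order, with "grey" reserved for unassigned genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

GREY = "grey"
_COLOR_SEQUENCE = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
    "darkolivegreen", "darkmagenta", "whitesmoke", "lightgrey",
]


@dataclass
class ModuleSet:
    """Gene-to-module assignment with eigengenes and network summaries."""

    assignment: pd.Series  # gene -> module label, "grey" = unassigned
    eigengenes: pd.DataFrame | None = None  # samples x modules, unit-norm columns
    kwithin: pd.Series | None = None
    module_trait: pd.DataFrame | None = None
    beta: int = 17
    merge_thresh: float = 0.2
    min_size: int = 30

    @property
    def modules(self) -> list:
        return [m for m in self.assignment.unique() if m != GREY]

    def genes_in(self, module: str) -> list:
        return list(self.assignment.index[self.assignment == module])


def signed_adjacency(expr: pd.DataFrame, beta: int = 17) -> pd.DataFrame:
    """Signed soft-threshold adjacency from gene x sample expression.

    ``a_ij = ((1 + cor(x_i, x_j))/2)^beta`` with Pearson correlation
    across samples; perfectly anti-correlated pairs map to 0, perfectly
    correlated pairs to 1.  Diagonal is set to 1.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    sds = expr.values.std(axis=1)
    zero_var = expr.index[sds == 0].tolist()
    if zero_var:
        raise ValueError(f"zero-variance genes: {zero_var[:10]}")
    cor = np.corrcoef(expr.values)
    a = np.clip((1.0 + cor) / 2.0, 0.0, 1.0) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix from a signed adjacency.

    ``TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) /
    (min(k_i, k_j) + 1 - a_ij)`` with ``k_i = sum_{u != i} a_iu``;
    diagonal 1.  Shared-neighbor weight makes hub-adjacent gene pairs
    more similar than their direct edge alone.
    """
    a = adj.values
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # with zeroed diagonal this is sum over u != i, j
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = num / den
    tom = np.where(den > 0, tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def module_eigengenes(expr: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    """First principal component of each module's standardized expression.

    Member genes are z-scored across samples; the eigengene is the
    leading right singular vector of the member x sample matrix (unit
    norm), sign-oriented so its mean correlation with member genes is
    non-negative.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples for eigengenes")
    cols = {}
    for module in sorted(set(assignment) - {GREY}):
        genes = assignment.index[assignment == module]
        sub = expr.loc[genes].values.astype(float)
        sd = sub.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        zs = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        _, _, vt = np.linalg.svd(zs, full_matrices=False)
        e = vt[0]
        orient = (zs @ e).sum()  # sum of cor(gene, eigengene) up to scale
        if orient < 0:
            e = -e
        cols[module] = e
    if not cols:
        raise ValueError("no non-grey modules")
    return pd.DataFrame(cols, index=expr.columns)


def detect_modules(
    tom: pd.DataFrame,
    expr: pd.DataFrame | None = None,
    min_size: int = 30,
    merge_thresh: float = 0.2,
    cut_quantile: float = 0.99,
    beta: int = 17,
    kme_min: float = 0.3,
) -> ModuleSet:
    """Cluster genes on 1 - TOM and merge similar modules.

    Average-linkage hierarchical clustering of the TOM dissimilarity is
    cut recursively: each branch splits at the highest height (capped
    at the ``cut_quantile`` quantile of merge heights) that produces at
    least two children of ``min_size``, and the recursion descends into
    the children.  Clusters smaller than ``min_size`` become grey.
    When ``expr`` is given, genes whose signed correlation with their
    module eigengene falls below ``kme_min`` are released to grey, and
    module pairs whose eigengene dissimilarity ``1 - cor(E_a, E_b)``
    falls below ``merge_thresh`` are merged iteratively (re-joining any
    over-splits from the recursion).  Surviving modules are named by
    descending size along the conventional color sequence.
    """
    d = 1.0 - tom.values
    np.fill_diagonal(d, 0.0)
    genes = tom.index
    n = len(genes)

    # Recursive top-down splitting: cut each branch at the highest height
    # that yields >= 2 children of valid size, then recurse into the
    # children.  Over-splitting is harmless because the eigengene-merge
    # pass below re-joins modules driven by the same underlying profile;
    # the recursion is what separates distinct blocks that a single
    # static cut would leave glued together.
    def split(idx: np.ndarray) -> list:
        if len(idx) < 2 * min_size:
            return [idx]
        sub = d[np.ix_(idx, idx)]
        link = hierarchy.linkage(squareform(sub, checks=False), method="average")
        heights = np.unique(link[:, 2])
        hi = float(np.quantile(link[:, 2], cut_quantile))
        best = None
        for h in heights[::-1]:
            if h > hi:
                continue
            lab = hierarchy.fcluster(link, t=h, criterion="distance")
            sizes = np.bincount(lab)[1:]
            if (sizes >= min_size).sum() >= 2:
                best = lab
                break
        if best is None:
            return [idx]
        out = []
        for c in np.unique(best):
            child = idx[best == c]
            if len(child) >= min_size:
                out.extend(split(child))
            else:
                out.append(child)  # fragment; greyed below
        return out

    labels = pd.Series(-1, index=genes)
    for j, cluster in enumerate(split(np.arange(n))):
        if len(cluster) >= min_size:
            labels.iloc[cluster] = j

    # membership filter: a gene stays in its module only if it tracks the
    # module eigengene (kME >= kme_min, signed); loosely attached genes go
    # grey, and modules falling under min_size dissolve
    if expr is not None and (labels != -1).any():
        assign = labels.map(lambda v: str(v) if v != -1 else GREY)
        eg = module_eigengenes(expr, assign)
        ev = expr.values
        sd = ev.std(axis=1, ddof=0)
        zs = (ev - ev.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)[:, None]
        for i, g in enumerate(genes):
            m = assign.iloc[i]
            if m == GREY:
                continue
            e = eg[m].values
            kme = float(zs[i] @ (e - e.mean())) / (
                len(e) * max(np.std(e), 1e-12)
            )
            if kme < kme_min:
                labels.iloc[i] = -1
        sizes = labels[labels != -1].value_counts()
        labels[labels.isin(sizes.index[sizes < min_size])] = -1

    if expr is not None and (labels != -1).any():
        while True:
            live = sorted(set(labels) - {-1})
            if len(live) < 2:
                break
            assign = labels.map(lambda v: str(v) if v != -1 else GREY)
            eg = module_eigengenes(expr, assign)
            cor = np.corrcoef(eg.values.T)
            diss = 1.0 - cor
            np.fill_diagonal(diss, np.inf)
            i, j = np.unravel_index(np.argmin(diss), diss.shape)
            if diss[i, j] >= merge_thresh:
                break
            a, b = int(eg.columns[i]), int(eg.columns[j])
            labels[labels == b] = a

    live = sorted(set(labels) - {-1})
    if not live:
        warnings.warn("all genes unassigned (grey)", stacklevel=2)
        assignment = pd.Series(GREY, index=genes, name="module")
        return ModuleSet(assignment=assignment, beta=beta, merge_thresh=merge_thresh, min_size=min_size)

    by_size = sorted(live, key=lambda v: (-int((labels == v).sum()), v))
    name_of = {v: _COLOR_SEQUENCE[i % len(_COLOR_SEQUENCE)] for i, v in enumerate(by_size)}
    assignment = labels.map(lambda v: name_of.get(v, GREY))
    assignment.name = "module"
    eig = module_eigengenes(expr, assignment) if expr is not None else None
    return ModuleSet(
        assignment=assignment, eigengenes=eig, beta=beta,
        merge_thresh=merge_thresh, min_size=min_size,
    )


def module_trait_correlation(eigengenes: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each eigengene with each trait column.

    Traits are numeric sample covariates (group one-hot indicators,
    binary sex, ...).  p-values come from the t reference with n - 2
    degrees of freedom; constant traits yield missing entries.
    Returns a long table (module, trait, r, p).
    """
    n = len(eigengenes)
    if n < 4:
        raise ValueError("need at least 4 samples for module-trait correlation")
    traits = traits.loc[eigengenes.index]
    rows = []
    for module in eigengenes.columns:
        e = eigengenes[module].values.astype(float)
        for trait in traits.columns:
            t = traits[trait].values.astype(float)
            if np.std(t) == 0 or np.std(e) == 0:
                rows.append((module, trait, np.nan, np.nan))
                continue
            r = float(np.corrcoef(e, t)[0, 1])
            rows.append((module, trait, r, correlation_pvalue(r, n)))
    return pd.DataFrame(rows, columns=["module", "trait", "r", "p"])


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson r at sample size n (t with n-2 df)."""
    if n < 3:
        raise ValueError("need n >= 3")
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def intramodular_connectivity(adj: pd.DataFrame, assignment: pd.Series) -> pd.Series:
    """Sum of a gene's adjacency to the other genes of its module.

    Grey (unassigned) genes get a missing value; a singleton module
    yields 0.
    """
    k = pd.Series(np.nan, index=adj.index, name="kwithin")
    for module in set(assignment) - {GREY}:
        genes = [g for g in adj.index if assignment.get(g) == module]
        sub = adj.loc[genes, genes].values
        k.loc[genes] = sub.sum(axis=1) - np.diag(sub)
    return k
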