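"""Hub-gene priority scoring, qPCR fold changes, stepwise validation.

Candidate genes for wet-lab validation are ranked within a
trait-correlated co-expression module by

    priority = -log10(adjusted P) * |log2(fold change)| * log10(kWithin)

combining differential-expression evidence with intramodular hubness.
Validation-side utilities compute 2^-ddCt relative expression from Ct
tables (housekeeping-normalized, referenced to a baseline group) and
run classic forward-entry / backward-removal stepwise linear
regression of a behavioral composite score on gene expression, with
F-to-enter and F-to-remove thresholds.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from escalade.de import DEResult
from escalade.wgcna import ModuleSet


@dataclass
class PriorityTable:
    """Ranked module genes with their score components."""

    table: pd.DataFrame  # gene-indexed: module, adjP, log2fc, kwithin, priority, rank
    module: str
    contrast: tuple


@dataclass
class StepwiseFit:
    """Stepwise regression outcome.

    ``selected`` lists predictors in entry order; ``coef`` includes the
    intercept; ``predicted`` pairs fitted with observed responses.
    """

    selected: list
    coef: pd.Series
    r2: float
    f_stat: float
    p: float
    predicted: pd.DataFrame
    history: list = field(default_factory=list)


def priority_score(adjP: float, log2fc: float, kwithin: float) -> float:
    """-log10(adjP) * |log2fc| * log10(kwithin).

    Zero whenever adjP = 1, log2fc = 0 or kwithin = 1; negative when
    kwithin < 1 (weakly connected genes rank below zero by design).
    """
    if not (0 < adjP <= 1):
        raise ValueError("adjP must lie in (0, 1]; floor exact zeros upstream")
    if kwithin <= 0:
        raise ValueError("kwithin must be > 0")
    return float(-np.log10(adjP) * abs(log2fc) * np.log10(kwithin))


def rank_module_genes(
    de: DEResult,
    modules: ModuleSet,
    module_name: str,
    p_column: str = "q",
) -> PriorityTable:
    """Priority-score and rank the genes of one module.

    Uses the module's intramodular connectivity together with the DE
    contrast's adjusted p-values and log2 fold changes.  Genes lacking
    DE statistics are excluded with a warning; adjusted p-values of
    exactly 0 are floored at the smallest positive float.  Ranks are
    descending by score with gene-id tie-break.
    """
    if module_name not in set(modules.assignment.values):
        raise ValueError(f"unknown module {module_name!r}")
    if modules.kwithin is None:
        raise ValueError("ModuleSet has no intramodular connectivity; compute kwithin first")
    genes = modules.genes_in(module_name)
    have = [g for g in genes if g in de.table.index and np.isfinite(de.table.loc[g, p_column])]
    dropped = sorted(set(genes) - set(have))
    if dropped:
        warnings.warn(f"{len(dropped)} module genes lack DE statistics; excluded", stacklevel=2)
    adjp = de.table.loc[have, p_column].astype(float).clip(lower=sys.float_info.min)
    if (de.table.loc[have, p_column] <= 0).any():
        warnings.warn("adjusted p-values of 0 floored at the smallest positive float", stacklevel=2)
    lfc = de.table.loc[have, "log2fc"].astype(float)
    kw = modules.kwithin.loc[have].astype(float)
    bad_k = kw[kw <= 0].index.tolist()
    if bad_k:
        raise ValueError(f"non-positive kwithin for genes {bad_k[:5]}")
    score = -np.log10(adjp) * lfc.abs() * np.log10(kw)
    table = pd.DataFrame(
        {
            "module": module_name,
            "adjP": adjp,
            "log2fc": lfc,
            "kwithin": kw,
            "priority": score,
        },
        index=pd.Index(have, name="gene"),
    )
    table = table.sort_values(["priority", "gene"], ascending=[False, True], kind="stable")
    table["rank"] = np.arange(1, len(table) + 1)
    return PriorityTable(table=table, module=module_name, contrast=de.contrast)


def ddct_fold_change(
    panel: pd.DataFrame,
    housekeeping: str = "Tbp",
    reference_group: int = 1,
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    ``panel`` is long-format (rat_id, group, gene, ct).  Per rat and
    gene, dCt = Ct_gene - Ct_housekeeping; ddCt subtracts the
    reference group's mean dCt for that gene; fold change is 2^-ddCt.
    Rats without a housekeeping measurement are excluded with a
    warning.  Returns a long table (rat_id, group, gene, fold_change).
    """
    hk = panel[panel["gene"] == housekeeping].set_index("rat_id")["ct"]
    targets = panel[panel["gene"] != housekeeping]
    missing = sorted(set(targets["rat_id"]) - set(hk.index))
    if missing:
        warnings.warn(f"rats without housekeeping Ct excluded: {missing[:5]}", stacklevel=2)
        targets = targets[~targets["rat_id"].isin(missing)]
    if targets.empty:
        raise ValueError("no target-gene measurements with housekeeping coverage")
    d = targets.copy()
    d["dct"] = d["ct"].values - hk.loc[d["rat_id"]].values
    ref = d[d["group"] == reference_group]
    if ref.empty:
        raise ValueError(f"reference group {reference_group} absent from qPCR panel")
    ref_mean = ref.groupby("gene")["dct"].mean()
    d["ddct"] = d["dct"] - d["gene"].map(ref_mean).values
    d["fold_change"] = np.exp2(-d["ddct"])
    return d[["rat_id", "group", "gene", "fold_change"]].reset_index(drop=True)


def _partial_f(rss_small: float, rss_big: float, df_diff: int, df_resid_big: int) -> float:
    gain = rss_small - rss_big
    if gain <= 1e-12 * max(1.0, rss_small):
        return 0.0
    if df_resid_big <= 0 or rss_big <= 1e-12 * max(1.0, rss_small):
        return np.inf
    return (gain / df_diff) / (rss_big / df_resid_big)


def _ols_rss(Xc: np.ndarray, y: np.ndarray):
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ beta
    return float(resid @ resid), beta


def stepwise_regression(
    X: pd.DataFrame,
    y: pd.Series,
    f_enter: float = 2.0,
    f_remove: float = 1.0,
    max_steps: int = 100,
) -> StepwiseFit:
    """Forward-entry / backward-removal stepwise OLS on partial F.

    Each cycle first considers entry — the excluded predictor with the
    largest partial F enters if that F >= ``f_enter`` — then removal —
    the included predictor with the smallest partial F leaves if that
    F < ``f_remove`` — until neither applies.  A predictor whose entry
    makes the design collinear is dropped again with a warning.
    Returns the final OLS fit with R^2, overall F and p, and the
    fitted-versus-observed pairs.
    """
    X = X.loc[y.index]
    n = len(y)
    yv = y.values.astype(float)
    cols = list(X.columns)
    selected: list = []
    history: list = []

    def design(sel):
        return np.column_stack([np.ones(n)] + [X[c].values.astype(float) for c in sel])

    rss_cur, _ = _ols_rss(design(selected), yv)
    for _ in range(max_steps):
        changed = False
        # entry
        candidates = [c for c in cols if c not in selected]
        best_c, best_f, best_rss = None, -np.inf, None
        for c in candidates:
            Xc = design(selected + [c])
            if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
                continue
            rss_new, _ = _ols_rss(Xc, yv)
            f = _partial_f(rss_cur, rss_new, 1, n - Xc.shape[1])
            if f > best_f:
                best_c, best_f, best_rss = c, f, rss_new
        if best_c is not None and best_f >= f_enter:
            selected.append(best_c)
            rss_cur = best_rss
            history.append(("enter", best_c, best_f))
            changed = True
        # removal
        if len(selected) > 0:
            worst_c, worst_f = None, np.inf
            Xfull = design(selected)
            rss_full, _ = _ols_rss(Xfull, yv)
            for c in selected:
                rest = [s for s in selected if s != c]
                rss_rest, _ = _ols_rss(design(rest), yv)
                f = _partial_f(rss_rest, rss_full, 1, n - Xfull.shape[1])
                if f < worst_f:
                    worst_c, worst_f = c, f
            if worst_c is not None and worst_f < f_remove:
                selected.remove(worst_c)
                rss_cur, _ = _ols_rss(design(selected), yv)
                history.append(("remove", worst_c, worst_f))
                changed = True
        if not changed:
            break

    Xf = design(selected)
    if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
        warnings.warn("collinear selected set; dropping the latest entrant", stacklevel=2)
        selected = selected[:-1]
        Xf = design(selected)
    rss, beta = _ols_rss(Xf, yv)
    tss = float(((yv - yv.mean()) ** 2).sum())
    k = len(selected)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    if k > 0 and n - k - 1 > 0 and rss > 0:
        f_stat = (r2 / k) / ((1 - r2) / (n - k - 1))
        p = float(stats.f.sf(f_stat, k, n - k - 1))
    else:
        f_stat, p = np.nan, np.nan
    fitted = Xf @ beta
    return StepwiseFit(
        selected=selected,
        coef=pd.Series(beta, index=["intercept"] + selected),
        r2=r2,
        f_stat=f_stat,
        p=p,
        predicted=pd.DataFrame({"predicted": fitted, "observed": yv}, index=y.index),
        history=history,
    )
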