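"""Progressive-ratio schedule math and behavioral summary scores.

Covers the antecedent-reward side of the pipeline: the exponential
progressive-ratio (PR) response requirement, standardization of sucrose
PR breakpoints into cohort z-scores, and two per-rat summaries of
self-administration behavior used to validate candidate genes — a
combined three-outcome z-score (reinforced minus futile plus inactive,
each standardized against a reference group, divided by 3) and the
first principal component of the same three window-averaged outcomes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from escalade.synthetic import OUTCOMES


@dataclass
class SucroseSummary:
    """Per-rat sucrose PR breakpoint means and cohort z-scores."""

    means: pd.Series
    overall_mean: float
    overall_sd: float
    z: pd.Series
    window: int


@dataclass
class BehaviorSummary:
    """Window-averaged outcomes and the combined z-score per rat.

    ``x`` holds per-rat averages of reinforced (X1), futile (X2) and
    inactive (X3) presses over the trailing window; ``ref_mean`` and
    ``ref_sd`` are the reference-group statistics used to standardize
    each outcome; ``z_total`` is the signed three-outcome composite.
    """

    x: pd.DataFrame
    ref_mean: pd.Series
    ref_sd: pd.Series
    z_total: pd.Series
    signs: tuple
    window: int


def pr_requirement(pellet_index: int) -> int:
    """Response requirement for the j-th reward on the exponential PR schedule.

    The requirement grows as ``round(5 e^(0.2 j) - 5)`` with a floor of
    one response, reproducing the canonical published ratio sequence
    1, 2, 4, 6, 9, 12, 15, 20, 25, 32, ...  Rounding is half away from
    zero to the nearest integer.
    """
    j = pellet_index
    if not float(j).is_integer() or j < 1:
        raise ValueError(f"pellet_index must be a positive integer, got {pellet_index}")
    raw = 5.0 * math.exp(0.2 * j) - 5.0
    return max(1, int(math.floor(raw + 0.5)))


def _window_means(df: pd.DataFrame, value_col: str, window: int) -> pd.Series:
    """Per-rat mean of `value_col` over each rat's last `window` days."""

    def tail_mean(g: pd.DataFrame) -> float:
        g = g.sort_values("day")
        return float(g[value_col].tail(window).mean())

    out = df.groupby("rat_id", sort=True).apply(tail_mean, include_groups=False)
    out.name = value_col
    return out


def breakpoint_zscores(breakpoints: pd.DataFrame, window: int = 3) -> SucroseSummary:
    """Standardize per-rat PR breakpoints against the cohort.

    ``breakpoints`` is long-format with columns ``rat_id, day,
    breakpoint``.  Each rat's breakpoint is averaged over its final
    `window` days; z-scores subtract the cohort mean of these averages
    and divide by the cohort sample standard deviation (n-1
    denominator).
    """
    required = {"rat_id", "day", "breakpoint"}
    if not required.issubset(breakpoints.columns):
        raise ValueError(f"breakpoints table needs columns {sorted(required)}")
    n_days = breakpoints.groupby("rat_id")["day"].count()
    if (n_days < window).any():
        raise ValueError(f"every rat needs >= {window} days of breakpoints")
    means = _window_means(breakpoints, "breakpoint", window)
    overall_mean = float(means.mean())
    overall_sd = float(means.std(ddof=1))
    if not np.isfinite(overall_sd) or overall_sd == 0:
        raise ValueError("overall breakpoint sd is zero; z-scores undefined")
    z = (means - overall_mean) / overall_sd
    z.name = "z_sucrose"
    return SucroseSummary(means=means, overall_mean=overall_mean, overall_sd=overall_sd, z=z, window=window)


def _outcome_window_matrix(panel: pd.DataFrame, window: int) -> pd.DataFrame:
    """Rats x outcomes matrix of trailing-window averages."""
    cols = {}
    for k, name in enumerate(OUTCOMES):
        sub = panel[panel["outcome"] == name]
        if sub.empty:
            raise ValueError(f"panel has no rows for outcome {name!r}")
        cols[name] = _window_means(sub, "value", window)
    return pd.DataFrame(cols)


def combined_zscore(
    panel: pd.DataFrame,
    groups: pd.Series,
    reference_group: int = 1,
    window: int = 7,
    signs: tuple = (1, -1, 1),
) -> BehaviorSummary:
    """Composite z-score of the three operant outcomes per rat.

    Each outcome X_k is averaged over the rat's last `window` sessions
    and standardized against the reference group's mean and sample sd;
    the composite is ``(z1 - z2 + z3)/3`` with the default signs
    (reinforced +, futile -, inactive +).

    ``groups`` maps rat_id to trajectory group; ``reference_group``
    names the group supplying the standardization statistics.
    """
    x = _outcome_window_matrix(panel, window)
    ref_rats = groups.index[groups == reference_group]
    ref_rats = [r for r in ref_rats if r in x.index]
    if len(ref_rats) == 0:
        raise ValueError(f"reference group {reference_group} is empty")
    ref = x.loc[ref_rats]
    ref_mean = ref.mean()
    ref_sd = ref.std(ddof=1)
    for name, sd in ref_sd.items():
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"reference-group sd is zero for outcome {name!r}")
    z = (x - ref_mean) / ref_sd
    s = np.asarray(signs, dtype=float)
    if s.shape != (3,):
        raise ValueError("signs must have length 3")
    z_total = (z.values @ s) / 3.0
    z_total = pd.Series(z_total, index=x.index, name="z_total")
    return BehaviorSummary(x=x, ref_mean=ref_mean, ref_sd=ref_sd, z_total=z_total, signs=tuple(signs), window=window)


def behavior_pc1(panel: pd.DataFrame, window: int = 7) -> pd.Series:
    """First principal component of the window-averaged outcomes.

    The three outcomes are standardized across rats (correlation-matrix
    PCA) and projected onto the leading eigenvector, with the sign
    oriented so that the score correlates positively with reinforced
    pressing.  A constant outcome column is dropped with a warning;
    fewer than two varying columns is an error.
    """
    x = _outcome_window_matrix(panel, window)
    if len(x) < 3:
        raise ValueError("behavior_pc1 requires at least 3 rats")
    sds = x.std(ddof=1)
    keep = [c for c in x.columns if np.isfinite(sds[c]) and sds[c] > 0]
    dropped = [c for c in x.columns if c not in keep]
    if dropped:
        warnings.warn(f"dropping constant outcome columns: {dropped}", stacklevel=2)
    if len(keep) < 2:
        raise ValueError("need at least 2 non-constant outcome columns for PCA")
    xs = (x[keep] - x[keep].mean()) / sds[keep]
    # SVD of the centered standardized matrix; first right singular vector
    u, s, vt = np.linalg.svd(xs.values, full_matrices=False)
    scores = xs.values @ vt[0]
    if keep[0] == OUTCOMES[0]:
        ref = xs[OUTCOMES[0]].values
    else:
        ref = xs[keep[0]].values
    c = float(np.dot(scores - scores.mean(), ref - ref.mean()))
    if c < 0 or (c == 0 and vt[0][0] < 0):
        scores = -scores
    return pd.Series(scores, index=x.index, name="pc1")
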