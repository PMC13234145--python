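"""Synthetic behavioral, count and qPCR data with known ground truth.

The generator emulates the structure of an extended-access opioid
self-administration study: each rat belongs to one of a small number of
latent trajectory groups, and three operant outcomes (reinforced,
futile and inactive presses) follow group-specific polynomial mean
trajectories with censored-normal noise.  Downstream, a bulk RNA-seq
count matrix carries planted co-expression modules whose latent factors
shift by trajectory group, and a qPCR Ct table carries planted fold
changes, so every analysis stage can be checked against ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

OUTCOMES = ("reinforced", "futile", "inactive")


class SimConfigError(ValueError):
    """A SimConfig field failed validation."""


def _default_poly_coefs() -> np.ndarray:
    # group x outcome x coefficient (intercept, slope, curvature), day 1 at t=0.
    # Reinforced presses on the raw count scale; futile/inactive on log(x+1).
    # Shapes chosen to mimic low / medium / high escalator phenotypes:
    # low ~ shallow linear, medium ~ steeper linear, high ~ steep with plateau.
    return np.array(
        [
            [[20.0, 2.0, 0.0], [1.5, 0.00, 0.0], [1.5, 0.05, 0.0]],
            [[30.0, 5.0, 0.0], [2.0, 0.05, 0.0], [1.2, 0.06, 0.0]],
            [[40.0, 18.0, -0.45], [2.5, 0.08, 0.0], [1.0, 0.00, 0.0]],
        ]
    )


@dataclass
class SimConfig:
    """Ground-truth parameters for the synthetic study.

    Parameters
    ----------
    n_rats, n_days, n_groups
        Cohort size, daily sessions per phase, number of latent
        trajectory groups.
    mixing
        Group membership probabilities, summing to 1.
    poly_coefs
        ``(n_groups, 3, order+1)`` mean-trajectory coefficients per
        group and outcome, on the modeling scale (log(x+1) for outcomes
        listed in ``log_outcomes``).  Day 1 is coded t = 0.
    noise_sd
        Per-outcome residual standard deviation on the modeling scale.
    censor_limits
        Per-outcome ``(lower, upper)`` recording bounds on the modeling
        scale; observations beyond a bound are recorded at the bound
        and flagged.
    log_outcomes
        Indices of outcomes simulated on the log(x+1) scale and
        back-transformed to integer counts.
    re_sd
        Per-outcome ``(order+1,)`` standard deviations of rat-level
        Gaussian deviations of the polynomial coefficients (latent
        growth curve random effects); zero by default.
    covariate_effect
        ``(order+1,)`` linear effect of the per-rat standard-normal
        covariate (sucrose z-score) on the reinforced-press
        coefficients.
    n_genes, n_modules, module_size
        Count-matrix dimensions and planted co-expression block size.
    module_shift
        ``(n_modules, n_groups)`` latent-factor offsets; a module whose
        offsets vary across groups yields planted DE genes.
    nb_dispersion
        Negative-binomial dispersion alpha (variance m + alpha m^2).
    lib_size_range
        Library-size factors drawn log-uniformly from this range.
    seed
        Root seed for all generators.
    """

    n_rats: int = 58
    n_days: int = 21
    n_groups: int = 3
    mixing: np.ndarray = field(default_factory=lambda: np.array([0.30, 0.42, 0.28]))
    poly_coefs: np.ndarray = field(default_factory=_default_poly_coefs)
    noise_sd: np.ndarray = field(default_factory=lambda: np.array([12.0, 0.5, 0.5]))
    censor_limits: tuple = ((0.0, 500.0), (0.0, 10.0), (0.0, 10.0))
    log_outcomes: frozenset = frozenset({1, 2})
    re_sd: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    covariate_effect: np.ndarray = field(default_factory=lambda: np.array([6.0, 0.0, 0.0]))
    n_genes: int = 2000
    n_modules: int = 3
    module_size: int = 60
    module_shift: np.ndarray | None = None
    nb_dispersion: float = 0.05
    lib_size_range: tuple = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self):
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.poly_coefs = np.asarray(self.poly_coefs, dtype=float)
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        self.re_sd = np.asarray(self.re_sd, dtype=float)
        self.covariate_effect = np.asarray(self.covariate_effect, dtype=float)
        if self.module_shift is None:
            # group-dependent shift on module 0 only: monotone in intake group
            shift = np.zeros((self.n_modules, self.n_groups))
            shift[0] = np.linspace(0.0, 2.0, self.n_groups)
            self.module_shift = shift
        self.module_shift = np.asarray(self.module_shift, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_rats < 1:
            raise SimConfigError("n_rats must be >= 1")
        if self.n_days < 1:
            raise SimConfigError("n_days must be >= 1")
        if self.mixing.shape != (self.n_groups,):
            raise SimConfigError("mixing must have length n_groups")
        if abs(self.mixing.sum() - 1.0) > 1e-12:
            raise SimConfigError("mixing must sum to 1 within 1e-12")
        if np.any(self.mixing < 0):
            raise SimConfigError("mixing entries must be non-negative")
        if self.poly_coefs.shape[:2] != (self.n_groups, 3):
            raise SimConfigError("poly_coefs must be (n_groups, 3, order+1)")
        if self.noise_sd.shape != (3,) or np.any(self.noise_sd < 0):
            raise SimConfigError("noise_sd must be 3 non-negative reals")
        if len(self.censor_limits) != 3 or any(lo >= hi for lo, hi in self.censor_limits):
            raise SimConfigError("censor_limits must be 3 pairs with lower < upper")
        if self.module_size < 2:
            raise SimConfigError("module_size must be >= 2")
        if self.module_shift.shape != (self.n_modules, self.n_groups):
            raise SimConfigError("module_shift must be (n_modules, n_groups)")
        if self.nb_dispersion < 0:
            raise SimConfigError("nb_dispersion must be >= 0")
        lo, hi = self.lib_size_range
        if not (0 < lo <= hi):
            raise SimConfigError("lib_size_range must be positive with min <= max")


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulation.

    ``group_labels`` are 1-based and indexed by rat id; ``covariate``
    holds the per-rat standard-normal sucrose z-score used for growth
    effects; ``latent_factors`` is a samples x modules matrix;
    ``de_genes`` the set of gene ids with a planted group effect;
    ``qpcr_true_fc`` maps (gene, group) to the planted fold change.
    """

    group_labels: pd.Series | None = None
    covariate: pd.Series | None = None
    module_genes: dict | None = None
    latent_factors: pd.DataFrame | None = None
    de_genes: set | None = None
    qpcr_true_fc: pd.DataFrame | None = None


def _rat_ids(n: int) -> list:
    return [f"R{i+1:03d}" for i in range(n)]


def simulate_behavior(cfg: SimConfig, phase: str = "escalation") -> tuple[pd.DataFrame, SimTruth]:
    """Draw a long-format behavior panel from the latent-group model.

    Each rat is assigned a group from ``cfg.mixing``; outcome *k* on day
    *t* (coded t = day-1) is ``poly_gk(t) + b_i(t) + c(t) z_i + eps`` on
    the modeling scale, where ``b_i`` are optional rat-level random
    coefficients and ``c(t) z_i`` applies only to the reinforced
    outcome.  Log-scale outcomes are back-transformed with
    ``exp(v) - 1``, floored at 0 and rounded to integer counts.
    Observations beyond a censor limit are recorded at the limit and
    flagged in the ``censored`` column.

    Returns
    -------
    panel : DataFrame
        Columns ``rat_id, sex, phase, day, outcome, value, censored``.
    truth : SimTruth
        Group labels and the per-rat covariate draw.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rats = _rat_ids(cfg.n_rats)
    groups = rng.choice(cfg.n_groups, size=cfg.n_rats, p=cfg.mixing) + 1
    sexes = np.where(np.arange(cfg.n_rats) % 2 == 0, "M", "F")
    rng.shuffle(sexes)
    z = rng.standard_normal(cfg.n_rats)

    order_p1 = cfg.poly_coefs.shape[2]
    t = np.arange(cfg.n_days, dtype=float)
    tpow = np.vander(t, order_p1, increasing=True)  # (days, order+1)

    rows = []
    for k, name in enumerate(OUTCOMES):
        lo, hi = cfg.censor_limits[k]
        coefs = cfg.poly_coefs[groups - 1, k, :]  # (rats, order+1)
        if cfg.re_sd.shape[1] >= order_p1:
            re = rng.standard_normal((cfg.n_rats, order_p1)) * cfg.re_sd[k, :order_p1]
        else:
            re = np.zeros((cfg.n_rats, order_p1))
        coefs = coefs + re
        if k == 0 and cfg.covariate_effect.size:
            ce = np.zeros(order_p1)
            ce[: min(order_p1, cfg.covariate_effect.size)] = cfg.covariate_effect[
                : min(order_p1, cfg.covariate_effect.size)
            ]
            coefs = coefs + z[:, None] * ce
        mu = coefs @ tpow.T  # (rats, days), modeling scale
        v = mu + rng.standard_normal((cfg.n_rats, cfg.n_days)) * cfg.noise_sd[k]
        censored = (v <= lo) | (v >= hi)
        v = np.clip(v, lo, hi)
        if k in cfg.log_outcomes:
            y = np.round(np.maximum(np.expm1(v), 0.0))
        else:
            y = np.round(np.maximum(v, 0.0))
        for i, rat in enumerate(rats):
            for d in range(cfg.n_days):
                rows.append((rat, sexes[i], phase, d + 1, name, y[i, d], bool(censored[i, d])))

    panel = pd.DataFrame(rows, columns=["rat_id", "sex", "phase", "day", "outcome", "value", "censored"])
    truth = SimTruth(
        group_labels=pd.Series(groups, index=pd.Index(rats, name="rat_id"), name="group"),
        covariate=pd.Series(z, index=pd.Index(rats, name="rat_id"), name="z_sucrose"),
    )
    return panel, truth


def simulate_counts(cfg: SimConfig, group_labels: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Draw a genes x samples count matrix with planted modules.

    Genes in module *m* load on a shared standard-normal latent factor
    whose mean is offset by ``cfg.module_shift[m, group-1]`` for each
    sample's trajectory group; background genes are independent.
    Counts follow a negative binomial with log-uniform library sizes
    and dispersion ``cfg.nb_dispersion`` (variance m + alpha m^2).

    Returns ``(counts, meta, truth)`` where ``counts`` is a genes x
    samples DataFrame, ``meta`` a per-sample table (sample_id, rat_id,
    group, sex), and ``truth`` records module membership, latent
    factors and the planted DE gene set.
    """
    cfg.validate()
    n_planted = cfg.n_modules * cfg.module_size
    if cfg.n_genes < n_planted:
        raise SimConfigError(
            f"n_genes={cfg.n_genes} cannot hold {cfg.n_modules} modules of size {cfg.module_size}"
        )
    rng = np.random.default_rng(cfg.seed + 1)
    samples = list(group_labels.index)
    n_s = len(samples)
    groups = np.asarray(group_labels.values, dtype=int)

    genes = [f"G{j+1:05d}" for j in range(cfg.n_genes)]
    module_genes = {
        m: genes[m * cfg.module_size : (m + 1) * cfg.module_size] for m in range(cfg.n_modules)
    }

    factors = rng.standard_normal((n_s, cfg.n_modules))
    factors = factors + cfg.module_shift.T[groups - 1, :]  # (samples, modules)

    log_base = rng.uniform(np.log(50.0), np.log(500.0), size=cfg.n_genes)
    loadings = rng.uniform(0.3, 0.6, size=cfg.n_genes)
    log_mu = np.tile(log_base[:, None], (1, n_s))
    for m in range(cfg.n_modules):
        sl = slice(m * cfg.module_size, (m + 1) * cfg.module_size)
        log_mu[sl, :] += loadings[sl, None] * factors[None, :, m][0]

    lo, hi = cfg.lib_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_s))
    mu = np.exp(log_mu) * lib[None, :]

    alpha = cfg.nb_dispersion
    if alpha > 0:
        # NB as gamma-Poisson: shape 1/alpha, scale alpha*mu
        lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    shifted = np.ptp(cfg.module_shift, axis=1) > 0
    de_genes: set = set()
    for m in range(cfg.n_modules):
        if shifted[m]:
            de_genes.update(module_genes[m])

    # expected expression ratio vs group 1, per gene and group: for a module
    # gene, E[expr | group j] / E[expr | group 1] = exp(loading * (shift_j -
    # shift_1)) since the factor variance is common to all groups
    group_ids = sorted(np.unique(groups))
    fc = np.ones((cfg.n_genes, len(group_ids)))
    for m in range(cfg.n_modules):
        sl = slice(m * cfg.module_size, (m + 1) * cfg.module_size)
        for j, gid in enumerate(group_ids):
            fc[sl, j] = np.exp(loadings[sl] * (cfg.module_shift[m, gid - 1] - cfg.module_shift[m, 0]))
    qpcr_true_fc = pd.DataFrame(fc, index=pd.Index(genes, name="gene"), columns=group_ids)

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "rat_id": samples,
            "group": groups,
            "sex": rng.choice(["M", "F"], size=n_s),
        }
    ).set_index("sample_id")
    truth = SimTruth(
        group_labels=group_labels,
        module_genes=module_genes,
        latent_factors=pd.DataFrame(
            factors, index=pd.Index(samples, name="sample_id"),
            columns=[f"module_{m}" for m in range(cfg.n_modules)],
        ),
        de_genes=de_genes,
        qpcr_true_fc=qpcr_true_fc,
    )
    return counts_df, meta, truth


def simulate_qpcr(
    cfg: SimConfig,
    group_labels: pd.Series,
    genes: list | None = None,
    true_fc: pd.DataFrame | None = None,
    housekeeping: str = "Tbp",
    ct_noise_sd: float = 0.15,
    plate_sd: float = 0.1,
    reference_group: int = 1,
) -> tuple[pd.DataFrame, SimTruth]:
    """Draw a qPCR Ct table consistent with planted fold changes.

    Ct for gene g in a rat of group j is ``baseline_g - log2(fc[g, j]) +
    noise``; the housekeeping gene's Ct does not depend on group, so the
    ddCt recipe recovers ``fc`` exactly in the noise-free limit.

    ``true_fc`` is a genes x groups table of fold changes relative to
    ``reference_group`` (column of ones there); by default a 2-fold
    increase in the top group is planted for every assay gene.
    """
    cfg.validate()
    labels = np.asarray(group_labels.values, dtype=int)
    n_groups = len(np.unique(labels))
    if n_groups < 2:
        raise SimConfigError("simulate_qpcr requires at least 2 groups")
    counts = pd.Series(labels).value_counts()
    if (counts < 3).any():
        warnings.warn("fewer than 3 replicates in some group", stacklevel=2)
    rng = np.random.default_rng(cfg.seed + 2)
    if genes is None:
        genes = ["Kcna2", "Kcnq3", "Kcnma1", "Kcnh7", "Grin2a", "Grin2b", "Slc1a2", "Erbb4", "Tnr"]
    group_ids = sorted(np.unique(labels))
    if true_fc is None:
        fc = np.ones((len(genes), len(group_ids)))
        fc[:, -1] = 2.0
        true_fc = pd.DataFrame(fc, index=pd.Index(genes, name="gene"), columns=group_ids)
    if (np.asarray(true_fc.values) <= 0).any():
        raise SimConfigError("planted fold changes must be > 0")

    baselines = rng.uniform(22.0, 30.0, size=len(genes))
    hk_baseline = 20.0
    rows = []
    for rat, grp in zip(group_labels.index, labels):
        plate = rng.normal(0.0, plate_sd) if plate_sd > 0 else 0.0  # rat-level plate offset
        for gi, g in enumerate(genes):
            ct = baselines[gi] - np.log2(true_fc.loc[g, grp]) + plate + rng.normal(0.0, ct_noise_sd)
            rows.append((rat, grp, g, ct))
        rows.append((rat, grp, housekeeping, hk_baseline + plate + rng.normal(0.0, ct_noise_sd)))
    panel = pd.DataFrame(rows, columns=["rat_id", "group", "gene", "ct"])
    truth = SimTruth(group_labels=group_labels, qpcr_true_fc=true_fc)
    return panel, truth
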