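"""Shared fixtures: small synthetic designs with known ground truth."""

import numpy as np
import pandas as pd
import pytest

from escalade import SimConfig, simulate_behavior


def separated_config(seed: int = 0, n_rats: int = 60) -> SimConfig:
    """Three trajectory groups with mean separation >= 5 sigma on every
    outcome, within the censor limits throughout the 21 days."""
    return SimConfig(
        seed=seed,
        n_rats=n_rats,
        n_groups=3,
        mixing=np.array([0.30, 0.40, 0.30]),
        poly_coefs=np.array(
            [
                [[50.0, 1.0, 0.0], [1.5, 0.0, 0.0], [1.2, 0.0, 0.0]],
                [[150.0, 1.0, 0.0], [4.0, 0.0, 0.0], [3.5, 0.0, 0.0]],
                [[250.0, 1.0, 0.0], [6.5, 0.0, 0.0], [6.0, 0.0, 0.0]],
            ]
        ),
        noise_sd=np.array([12.0, 0.35, 0.35]),
        covariate_effect=np.zeros(3),
    )


def lgcm_config(seed: int = 0, n_rats: int = 60, c0: float = 0.0) -> SimConfig:
    """Single-group cohort with Gaussian rat-level random coefficients —
    exactly the latent growth curve generative model; the covariate acts
    on the day-1 level with strength c0."""
    return SimConfig(
        seed=seed,
        n_rats=n_rats,
        n_groups=1,
        mixing=np.array([1.0]),
        poly_coefs=np.array([[[50.0, 5.0, -0.1], [1.5, 0.0, 0.0], [1.5, 0.0, 0.0]]]),
        noise_sd=np.array([8.0, 0.4, 0.4]),
        re_sd=np.array([[10.0, 1.0, 0.03], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]]),
        covariate_effect=np.array([c0, 0.0, 0.0]),
    )


def planted_expression(seed: int = 0, n_samples: int = 24, n_genes: int = 600,
                       block: int = 60, noise_sd: float = 0.3, shift=(0.0, 1.0, 2.0)):
    """Gaussian expression with three planted factor blocks; block 0's
    factor mean shifts with the sample group (8/8/8 design by default).
    Returns (expr, truth_labels, factors, groups)."""
    rng = np.random.default_rng(seed)
    groups = np.repeat([1, 2, 3], n_samples // 3)
    f = rng.standard_normal((3, n_samples))
    f[0] += np.asarray(shift)[groups - 1]
    X = rng.standard_normal((n_genes, n_samples)) * noise_sd
    truth = np.full(n_genes, -1)
    for m in range(3):
        X[m * block:(m + 1) * block] += f[m]
        truth[m * block:(m + 1) * block] = m
    expr = pd.DataFrame(
        X, index=[f"g{i:04d}" for i in range(n_genes)],
        columns=[f"s{i:02d}" for i in range(n_samples)],
    )
    return expr, truth, f, groups


@pytest.fixture
def behavior_panel_small():
    cfg = SimConfig(seed=42, n_rats=20, covariate_effect=np.zeros(3))
    panel, truth = simulate_behavior(cfg)
    return panel, truth


def make_panel(values: dict, outcomes=("reinforced", "futile", "inactive")) -> pd.DataFrame:
    """Hand-built long panel: values[rat] = {outcome: [day values]}."""
    rows = []
    for rat, per_outcome in values.items():
        for name in outcomes:
            for d, v in enumerate(per_outcome[name], start=1):
                rows.append((rat, "F", "escalation", d, name, float(v), False))
    return pd.DataFrame(
        rows, columns=["rat_id", "sex", "phase", "day", "outcome", "value", "censored"]
    )
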