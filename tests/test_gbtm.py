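"""Censored-normal trajectory mixture: likelihood, EM, selection, crosstab."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from escalade import (
    TrajModelSpec,
    censored_normal_loglik,
    crosstab_exact_test,
    fit_gbtm,
    select_groups,
    simulate_behavior,
)
from conftest import separated_config


class TestCensoredNormalLoglik:
    def test_mass_at_upper_equal_mean_is_half(self):
        # y = upper = mu: log P(Y >= upper) = log(1 - Phi(0)) = log 0.5
        assert censored_normal_loglik(5.0, 5.0, 1.0, 0.0, 5.0) == pytest.approx(np.log(0.5), abs=1e-12)

    def test_infinite_bounds_match_normal_density(self):
        for y, mu, s in [(0.3, 0.0, 1.0), (-2.0, 1.0, 2.5), (10.0, 9.0, 0.3)]:
            got = censored_normal_loglik(y, mu, s)
            assert got == pytest.approx(stats.norm.logpdf(y, mu, s), abs=1e-10)

    def test_upper_tail_one_sigma(self):
        # y at the limit with mu one sd below: log(1 - Phi(1))
        got = censored_normal_loglik(10.0, 9.0, 1.0, -np.inf, 10.0)
        assert got == pytest.approx(np.log(0.15865525393145707), abs=1e-10)

    def test_lower_tail(self):
        got = censored_normal_loglik(0.0, 1.0, 1.0, 0.0, np.inf)
        assert got == pytest.approx(stats.norm.logcdf(-1.0), abs=1e-10)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            censored_normal_loglik(11.0, 0.0, 1.0, 0.0, 10.0)
        with pytest.raises(ValueError):
            censored_normal_loglik(1.0, 0.0, 0.0, 0.0, 10.0)  # sigma <= 0

    def test_vectorized_matches_scalar(self):
        y = np.array([0.0, 2.5, 10.0])
        got = censored_normal_loglik(y, 2.0, 1.5, 0.0, 10.0)
        exp = [censored_normal_loglik(v, 2.0, 1.5, 0.0, 10.0) for v in y]
        assert np.allclose(got, exp)


def _no_censor_spec(**kw):
    kw.setdefault("censor", ((-1e9, 1e9),) * 3)
    kw.setdefault("log_transform", (False, False, False))
    return TrajModelSpec(**kw)


class TestFitGbtm:
    def test_single_group_order_zero_closed_form(self):
        panel, _ = simulate_behavior(separated_config(seed=1, n_rats=30))
        spec = _no_censor_spec(n_groups=1, poly_order=(0, 0, 0), n_starts=1, seed=0)
        fit = fit_gbtm(panel, spec)
        r = panel[panel.outcome == "reinforced"].value
        assert fit.coefs[0][0, 0] == pytest.approx(r.mean(), abs=1e-6)
        assert fit.sigma[0] == pytest.approx(r.std(ddof=0), rel=1e-4)

    def test_planted_groups_recovered(self):
        cfg = separated_config(seed=2, n_rats=60)
        panel, truth = simulate_behavior(cfg)
        spec = TrajModelSpec(n_groups=3, n_starts=2, seed=0)
        fit = fit_gbtm(panel, spec)
        acc = (fit.assignment.values == truth.group_labels.values).mean()
        assert acc >= 0.95
        assert (fit.posterior.sum(axis=1) - 1).abs().max() < 1e-8

    def test_duplicating_every_rat_preserves_parameters(self):
        cfg = separated_config(seed=4, n_rats=30)
        panel, _ = simulate_behavior(cfg)
        dup = panel.copy()
        dup["rat_id"] = dup["rat_id"] + "_copy"
        both = pd.concat([panel, dup], ignore_index=True)
        spec = TrajModelSpec(n_groups=3, n_starts=2, seed=0)
        f1 = fit_gbtm(panel, spec)
        f2 = fit_gbtm(both, spec)
        assert np.allclose(f1.pi, f2.pi, atol=1e-3)
        for k in range(3):
            assert np.allclose(f1.coefs[k], f2.coefs[k], atol=0.05 * (1 + np.abs(f1.coefs[k])).max())

    def test_em_loglik_monotone(self):
        panel, _ = simulate_behavior(separated_config(seed=5, n_rats=40))
        spec = TrajModelSpec(n_groups=3, n_starts=1, seed=1)
        fit = fit_gbtm(panel, spec)
        trace = np.array(fit.loglik_trace)
        assert (np.diff(trace) >= -1e-8 * np.abs(trace[:-1])).all()

    def test_groups_ordered_by_reinforced_intake(self):
        panel, _ = simulate_behavior(separated_config(seed=6, n_rats=45))
        fit = fit_gbtm(panel, TrajModelSpec(n_groups=3, n_starts=2, seed=0))
        t = np.arange(21, dtype=float)
        T = np.vander(t, fit.coefs[0].shape[1], increasing=True)
        intake = (fit.coefs[0] @ T.T).mean(axis=1)
        assert (np.diff(intake) > 0).all()

    def test_censored_cells_handled(self):
        # push group means against the reinforced cap so censoring engages
        cfg = separated_config(seed=7, n_rats=30)
        cfg.poly_coefs[2, 0, 0] = 495.0
        cfg.poly_coefs[2, 0, 1] = 0.0
        panel, truth = simulate_behavior(cfg)
        assert panel[panel.outcome == "reinforced"].censored.any()
        fit = fit_gbtm(panel, TrajModelSpec(n_groups=3, n_starts=2, seed=0))
        assert np.isfinite(fit.loglik)
        acc = (fit.assignment.values == truth.group_labels.values).mean()
        assert acc >= 0.9

    def test_too_few_rats_rejected(self):
        panel, _ = simulate_behavior(separated_config(seed=8, n_rats=2))
        with pytest.raises(ValueError):
            fit_gbtm(panel, TrajModelSpec(n_groups=3))


class TestSelectGroups:
    def test_loglik_non_decreasing_in_g(self):
        panel, _ = simulate_behavior(separated_config(seed=9, n_rats=45))
        table, chosen, _ = select_groups(panel, TrajModelSpec(n_starts=2, seed=0), [1, 2, 3])
        ll = table["loglik"].values
        assert (np.diff(ll) >= -1e-4 * np.abs(ll[:-1])).all()

    def test_g1_matches_pooled_fit(self):
        panel, _ = simulate_behavior(separated_config(seed=10, n_rats=30))
        spec = TrajModelSpec(n_groups=1, n_starts=1, seed=0)
        pooled = fit_gbtm(panel, spec)
        table, _, fits = select_groups(panel, spec, [1])
        assert fits[1].loglik == pytest.approx(pooled.loglik, abs=1e-6)

    def test_empty_range_rejected(self):
        panel, _ = simulate_behavior(separated_config(seed=11, n_rats=20))
        with pytest.raises(ValueError):
            select_groups(panel, TrajModelSpec(), [])


class TestCrosstabExactTest:
    def test_perfect_diagonal_2x2(self):
        a = pd.Series([1] * 5 + [2] * 5, index=range(10))
        b = pd.Series([1] * 5 + [2] * 5, index=range(10))
        res = crosstab_exact_test(a, b, min_group_n=1)
        assert res.p == pytest.approx(1 / 126, rel=1e-9)

    def test_balanced_2x2_p_one(self):
        a = pd.Series([1, 1, 1, 1, 2, 2, 2, 2], index=range(8))
        b = pd.Series([1, 2, 1, 2, 1, 2, 1, 2], index=range(8))
        res = crosstab_exact_test(a, b, min_group_n=1)
        assert res.p == pytest.approx(1.0)

    def test_small_groups_excluded(self):
        a = pd.Series([1] * 5 + [2] * 5 + [3] * 2, index=range(12))
        b = pd.Series([1, 2] * 6, index=range(12))
        res = crosstab_exact_test(a, b, min_group_n=3)
        assert 3 not in res.table.index
        assert res.table.values.sum() == 10

    def test_single_margin_level_rejected(self):
        a = pd.Series([1] * 8, index=range(8))
        b = pd.Series([1, 2] * 4, index=range(8))
        with pytest.raises(ValueError):
            crosstab_exact_test(a, b, min_group_n=1)

    def test_enumeration_matches_chi2_ordering_3x3(self):
        # strong diagonal association must give a small exact p
        rng = np.random.default_rng(0)
        labels = np.repeat([1, 2, 3], 10)
        a = pd.Series(labels, index=range(30))
        noisy = labels.copy()
        flip = rng.random(30) < 0.2
        noisy[flip] = rng.integers(1, 4, flip.sum())
        b = pd.Series(noisy, index=range(30))
        res = crosstab_exact_test(a, b, min_group_n=1)
        assert res.method in ("exact_enumeration", "monte_carlo")
        assert res.p < 0.01

    def test_null_rejection_rate_is_valid(self):
        # independent assignments: exact test should reject at most ~alpha
        rng = np.random.default_rng(1)
        rejections = 0
        reps = 200
        for _ in range(reps):
            a = pd.Series(rng.integers(1, 3, 24), index=range(24))
            b = pd.Series(rng.integers(1, 3, 24), index=range(24))
            try:
                res = crosstab_exact_test(a, b, min_group_n=1)
            except ValueError:
                continue
            rejections += res.p <= 0.05
        rate = rejections / reps
        assert 0.005 <= rate <= 0.08

    def test_monte_carlo_reports_se(self):
        rng = np.random.default_rng(2)
        a = pd.Series(rng.integers(1, 5, 120), index=range(120))
        b = pd.Series(rng.integers(1, 5, 120), index=range(120))
        res = crosstab_exact_test(a, b, min_group_n=1, n_mc=2000, enumeration_cap=1000)
        assert res.method == "monte_carlo"
        assert res.se is not None and 0 < res.se < 0.05


class TestRankTestByGroup:
    def test_matches_scipy_kruskal(self):
        from escalade.gbtm import rank_test_by_group
        rng = np.random.default_rng(0)
        z = pd.Series(rng.standard_normal(30), index=range(30))
        g = pd.Series(rng.integers(1, 4, 30), index=range(30))
        stat, p = rank_test_by_group(z, g)
        groups = [z[g == k].values for k in sorted(g.unique())]
        expect = stats.kruskal(*groups)
        assert stat == pytest.approx(expect.statistic)
        assert p == pytest.approx(expect.pvalue)

    def test_shifted_group_detected(self):
        from escalade.gbtm import rank_test_by_group
        rng = np.random.default_rng(1)
        z = pd.Series(np.concatenate([rng.normal(0, 1, 15), rng.normal(3, 1, 15)]),
                      index=range(30))
        g = pd.Series([1] * 15 + [2] * 15, index=range(30))
        assert rank_test_by_group(z, g)[1] < 0.001

    def test_single_group_rejected(self):
        from escalade.gbtm import rank_test_by_group
        z = pd.Series([1.0, 2.0, 3.0], index=range(3))
        g = pd.Series([1, 1, 1], index=range(3))
        with pytest.raises(ValueError):
            rank_test_by_group(z, g)
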