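"""Signed network construction, TOM, module detection, trait correlation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from escalade import (
    detect_modules,
    intramodular_connectivity,
    module_eigengenes,
    module_trait_correlation,
    signed_adjacency,
    tom_similarity,
)
from escalade.wgcna import GREY, correlation_pvalue
from conftest import planted_expression


def _corr_pair(r: float, n: int = 50, seed: int = 0) -> pd.DataFrame:
    """Two genes with exact sample correlation r (Gram-Schmidt)."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    a = (a - a.mean()) / a.std()
    b = b - b.mean()
    b -= (b @ a) / (a @ a) * a
    b = b / b.std()
    y = r * a + np.sqrt(1 - r * r) * b
    return pd.DataFrame([a, y], index=["g1", "g2"],
                        columns=[f"s{i}" for i in range(n)])


class TestSignedAdjacency:
    def test_endpoints_of_signed_map(self):
        expr = _corr_pair(1.0 - 1e-15)
        a = signed_adjacency(expr, beta=17)
        assert a.loc["g1", "g2"] == pytest.approx(1.0, abs=1e-10)
        expr2 = pd.DataFrame([expr.iloc[0], -expr.iloc[0]], index=["g1", "g2"])
        a2 = signed_adjacency(expr2, beta=17)
        assert a2.loc["g1", "g2"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_correlation_soft_power(self):
        a = signed_adjacency(_corr_pair(0.0), beta=17)
        assert a.loc["g1", "g2"] == pytest.approx(0.5**17, rel=1e-9)

    def test_beta_one_half_correlation(self):
        a = signed_adjacency(_corr_pair(0.5), beta=1)
        assert a.loc["g1", "g2"] == pytest.approx(0.75, abs=1e-10)

    def test_zero_variance_gene_rejected(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "g2"])
        with pytest.raises(ValueError, match="flat"):
            signed_adjacency(expr)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            signed_adjacency(pd.DataFrame([[1.0, 2.0], [2.0, 1.0]]))


class TestTomSimilarity:
    def test_two_gene_network_equals_adjacency(self):
        for t in (0.1, 0.5, 0.9):
            adj = pd.DataFrame([[1.0, t], [t, 1.0]], index=["a", "b"], columns=["a", "b"])
            tom = tom_similarity(adj)
            assert tom.loc["a", "b"] == pytest.approx(t, abs=1e-12)

    def test_identity_adjacency_is_identity(self):
        adj = pd.DataFrame(np.eye(5))
        tom = tom_similarity(adj)
        assert np.allclose(tom.values, np.eye(5))

    def test_bounds_and_symmetry_on_random_networks(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((15, 10))
            a = ((1 + np.corrcoef(x)) / 2) ** 4
            np.fill_diagonal(a, 1.0)
            tom = tom_similarity(pd.DataFrame(a)).values
            assert tom.min() >= -1e-12 and tom.max() <= 1 + 1e-12
            assert np.allclose(tom, tom.T)
            assert np.allclose(np.diag(tom), 1.0)

    def test_asymmetric_rejected(self):
        adj = pd.DataFrame([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(adj)


class TestDetectModules:
    def test_planted_blocks_recovered(self):
        expr, truth, _, _ = planted_expression(seed=1)
        adj = signed_adjacency(expr, beta=17)
        mods = detect_modules(tom_similarity(adj), expr, min_size=30)
        lab = mods.assignment.values
        planted = truth >= 0
        assert adjusted_rand_score(truth[planted], lab[planted]) >= 0.9

    def test_small_block_goes_grey(self):
        rng = np.random.default_rng(2)
        n_s = 20
        f = rng.standard_normal(n_s)
        X = rng.standard_normal((80, n_s)) * 1.5  # background, no structure
        X[:10] = f + rng.standard_normal((10, n_s)) * 0.1
        expr = pd.DataFrame(X, index=[f"g{i}" for i in range(80)])
        mods = detect_modules(tom_similarity(signed_adjacency(expr, beta=6)),
                              expr, min_size=30)
        assert (mods.assignment.iloc[:10] == GREY).all()

    def test_shared_factor_blocks_merge(self):
        rng = np.random.default_rng(3)
        n_s = 24
        f = rng.standard_normal(n_s)
        X = np.vstack([
            f + rng.standard_normal((40, n_s)) * 0.2,
            f + rng.standard_normal((40, n_s)) * 0.2,
            rng.standard_normal((120, n_s)),
        ])
        expr = pd.DataFrame(X, index=[f"g{i}" for i in range(200)])
        mods = detect_modules(tom_similarity(signed_adjacency(expr, beta=6)),
                              expr, min_size=30, merge_thresh=0.2)
        blocks = mods.assignment.iloc[:80]
        assert blocks.nunique() == 1 and blocks.iloc[0] != GREY

    def test_gene_order_invariance_up_to_renaming(self):
        expr, truth, _, _ = planted_expression(seed=4, n_genes=300, block=50)
        tom = tom_similarity(signed_adjacency(expr, beta=6))
        m1 = detect_modules(tom, expr, min_size=30)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(expr))
        expr2 = expr.iloc[perm]
        m2 = detect_modules(tom_similarity(signed_adjacency(expr2, beta=6)), expr2, min_size=30)
        a1 = m1.assignment.sort_index()
        a2 = m2.assignment.sort_index()
        both = (a1 != GREY) & (a2 != GREY)
        assert adjusted_rand_score(a1[both], a2[both]) >= 0.95


class TestModuleEigengenes:
    def test_identical_genes_reproduce_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.0])
        expr = pd.DataFrame(np.tile(profile, (8, 1)), index=[f"g{i}" for i in range(8)])
        assign = pd.Series("m1", index=expr.index)
        eg = module_eigengenes(expr, assign)
        r = np.corrcoef(eg["m1"], profile)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)
        assert r > 0  # oriented along the member genes

    def test_planted_factor_recovered(self):
        rng = np.random.default_rng(5)
        f = rng.standard_normal(30)
        expr = pd.DataFrame(f + rng.standard_normal((40, 30)) * 0.1,
                            index=[f"g{i}" for i in range(40)])
        eg = module_eigengenes(expr, pd.Series("m1", index=expr.index))
        assert abs(np.corrcoef(eg["m1"], f)[0, 1]) >= 0.9

    def test_sign_convention_survives_global_flip(self):
        rng = np.random.default_rng(6)
        f = rng.standard_normal(20)
        expr = pd.DataFrame(f + rng.standard_normal((10, 20)) * 0.2,
                            index=[f"g{i}" for i in range(10)])
        assign = pd.Series("m1", index=expr.index)
        e1 = module_eigengenes(expr, assign)["m1"]
        e2 = module_eigengenes(-expr, assign)["m1"]
        # orientation is to the members: flipped members flip the eigengene
        assert np.corrcoef(e1, e2)[0, 1] == pytest.approx(-1.0, abs=1e-8)

    def test_unit_norm_columns(self):
        expr, _, _, _ = planted_expression(seed=7, n_genes=200, block=50)
        assign = pd.Series(GREY, index=expr.index)
        assign.iloc[:50] = "m1"
        eg = module_eigengenes(expr, assign)
        assert np.linalg.norm(eg["m1"]) == pytest.approx(1.0, abs=1e-10)

    def test_single_sample_rejected(self):
        expr = pd.DataFrame([[1.0], [2.0]], index=["a", "b"])
        with pytest.raises(ValueError):
            module_eigengenes(expr, pd.Series("m1", index=expr.index))


class TestModuleTraitCorrelation:
    def test_eigengene_equal_to_trait(self):
        rng = np.random.default_rng(8)
        e = rng.standard_normal(24)
        eg = pd.DataFrame({"m1": e}, index=[f"s{i}" for i in range(24)])
        traits = pd.DataFrame({"t": e}, index=eg.index)
        out = module_trait_correlation(eg, traits)
        assert out.r.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_printed_r_p_pairing_at_n24(self):
        # the t reference reproduces the published (R, p) pairing
        assert correlation_pvalue(0.5522, 24) == pytest.approx(0.005, abs=5e-4)
        assert correlation_pvalue(0.5418, 24) == pytest.approx(0.006, abs=8e-4)
        assert correlation_pvalue(0.4837, 24) == pytest.approx(0.017, abs=2e-3)

    def test_constant_trait_reported_missing(self):
        rng = np.random.default_rng(9)
        eg = pd.DataFrame({"m1": rng.standard_normal(10)}, index=range(10))
        traits = pd.DataFrame({"flat": np.ones(10)}, index=range(10))
        out = module_trait_correlation(eg, traits)
        assert np.isnan(out.r.iloc[0]) and np.isnan(out.p.iloc[0])

    def test_orthogonal_trait_mostly_insignificant(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            e = rng.standard_normal(24)
            t = rng.standard_normal(24)
            t -= (t @ (e - e.mean())) / ((e - e.mean()) @ (e - e.mean())) * (e - e.mean()) * 0
            out = module_trait_correlation(
                pd.DataFrame({"m": e}, index=range(24)),
                pd.DataFrame({"t": t}, index=range(24)),
            )
            hits += out.p.iloc[0] <= 0.05
        assert hits <= 3  # >= 90% insignificant

    def test_too_few_samples_rejected(self):
        eg = pd.DataFrame({"m": [1.0, 2.0, 1.5]}, index=range(3))
        with pytest.raises(ValueError):
            module_trait_correlation(eg, pd.DataFrame({"t": [0, 1, 0]}, index=range(3)))


class TestIntramodularConnectivity:
    def test_singleton_module_zero(self):
        adj = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        assign = pd.Series(["m1", GREY, GREY], index=list("abc"))
        k = intramodular_connectivity(adj, assign)
        assert k["a"] == 0.0
        assert np.isnan(k["b"])

    def test_three_gene_module_hand_value(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        adj = pd.DataFrame(a, index=list("abc"), columns=list("abc"))
        k = intramodular_connectivity(adj, pd.Series("m1", index=list("abc")))
        assert np.allclose(k.values, 1.0)

    def test_outside_genes_do_not_contribute(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((6, 20))
        a = ((1 + np.corrcoef(x)) / 2) ** 2
        np.fill_diagonal(a, 1.0)
        adj = pd.DataFrame(a, index=list("abcdef"), columns=list("abcdef"))
        assign = pd.Series(["m1"] * 3 + ["m2"] * 3, index=list("abcdef"))
        k_full = intramodular_connectivity(adj, assign)
        k_sub = intramodular_connectivity(adj.iloc[:3, :3], assign.iloc[:3])
        assert np.allclose(k_full.iloc[:3].values, k_sub.values)
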