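import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from coexnet import wgcna
from coexnet.wgcna import (
    WGCNA,
    cluster_modules,
    correlation_pvalue,
    module_eigengene,
    module_eigengenes,
    module_trait_relationships,
    pearson_correlation,
    pick_soft_threshold,
    scale_free_fit,
    soft_adjacency,
    tom_similarity,
    trait_design,
)
from oracles import pearson_bruteforce, tom_bruteforce


def block_tom(sizes, within, between, seed=None):
    """Block-structured matrix with unit diagonal, as a TOM stand-in."""
    n = sum(sizes)
    t = np.full((n, n), between)
    start = 0
    for s in sizes:
        t[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(t, 1.0)
    idx = [f"g{i}" for i in range(n)]
    return pd.DataFrame(t, index=idx, columns=idx)


class TestPearson:
    def test_perfect_and_anti_correlation(self):
        x = pd.DataFrame([[1, 2, 3], [2, 4, 6], [3, 2, 1]], index=["a", "b", "c"])
        r = pearson_correlation(x)
        assert np.isclose(r.loc["a", "b"], 1.0)
        assert np.isclose(r.loc["a", "c"], -1.0)

    def test_matches_two_pass_oracle(self, rng):
        x = pd.DataFrame(rng.normal(size=(50, 8)))
        r = pearson_correlation(x)
        assert np.allclose(r.to_numpy(), pearson_bruteforce(x.to_numpy()), atol=1e-12)

    def test_zero_variance_gene_named(self):
        x = pd.DataFrame([[1, 2, 3], [5, 5, 5]], index=["ok", "flat"])
        with pytest.raises(ValueError, match="flat"):
            pearson_correlation(x)


class TestSoftAdjacency:
    def test_power_examples(self):
        r = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]])
        assert np.isclose(soft_adjacency(r, 10).iloc[0, 1], 0.34867844)
        rneg = pd.DataFrame([[1.0, -1.0], [-1.0, 1.0]])
        for beta in (1, 5, 12):
            assert soft_adjacency(rneg, beta).iloc[0, 1] == 1.0
        assert (soft_adjacency(r, 1) == r.abs()).all().all()

    def test_mean_connectivity_decreasing_in_power(self, filtered_expression):
        r = pearson_correlation(filtered_expression.iloc[:100])
        ks = [
            wgcna.connectivity(soft_adjacency(r, b)).mean() for b in (1, 2, 4, 8, 16)
        ]
        assert all(k1 > k2 for k1, k2 in zip(ks, ks[1:]))


class TestScaleFreeFit:
    def test_exact_power_law_degree_sequence(self):
        # frequencies halve as degree doubles: log-log slope -1, R^2 = 1
        degrees = [8] + [4] * 2 + [2] * 4 + [1] * 8
        g = nx.havel_hakimi_graph(degrees)
        a = pd.DataFrame(nx.to_numpy_array(g))
        np.fill_diagonal(a.values, 1.0)
        signed_r2, slope = scale_free_fit(a)
        assert np.isclose(signed_r2, 1.0)
        assert np.isclose(slope, -1.0)

    def test_uniform_connectivity_is_degenerate(self):
        a = pd.DataFrame(np.full((5, 5), 0.5))
        np.fill_diagonal(a.values, 1.0)
        with pytest.raises(ValueError, match="degenerate"):
            scale_free_fit(a)

    def test_increasing_frequency_gives_negative_signed_r2(self):
        # one low-degree node, many interconnected high-degree nodes
        g = nx.complete_graph(10)
        g.add_edge(0, 10)
        a = pd.DataFrame(nx.to_numpy_array(g))
        np.fill_diagonal(a.values, 1.0)
        signed_r2, slope = scale_free_fit(a)
        assert slope > 0
        assert signed_r2 < 0


class TestPickSoftThreshold:
    def test_smallest_power_reaching_cut_is_chosen(self, filtered_expression):
        x = filtered_expression.iloc[:150]
        for cut in (0.0, 0.3):
            report = pick_soft_threshold(x, powers=tuple(range(1, 11)), r2_cut=cut)
            reaching = report.table.loc[report.table["signed_r2"] >= cut, "power"]
            if len(reaching):
                assert report.reached_cut
                assert report.power == reaching.iloc[0]

    def test_report_contents_and_fallback_flag(self, filtered_expression):
        x = filtered_expression.iloc[:120]
        report = pick_soft_threshold(x, powers=(1, 2, 3), r2_cut=0.999)
        assert list(report.table["power"]) == [1, 2, 3]
        assert set(report.table.columns) >= {
            "power", "signed_r2", "slope", "mean_k", "median_k", "max_k",
        }
        if not report.reached_cut:
            best = report.table.loc[report.table["signed_r2"].idxmax(), "power"]
            assert report.power == best

    def test_deterministic_on_simulated_data(self, filtered_expression):
        r1 = pick_soft_threshold(filtered_expression)
        r2 = pick_soft_threshold(filtered_expression.copy())
        assert r1.power == r2.power
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_rejects_unsorted_powers(self, filtered_expression):
        with pytest.raises(ValueError, match="ascending"):
            pick_soft_threshold(filtered_expression.iloc[:50], powers=(3, 2))


class TestTOM:
    def test_two_gene_network_reduces_to_adjacency(self):
        a = pd.DataFrame([[1.0, 0.37], [0.37, 1.0]])
        t = tom_similarity(a)
        assert np.isclose(t.iloc[0, 1], 0.37)

    def test_three_gene_hand_value(self):
        a = pd.DataFrame(np.full((3, 3), 0.5))
        np.fill_diagonal(a.values, 1.0)
        t = tom_similarity(a)
        off = t.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.5)  # (0.25 + 0.5) / (1 + 1 - 0.5)

    def test_matches_triple_loop_oracle_and_bounds(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 12))
            a = rng.uniform(size=(n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            t = tom_similarity(pd.DataFrame(a)).to_numpy()
            assert np.allclose(t, tom_bruteforce(a), atol=1e-12)
            assert (t >= 0).all() and (t <= 1 + 1e-12).all()
            assert np.allclose(t, t.T)


class TestClusterModules:
    def test_two_clean_blocks_named_by_size(self):
        t = block_tom([45, 40], within=0.8, between=0.01)
        labels = cluster_modules(t, min_module_size=35)
        counts = labels.value_counts()
        assert counts["turquoise"] == 45
        assert counts["blue"] == 40

    def test_blocks_below_min_size_are_grey(self):
        t = block_tom([30, 30], within=0.8, between=0.01)
        labels = cluster_modules(t, min_module_size=35)
        assert (labels == "grey").all()

    def test_min_size_exceeding_gene_count_errors(self):
        t = block_tom([10], within=0.8, between=0.0)
        with pytest.raises(ValueError, match="exceeds"):
            cluster_modules(t, min_module_size=35)

    def test_deterministic(self, filtered_expression):
        x = filtered_expression.iloc[:200]
        t = tom_similarity(soft_adjacency(pearson_correlation(x), 10))
        l1 = cluster_modules(t)
        l2 = cluster_modules(t.copy())
        assert (l1 == l2).all()


class TestEigengene:
    def test_identical_profiles_rank_one(self, rng):
        profile = rng.normal(size=10)
        x = pd.DataFrame([profile] * 5, index=[f"g{i}" for i in range(5)])
        e = module_eigengene(x, x.index)
        assert np.isclose(abs(np.corrcoef(e, profile)[0, 1]), 1.0)
        assert np.isclose(np.linalg.norm(e), 1.0)

    def test_sign_oriented_to_mean_profile(self, rng):
        x = pd.DataFrame(rng.normal(size=(6, 12)), index=[f"g{i}" for i in range(6)])
        e = module_eigengene(x, x.index)
        assert np.corrcoef(e, x.mean(axis=0))[0, 1] >= 0

    def test_first_pc_beats_any_single_member(self, rng):
        """Variance explained by the eigengene direction is maximal."""
        x = pd.DataFrame(rng.normal(size=(8, 15)), index=[f"g{i}" for i in range(8)])
        sub = x.to_numpy()
        z = (sub - sub.mean(1, keepdims=True)) / sub.std(1, ddof=1, keepdims=True)
        e = module_eigengene(x, x.index).to_numpy()
        var_e = ((z @ e) ** 2).sum()
        for i in range(8):
            d = z[i] / np.linalg.norm(z[i])
            assert var_e >= ((z @ d) ** 2).sum() - 1e-9

    def test_missing_member_errors(self, rng):
        x = pd.DataFrame(rng.normal(size=(3, 5)), index=["a", "b", "c"])
        with pytest.raises(KeyError, match="zzz"):
            module_eigengene(x, ["a", "zzz"])


class TestModuleTrait:
    @pytest.mark.parametrize(
        "r,lo,hi",
        [(0.46, 0.003, 0.005), (0.34, 0.035, 0.045), (0.36, 0.025, 0.035)],
    )
    def test_printed_correlation_pvalue_pairs(self, r, lo, hi):
        """n=36 module-trait correlations round to the published p-values."""
        assert lo <= correlation_pvalue(r, 36) <= hi

    def test_perfect_correlation_floors_not_crashes(self):
        p = correlation_pvalue(1.0, 36)
        assert 0 < p <= np.finfo(float).tiny

    def test_constant_indicator_reported_missing(self, rng):
        e = pd.DataFrame({"turquoise": rng.normal(size=8)}, index=range(8))
        design = pd.DataFrame({"ct_0h": np.ones(8), "ss_0h": [1, 0, 0, 1, 0, 1, 0, 0]}, index=range(8))
        out = module_trait_relationships(e, design)
        flat = out.set_index("trait")
        assert np.isnan(flat.loc["ct_0h", "r"])
        assert np.isfinite(flat.loc["ss_0h", "p"])

    def test_indicator_recovered_exactly(self, rng):
        d = np.tile([1.0, 0, 0], 4)
        e = pd.DataFrame({"m": d + 1e-9 * rng.normal(size=12)}, index=range(12))
        design = pd.DataFrame({"grp": d}, index=range(12))
        out = module_trait_relationships(e, design)
        assert out["r"].iloc[0] > 0.999
        assert out["p"].iloc[0] < 1e-8

    def test_trait_design_layout(self, sim_data):
        _, sheet, _ = sim_data
        design = trait_design(sheet)
        assert design.shape == (36, 12)
        assert list(design.columns)[:2] == ["ct_0h", "ct_3h"]
        assert list(design.columns)[-1] == "ss_48h"
        assert (design.sum(axis=0) == 3).all()  # 3 replicates per cell


@pytest.fixture(scope="module")
def fitted(filtered_expression):
    return WGCNA(power=10).fit(filtered_expression.T)


class TestWGCNAEstimator:
    def test_fitted_attributes(self, fitted, filtered_expression):
        n = filtered_expression.shape[0]
        assert fitted.power_ == 10
        assert fitted.labels_.shape == (n,)
        assert fitted.tom_.shape == (n, n)
        assert set(fitted.modules_) == set(fitted.eigengenes_.columns)
        assert all(len(g) >= 35 for g in fitted.modules_.values())

    def test_transform_reproduces_training_eigengenes(self, fitted, filtered_expression):
        scores = fitted.transform(filtered_expression.T)
        for m in fitted.modules_:
            c = np.corrcoef(scores[m], fitted.eigengenes_[m])[0, 1]
            assert np.isclose(abs(c), 1.0, atol=1e-8)

    def test_sklearn_protocol(self):
        est = WGCNA(power=6, min_module_size=20)
        cloned = clone(est)
        assert cloned.get_params()["min_module_size"] == 20
        cloned.set_params(r2_cut=0.85)
        assert cloned.r2_cut == 0.85
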