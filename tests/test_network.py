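"""Effect vectors, Spearman network, permutation null and clustering."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glyconet import network as net


@pytest.fixture(scope="module")
def lead_vectors(small_sim, called_loci):
    leads = [l.lead_snp for l in called_loci["loci"]]
    return net.build_effect_vectors(
        leads, small_sim["meta"], excluded_traits=sorted(small_sim["truth"].derived_parent)
    )


class TestEffectVectors:
    def test_z_is_beta_over_se(self):
        meta = pd.DataFrame(
            {
                "snp": ["rs1"] * 4,
                "trait_id": ["t1", "t2", "t3", "t4"],
                "beta": [0.2, 0.0, -0.1, 0.4],
                "se": [0.1, 0.1, 0.05, 0.2],
            }
        )
        vec = net.build_effect_vectors(["rs1"], meta)
        assert vec.loc["rs1", "t1"] == pytest.approx(2.0)
        assert vec.loc["rs1", "t2"] == 0.0

    def test_excluded_traits_absent(self, lead_vectors, small_sim):
        assert lead_vectors.shape[1] == 62
        assert not set(small_sim["truth"].derived_parent) & set(lead_vectors.columns)

    def test_missing_trait_is_hard_error(self):
        meta = pd.DataFrame(
            {"snp": ["rs1", "rs2"], "trait_id": ["t1", "t1"], "beta": [1, 1], "se": [1, 1]}
        )
        meta = pd.concat(
            [meta, pd.DataFrame({"snp": ["rs1"], "trait_id": ["t2"], "beta": [1], "se": [1]})]
        )
        with pytest.raises(net.NetworkError, match="rs2.*t2"):
            net.build_effect_vectors(["rs1", "rs2"], meta)


class TestSpearmanEdge:
    def test_identity(self):
        v = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        assert net.spearman_edge(v, v)["rho"] == pytest.approx(1.0)

    def test_antisymmetry(self):
        v = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        e = net.spearman_edge(v, -v)
        assert e["rho"] == pytest.approx(-1.0)
        assert e["abs_rho"] == pytest.approx(1.0)

    def test_hand_computed_rho(self):
        # d^2 sum = 4 -> rho = 1 - 6*4/(4*15) = 0.6
        e = net.spearman_edge([1, 2, 3, 4], [2, 1, 4, 3])
        assert e["rho"] == pytest.approx(0.6)

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(50):
            v1 = rng.integers(0, 5, size=12).astype(float)
            v2 = rng.integers(0, 5, size=12).astype(float)
            if np.all(v1 == v1[0]) or np.all(v2 == v2[0]):
                continue
            expected = stats.spearmanr(v1, v2)
            got = net.spearman_edge(v1, v2)
            assert got["rho"] == pytest.approx(expected.statistic, abs=1e-12)
            assert got["p"] == pytest.approx(expected.pvalue, abs=1e-10)

    def test_degenerate_vector_rejected(self):
        with pytest.raises(net.NetworkError, match="degenerate"):
            net.spearman_edge([1, 1, 1, 1], [1, 2, 3, 4])

    def test_exact_permutation_p_small_n(self):
        e_t = net.spearman_edge([1, 2, 3, 4, 5], [1, 3, 2, 5, 4], method="exact")
        # exact p for rho=0.8 at n=5: 16/120 orderings reach |rho| >= 0.8
        assert e_t["p"] == pytest.approx(16 / 120, abs=1e-12)


class TestBuildNetwork:
    def test_pair_count(self, lead_vectors):
        edges = net.build_network(lead_vectors)
        n = len(lead_vectors)
        assert len(edges) == n * (n - 1) // 2

    def test_two_vectors_one_edge(self):
        vec = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 10)))
        assert len(net.build_network(vec)) == 1

    def test_symmetry_under_row_reversal(self, lead_vectors):
        fwd = net.build_network(lead_vectors)
        rev = net.build_network(lead_vectors.iloc[::-1])
        key = lambda df: {
            frozenset((a, b)): r for a, b, r in df[["snp_a", "snp_b", "rho"]].itertuples(index=False)
        }
        f, r = key(fwd), key(rev)
        assert f.keys() == r.keys()
        for k in f:
            assert f[k] == pytest.approx(r[k], abs=1e-12)

    def test_single_vector_rejected(self, lead_vectors):
        with pytest.raises(net.NetworkError):
            net.build_network(lead_vectors.iloc[:1])


class TestPruning:
    def test_all_insignificant_empty(self):
        edges = pd.DataFrame({"snp_a": ["a"], "snp_b": ["b"], "rho": [0.1], "abs_rho": [0.1], "p": [1.0]})
        assert len(net.prune_network(edges)) == 0

    def test_threshold_reported(self, lead_vectors):
        edges = net.build_network(lead_vectors)
        pruned = net.prune_network(edges, alpha=0.05)
        assert pruned.attrs["threshold"] == pytest.approx(0.05 / len(edges))

    def test_monotone_in_alpha(self, lead_vectors):
        edges = net.build_network(lead_vectors)
        strict = net.prune_network(edges, alpha=0.01)
        loose = net.prune_network(edges, alpha=0.10)
        assert len(strict) <= len(loose)

    def test_zero_noise_within_cluster_edges_retained(
        self, lead_vectors, small_sim, called_loci
    ):
        truth = small_sim["truth"]
        pruned = net.prune_network(net.build_network(lead_vectors))
        kept = {frozenset((a, b)) for a, b in pruned[["snp_a", "snp_b"]].itertuples(index=False)}
        cluster_of = {
            s: truth.locus_cluster[truth.snp_locus[s]] for s in lead_vectors.index
        }
        snps = list(lead_vectors.index)
        for i, a in enumerate(snps):
            for b in snps[i + 1 :]:
                if cluster_of[a] == cluster_of[b]:
                    assert frozenset((a, b)) in kept


class TestPermutationPool:
    def test_toy_hand_count(self):
        table = pd.DataFrame(
            {
                "snp": [f"s{i}" for i in range(10)],
                "min_p": [0.5] * 5 + [1e-6, 1e-7] + [0.5] * 3,
            }
        )
        pool, prov = net.build_permutation_pool(table, ["s0", "s1", "s2"])
        assert prov == {
            "initial": 10,
            "after_locus_removal": 7,
            "n_p_filtered": 2,
            "final": 5,
        }
        assert len(pool) == 5

    def test_identity_when_nothing_filtered(self):
        table = pd.DataFrame({"snp": ["a", "b"], "min_p": [0.5, 0.9]})
        pool, prov = net.build_permutation_pool(table, [])
        assert pool == ["a", "b"]
        assert prov["initial"] == prov["final"] == 2

    def test_empty_pool_is_failure(self):
        table = pd.DataFrame({"snp": ["a"], "min_p": [1e-9]})
        with pytest.raises(net.NetworkError, match="empty"):
            net.build_permutation_pool(table, [])


@pytest.fixture(scope="module")
def pools():
    rng = np.random.default_rng(5)
    top = pd.DataFrame(rng.normal(size=(4, 20)), index=list("abcd"))
    pool = pd.DataFrame(rng.normal(size=(50, 20)), index=[f"n{i}" for i in range(50)])
    return top, pool


class TestPermutationNull:

    def test_same_seed_identical(self, pools):
        top, pool = pools
        a = net.permutation_null(top, pool, k=30, seed=7)
        b = net.permutation_null(top, pool, k=30, seed=7)
        for snp in a:
            np.testing.assert_array_equal(a[snp], b[snp])

    def test_k_exceeding_pool_rejected(self, pools):
        top, pool = pools
        with pytest.raises(net.NetworkError, match="exceeds pool"):
            net.permutation_null(top, pool, k=100, seed=1)

    def test_exhaustive_k_order_independent(self, pools):
        top, pool = pools
        a = net.permutation_null(top, pool, k=len(pool), seed=1)
        b = net.permutation_null(top, pool.sample(frac=1.0, random_state=9), k=len(pool), seed=2)
        for snp in a:
            np.testing.assert_allclose(a[snp], b[snp], atol=1e-12)

    def test_shared_sample_reused_across_top_snps(self, pools):
        top, pool = pools
        nulls = net.permutation_null(top, pool, k=30, seed=3)
        assert all(len(v) == 30 for v in nulls.values())


class TestNullQuantile:
    def test_observation_above_all(self):
        assert net.null_quantile(0.99, np.linspace(0, 0.5, 100)) == 0.0

    def test_observation_below_all(self):
        assert net.null_quantile(0.0, np.linspace(0.1, 0.5, 100)) == 1.0

    def test_median_of_101_values(self):
        null = np.linspace(0, 1, 101)
        # 51 of 101 values are >= the median value
        assert net.null_quantile(null[50], null) == pytest.approx(51 / 101)

    def test_empty_null_rejected(self):
        with pytest.raises(net.NetworkError):
            net.null_quantile(0.5, np.array([]))


class TestClustering:
    def test_identical_rows_merge_at_zero(self):
        mat = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        mat.loc["a", "b"] = mat.loc["b", "a"] = 1.0
        mat.loc["a", "a"] = mat.loc["b", "b"] = 1.0
        res = net.cluster_loci(mat, k=2)
        assert res.linkage[0, 2] == pytest.approx(0.0)
        assert res.labels["a"] == res.labels["b"] != res.labels["c"]

    def test_merge_heights_non_decreasing(self, lead_vectors):
        edges = net.build_network(lead_vectors)
        mat = net.correlation_matrix(edges, list(lead_vectors.index))
        res = net.cluster_loci(mat, k=3)
        heights = res.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_single_locus_trivial_tree(self):
        mat = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
        res = net.cluster_loci(mat, k=1)
        assert list(res.labels) == [1]

    def test_asymmetric_matrix_rejected(self):
        mat = pd.DataFrame([[1.0, 0.2], [0.5, 1.0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(net.NetworkError, match="symmetric"):
            net.cluster_loci(mat)


class TestExport:
    def test_round_trip(self, tmp_path):
        edges = pd.DataFrame(
            {
                "snp_a": ["a", "a", "b"],
                "snp_b": ["b", "c", "c"],
                "rho": [0.9, -0.5, 0.3],
                "abs_rho": [0.9, 0.5, 0.3],
                "p": [1e-6, 1e-3, 0.2],
            }
        )
        gml = tmp_path / "net.graphml"
        tsv = tmp_path / "net.tsv"
        net.export_network(edges, {s: {"locus": s.upper()} for s in "abc"}, gml, tsv)
        G = nx.read_graphml(gml)
        assert G.number_of_edges() == 3
        assert G.edges["a", "b"]["rho2"] == pytest.approx(0.81)
        assert G.nodes["a"]["locus"] == "A"
        back = pd.read_csv(tsv, sep="\t")
        assert back["rho2"].iloc[0] == pytest.approx(0.81)

    def test_empty_network_valid(self, tmp_path):
        edges = pd.DataFrame(columns=["snp_a", "snp_b", "rho", "abs_rho", "p"])
        gml = tmp_path / "empty.graphml"
        G = net.export_network(edges, {}, gml)
        assert nx.read_graphml(gml).number_of_edges() == 0


class TestDerivedTraitEffect:
    def test_including_derived_traits_inflates_null_correlation(self, small_sim):
        """Derived traits are rank-copies of their parents, so keeping them
        double-counts those coordinates and inflates |rho| between unrelated
        SNPs — the reason they are excluded before network construction."""
        meta = small_sim["meta"]
        truth = small_sim["truth"]
        null_snps = [s for s in truth.snp_meta["snp"] if s.startswith("rsbg")][:150]
        with_derived = net.build_effect_vectors(null_snps, meta)
        without = net.build_effect_vectors(
            null_snps, meta, excluded_traits=sorted(truth.derived_parent)
        )
        assert with_derived.shape[1] == 77 and without.shape[1] == 62
        e_with = net.build_network(with_derived)["abs_rho"].mean()
        e_without = net.build_network(without)["abs_rho"].mean()
        assert e_with > e_without
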