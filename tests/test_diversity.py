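import io

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

import coremicro as cm
from conftest import random_count_table


class TestAlpha:
    def test_chao1_bias_corrected_hand_example(self):
        t = cm.CountTable(list("abcd"), ["s"], np.array([[4], [1], [1], [2]]))
        out = cm.alpha_diversity(t)
        # S_obs = 4, F1 = 2, F2 = 1 -> 4 + 2*1/(2*2) = 4.5
        assert out["chao1"].iloc[0] == pytest.approx(4.5)

    def test_shannon_uniform(self):
        t = cm.CountTable(list("abcd"), ["s"], np.full((4, 1), 10))
        assert cm.alpha_diversity(t)["shannon"].iloc[0] == pytest.approx(np.log(4))

    def test_simpson_two_even(self):
        t = cm.CountTable(list("ab"), ["s"], np.array([[5], [5]]))
        assert cm.alpha_diversity(t)["simpson"].iloc[0] == pytest.approx(0.5)

    def test_matches_skbio(self):
        from skbio.diversity.alpha import chao1, shannon, simpson

        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, size=(12, 4))
        counts[0] += 1
        t = cm.CountTable(
            [f"o{i}" for i in range(12)], [f"s{j}" for j in range(4)], counts
        )
        out = cm.alpha_diversity(t)
        for j, sid in enumerate(t.sample_ids):
            col = counts[:, j]
            assert out.loc[sid, "chao1"] == pytest.approx(chao1(col, bias_corrected=True))
            assert out.loc[sid, "shannon"] == pytest.approx(shannon(col, base=np.e))
            assert out.loc[sid, "simpson"] == pytest.approx(simpson(col))

    def test_invariant_bounds(self):
        rng = np.random.default_rng(1)
        t = random_count_table(rng, n_otus=15, n_samples=6)
        out = cm.alpha_diversity(t)
        richness = (t.counts > 0).sum(axis=0)
        assert (out["chao1"].to_numpy() >= richness - 1e-9).all()
        assert (out["shannon"].to_numpy() <= np.log(richness) + 1e-9).all()
        assert out["simpson"].between(0, 1).all()

    def test_chao1_refused_on_fractional_table(self):
        t = cm.CountTable(["a", "b"], ["s"], np.array([[3], [1]]))
        rel = cm.tss(t)
        assert "chao1" not in cm.alpha_diversity(rel).columns


class TestDistances:
    def test_bray_curtis_hand_example(self):
        t = cm.CountTable(["a", "b"], ["x", "y"], np.array([[6, 2], [2, 2]]))
        assert cm.bray_curtis(t)["x", "y"] == pytest.approx(1 / 3)

    def test_identical_samples_zero(self):
        t = cm.CountTable(["a", "b"], ["x", "y"], np.array([[3, 3], [1, 1]]))
        assert cm.bray_curtis(t)["x", "y"] == 0.0
        assert cm.euclidean(t)["x", "y"] == 0.0

    def test_disjoint_supports_bc_one(self):
        t = cm.CountTable(["a", "b"], ["x", "y"], np.array([[5, 0], [0, 9]]))
        assert cm.bray_curtis(t)["x", "y"] == pytest.approx(1.0)

    def test_all_zero_sample_errors(self):
        t = cm.CountTable(["a"], ["x", "y"], np.array([[5, 0]]))
        with pytest.raises(ValueError, match="all-zero"):
            cm.bray_curtis(t)

    def test_oracle_equivalence_naive_double_loop(self):
        rng = np.random.default_rng(2)
        t = random_count_table(rng, n_otus=6, n_samples=6)
        bc = cm.bray_curtis(t)
        eu = cm.euclidean(t)
        X = t.counts.astype(float)
        for i in range(6):
            for j in range(6):
                num = np.abs(X[:, i] - X[:, j]).sum()
                den = (X[:, i] + X[:, j]).sum()
                assert abs(bc.data[i, j] - num / den) < 1e-12
                assert abs(eu.data[i, j] - np.sqrt(((X[:, i] - X[:, j]) ** 2).sum())) < 1e-12


class TestWeightedUnifrac:
    @pytest.fixture
    def three_leaf_tree(self):
        return TreeNode.read(io.StringIO("((A:1,B:1):1,C:2);"))

    def test_disjoint_hand_example(self, three_leaf_tree):
        t = cm.CountTable(["A", "B", "C"], ["x", "y"], np.array([[10, 0], [0, 0], [0, 10]]))
        assert cm.weighted_unifrac(t, three_leaf_tree, normalised=False)["x", "y"] == pytest.approx(4.0)
        assert cm.weighted_unifrac(t, three_leaf_tree, normalised=True)["x", "y"] == pytest.approx(1.0)

    def test_identical_samples_zero(self, three_leaf_tree):
        t = cm.CountTable(["A", "B", "C"], ["x", "y"], np.array([[4, 4], [2, 2], [1, 1]]))
        assert cm.weighted_unifrac(t, three_leaf_tree)["x", "y"] == pytest.approx(0.0)

    def test_branch_length_scaling(self, three_leaf_tree):
        t = cm.CountTable(["A", "B", "C"], ["x", "y"], np.array([[9, 1], [0, 3], [1, 6]]))
        doubled = three_leaf_tree.copy()
        for node in doubled.traverse(include_self=False):
            node.length *= 2
        raw1 = cm.weighted_unifrac(t, three_leaf_tree, normalised=False)["x", "y"]
        raw2 = cm.weighted_unifrac(t, doubled, normalised=False)["x", "y"]
        norm1 = cm.weighted_unifrac(t, three_leaf_tree, normalised=True)["x", "y"]
        norm2 = cm.weighted_unifrac(t, doubled, normalised=True)["x", "y"]
        assert raw2 == pytest.approx(2 * raw1)
        assert norm2 == pytest.approx(norm1)

    def test_star_tree_is_half_l1(self):
        star = TreeNode.read(io.StringIO("(A:1,B:1,C:1,D:1);"))
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 30, size=(4, 3))
        t = cm.CountTable(list("ABCD"), ["x", "y", "z"], counts)
        raw = cm.weighted_unifrac(t, star, normalised=False)
        props = counts / counts.sum(axis=0)
        for i in range(3):
            for j in range(3):
                l1 = np.abs(props[:, i] - props[:, j]).sum()
                assert abs(raw.data[i, j] - l1) < 1e-12  # unit branches: raw = L1

    def test_matches_skbio_on_random_trees(self):
        from skbio.diversity import beta_diversity

        tree = cm.generate_tree(14, seed=9)
        ids = cm.leaf_names(tree)
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 40, size=(14, 5))
        counts[0] += 1
        t = cm.CountTable(ids, [f"s{i}" for i in range(5)], counts)
        for normalised in (False, True):
            mine = cm.weighted_unifrac(t, tree, normalised=normalised)
            ref = beta_diversity(
                "weighted_unifrac", counts.T, ids=t.sample_ids, taxa=ids,
                tree=tree, normalized=normalised,
            )
            assert np.abs(mine.data - ref.data).max() < 1e-12

    def test_missing_otu_errors(self, three_leaf_tree):
        t = cm.CountTable(["A", "Z"], ["x", "y"], np.array([[1, 2], [3, 4]]))
        with pytest.raises(KeyError, match="Z"):
            cm.weighted_unifrac(t, three_leaf_tree)


class TestPcoa:
    def test_euclidean_input_recovered_exactly(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(8, 2))
        ids = [f"s{i}" for i in range(8)]
        d = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        res = cm.pcoa(d, k=2)
        rec = squareform(pdist(res.coordinates.to_numpy()))
        assert np.abs(rec - d.data).max() < 1e-9

    def test_collinear_points_on_one_axis(self):
        d = DistanceMatrix(
            np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]]),
            ids=list("abc"),
        )
        res = cm.pcoa(d, k=2)
        x = res.coordinates["PC1"].to_numpy()
        for i in range(3):
            for j in range(3):
                assert abs(abs(x[i] - x[j]) - d.data[i, j]) < 1e-9

    def test_zero_matrix_gives_zero_coordinates(self):
        d = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        res = cm.pcoa(d, k=2)
        assert np.allclose(res.coordinates.to_numpy(), 0.0)

    def test_proportions_non_increasing_and_bounded(self):
        rng = np.random.default_rng(6)
        t = random_count_table(rng, n_otus=10, n_samples=7)
        res = cm.pcoa(cm.bray_curtis(t))
        pos = res.proportion_explained
        assert (np.diff(pos) <= 1e-12).all()
        assert pos.sum() <= 1 + 1e-9


class TestPermanova:
    def test_exhaustive_separable_case(self):
        d = np.ones((6, 6))
        d[:3, :3] = 0
        d[3:, 3:] = 0
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])
        meta = pd.DataFrame({"sample_id": dm.ids, "grp": ["a"] * 3 + ["b"] * 3})
        res = cm.permanova(dm, meta, ["grp"], n_perm="exact")
        assert res.loc[res["term"] == "grp", "p_value"].iloc[0] == pytest.approx(2 / 20)
        assert np.isinf(res.loc[res["term"] == "grp", "pseudo_F"].iloc[0])

    def test_exact_enumeration_matches_monte_carlo_limit(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(6, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(6)])
        meta = pd.DataFrame({"sample_id": dm.ids, "grp": ["a", "a", "a", "b", "b", "b"]})
        exact = cm.permanova(dm, meta, ["grp"], n_perm="exact")
        mc = cm.permanova(dm, meta, ["grp"], n_perm=9999, seed=0)
        p_exact = exact["p_value"].iloc[0]
        p_mc = mc["p_value"].iloc[0]
        assert abs(p_exact - p_mc) < 0.03

    def test_r2_partition_identity(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(16, 4))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(16)])
        meta = pd.DataFrame(
            {
                "sample_id": dm.ids,
                "study": list(np.repeat(["u", "v"], 8)),
                "grp": list(np.tile(["a", "b"], 8)),
            }
        )
        res = cm.permanova(dm, meta, ["study", "grp"], n_perm=49, seed=1)
        r2 = res.loc[res["term"] != "Total", "R2"].sum()
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_matches_vegan_adonis2_sequential(self):
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(12, 5))
        dm = DistanceMatrix(squareform(pdist(Y)), ids=[f"s{i}" for i in range(12)])
        meta = pd.DataFrame(
            {
                "sample_id": dm.ids,
                "grp": ["a"] * 4 + ["b"] * 4 + ["c"] * 4,
                "cov": list(np.tile(["u", "v"], 6)),
            }
        )
        res = cm.permanova(dm, meta, ["grp", "cov"], n_perm=49, seed=1)
        # frozen from vegan::adonis2(D ~ grp + cov, by="terms") on this input
        assert res["sum_of_squares"].iloc[0] == pytest.approx(12.722845, abs=1e-5)
        assert res["sum_of_squares"].iloc[1] == pytest.approx(3.419509, abs=1e-5)
        assert res["pseudo_F"].iloc[0] == pytest.approx(1.781482, abs=1e-5)
        assert res["pseudo_F"].iloc[1] == pytest.approx(0.957615, abs=1e-5)

    def test_single_level_term_rejected(self):
        dm = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=list("abcd"))
        meta = pd.DataFrame({"sample_id": list("abcd"), "grp": ["x"] * 4})
        with pytest.raises(ValueError, match="single level"):
            cm.permanova(dm, meta, ["grp"], n_perm=9)

    def test_strata_restricts_permutations(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(12, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(12)])
        meta = pd.DataFrame(
            {
                "sample_id": dm.ids,
                "study": list(np.repeat(["u", "v", "w"], 4)),
                "grp": list(np.tile(["a", "b"], 6)),
            }
        )
        res = cm.permanova(dm, meta, ["grp"], n_perm=99, seed=2, strata="study")
        p = res["p_value"].iloc[0]
        assert 1 / 100 <= p <= 1.0

    def test_determinism(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(10, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(10)])
        meta = pd.DataFrame({"sample_id": dm.ids, "grp": ["a"] * 5 + ["b"] * 5})
        r1 = cm.permanova(dm, meta, ["grp"], n_perm=199, seed=42)
        r2 = cm.permanova(dm, meta, ["grp"], n_perm=199, seed=42)
        pd.testing.assert_frame_equal(r1, r2)
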