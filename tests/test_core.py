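import numpy as np
import pandas as pd
import pytest

import coremicro as cm


def make_ao(rows):
    """Build an abundance-occupancy frame from (id, mra, occ, mean_study_occ, n_full)."""
    frame = pd.DataFrame(
        rows, columns=["otu_id", "mra", "occ_samples", "mean_study_occupancy", "n_studies_full"]
    ).set_index("otu_id")
    return frame


class TestAbundanceOccupancy:
    def test_toy_two_study_counting(self):
        t = cm.CountTable(
            ["everywhere", "patchy", "absent"],
            ["a1", "a2", "b1", "b2"],
            np.array([[50, 50, 50, 50], [30, 20, 40, 0], [0, 0, 0, 0]]),
        )
        meta = pd.DataFrame(
            {"sample_id": ["a1", "a2", "b1", "b2"], "study": ["A", "A", "B", "B"]}
        )
        ao = cm.abundance_occupancy(t, meta, rarefy_depth=50, seed=0)
        assert ao.loc["everywhere", "occ_samples"] == 1.0
        assert ao.loc["everywhere", "n_studies_full"] == 2
        occ = ao.attrs["occ_by_study"]
        assert occ.loc["patchy", "A"] == 1.0
        assert occ.loc["patchy", "B"] == 0.5
        assert ao.loc["patchy", "n_studies_full"] == 1
        assert ao.loc["absent", "mra"] == 0.0
        assert ao.loc["absent", "occ_samples"] == 0.0


class TestThresholdCore:
    def test_quoted_threshold_rules(self):
        ao = make_ao(
            [
                ("in_occ", 0.002, 0.80, 0.8, 0),
                ("in_study", 0.002, 0.50, 0.5, 11),
                ("out_mra", 0.0005, 0.99, 0.99, 20),
                ("out_occ", 0.002, 0.50, 0.5, 10),
            ]
        )
        core = cm.core_by_threshold(ao)
        assert set(core.members) == {"in_occ", "in_study"}

    def test_equals_brute_force_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(1, 40)
            ao = pd.DataFrame(
                {
                    "mra": rng.uniform(0, 0.01, n),
                    "occ_samples": rng.uniform(0, 1, n),
                    "mean_study_occupancy": rng.uniform(0, 1, n),
                    "n_studies_full": rng.integers(0, 20, n),
                },
                index=pd.Index([f"o{i}" for i in range(n)], name="otu_id"),
            )
            got = set(cm.core_by_threshold(ao).members)
            want = {
                o
                for o, row in ao.iterrows()
                if row["mra"] > 0.001
                and (row["occ_samples"] > 0.75 or row["n_studies_full"] > 10)
            }
            assert got == want


class TestRanking:
    def test_rank_keys(self):
        ao = make_ao(
            [
                ("first", 0.001, 1.0, 1.0, 5),
                ("second", 0.01, 0.7, 0.7, 2),
                ("third", 0.02, 0.7, 0.7, 2),
            ]
        )
        assert cm.rank_by_occupancy(ao) == ["first", "third", "second"]

    def test_identical_stats_fall_back_to_id_order(self):
        ao = make_ao([(i, 0.01, 0.5, 0.5, 1) for i in ["z", "a", "m"]])
        assert cm.rank_by_occupancy(ao) == ["a", "m", "z"]

    def test_singleton(self):
        ao = make_ao([("only", 0.01, 0.5, 0.5, 1)])
        assert cm.rank_by_occupancy(ao) == ["only"]


class TestContributionCurve:
    def test_full_prefix_explains_everything(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 30, size=(8, 5))
        counts[0] += 1
        t = cm.CountTable([f"o{i}" for i in range(8)], [f"s{j}" for j in range(5)], counts)
        ranked = list(t.otu_ids)
        curve = cm.contribution_curve(t, ranked, "bray_curtis")
        assert curve.explained[-1] == pytest.approx(1.0)

    def test_single_discriminating_otu(self):
        t = cm.CountTable(["big", "same"], ["x", "y"], np.array([[90, 10], [10, 10]]))
        curve = cm.contribution_curve(t, ["big", "same"], "bray_curtis")
        # "big" carries every between-sample count difference
        assert curve.explained[0] == pytest.approx(1.0)
        assert curve.explained[-1] == pytest.approx(1.0)

    def test_monotone_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            counts = rng.integers(0, 25, size=(10, 6))
            counts[0] += 1
            t = cm.CountTable(
                [f"o{i}" for i in range(10)], [f"s{j}" for j in range(6)], counts
            )
            curve = cm.contribution_curve(t, list(t.otu_ids), "bray_curtis")
            assert (np.diff(curve.explained) >= -1e-12).all()

    def test_wuf_curve_consistent_with_distance(self):
        tree = cm.generate_tree(8, seed=4)
        ids = cm.leaf_names(tree)
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 30, size=(8, 4))
        t = cm.CountTable(ids, list("wxyz"), counts)
        curve = cm.contribution_curve(t, ids, "weighted_unifrac", tree=tree)
        assert curve.explained[-1] == pytest.approx(1.0)
        assert len(curve) == 8

    def test_requires_tree_for_wuf(self, toy_table):
        with pytest.raises(ValueError, match="tree"):
            cm.contribution_curve(toy_table, list(toy_table.otu_ids), "weighted_unifrac")


class TestStoppingRule:
    def test_stops_after_last_big_gain(self):
        explained = np.array([0.5, 0.9, 0.905, 0.906, 1.0])
        curve = cm.ContributionCurve(explained, "bray_curtis", list("abcde"))
        core = cm.core_by_ranked_contribution(curve, list("abcde"), gain_threshold=0.02)
        # the final 0.094 jump to 1.0 exceeds 2%, so the rule keeps everything
        assert core.members == list("abcde")

    def test_spec_curve_without_terminal_jump(self):
        explained = np.array([0.5, 0.9, 0.905, 0.906, 0.907])
        curve = cm.ContributionCurve(explained, "bray_curtis", list("abcde"))
        core = cm.core_by_ranked_contribution(curve, list("abcde"), gain_threshold=0.02)
        assert core.members == ["a", "b"]

    def test_linear_curve_includes_all(self):
        n = 40
        explained = np.arange(1, n + 1) / n
        ranked = [f"o{i}" for i in range(n)]
        curve = cm.ContributionCurve(explained, "bray_curtis", ranked)
        core = cm.core_by_ranked_contribution(curve, ranked, gain_threshold=0.02)
        assert core.members == ranked

    def test_threshold_one_keeps_argmax_gain_only(self):
        explained = np.array([0.2, 0.7, 0.8, 1.0])
        ranked = list("abcd")
        curve = cm.ContributionCurve(explained, "bray_curtis", ranked)
        core = cm.core_by_ranked_contribution(curve, ranked, gain_threshold=1.0)
        assert core.members == ["a", "b"]  # rank 2 carries the largest single gain

    def test_flat_curve_degenerates_with_warning(self):
        curve = cm.ContributionCurve(np.zeros(4), "bray_curtis", list("abcd"))
        with pytest.warns(UserWarning, match="flat"):
            core = cm.core_by_ranked_contribution(curve, list("abcd"))
        assert core.members == ["a"]


class TestConsensus:
    def _core(self, members, method="MRA_OCC"):
        return cm.CoreSet(method, list(members), pd.DataFrame(index=pd.Index(list(members))))

    def test_set_algebra(self):
        cores = [self._core("ABC"), self._core("BCD"), self._core("BC")]
        assert cm.consensus_core(cores).members == ["B", "C"]

    def test_disjoint_warns_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            out = cm.consensus_core([self._core("AB"), self._core("CD")])
        assert out.members == []

    def test_idempotent_and_order_independent(self):
        a, b = self._core("ABC"), self._core("CAB")
        assert set(cm.consensus_core([a, b]).members) == set(
            cm.consensus_core([b, a]).members
        )
        twice = cm.consensus_core([cm.consensus_core([a, b]), a])
        assert set(twice.members) == {"A", "B", "C"}


class TestSubgroupProfiles:
    def test_uniform_otu_uniform_profile_and_cumulative(self):
        t = cm.CountTable(
            ["core1", "other"],
            ["a", "b", "c", "d"],
            np.array([[30, 30, 30, 30], [10, 10, 10, 10]]),
        )
        meta = pd.DataFrame(
            {
                "sample_id": list("abcd"),
                "study": ["s"] * 4,
                "gender": ["male", "male", "female", "female"],
            }
        )
        core = cm.CoreSet("CONSENSUS", ["core1"], pd.DataFrame(index=pd.Index(["core1"])))
        prof = cm.subgroup_profiles(t, meta, core, ["gender"])
        assert prof.loc["core1", ("gender", "male")] == pytest.approx(0.75)
        assert prof.loc["core1", ("gender", "female")] == pytest.approx(0.75)
        mean, sd = prof.attrs["cumulative_core"][("gender", "male")]
        assert mean == pytest.approx(0.75) and sd == pytest.approx(0.0)

    def test_identical_profiles_cluster_together(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(0.001, 0.1, size=6)
        matrix = pd.DataFrame(
            {
                "twin_a": base,
                "twin_b": base,
                "loner": base * 120,
                "other": base[::-1] * 40,
            }
        ).T
        for k in (2, 3):  # any k <= n - 1 keeps identical profiles together
            labels = cm.cluster_profiles(matrix, k=k)
            assert labels["twin_a"] == labels["twin_b"]
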