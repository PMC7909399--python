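"""Alpha/beta diversity indices, overlap summaries and UPGMA clustering."""

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode
from skbio.diversity.alpha import chao1 as skbio_chao1
from skbio.diversity.alpha import shannon as skbio_shannon

from aquassembly import (CommunityMatrix, alpha_diversity, bray_curtis_matrix,
                         group_overlap, rarefaction_curve, upgma_tree,
                         within_group_beta)
from aquassembly.diversity import DistanceMatrix


def cm_from_rows(rows, prefix="s"):
    df = pd.DataFrame(rows)
    df.index = [f"{prefix}{i}" for i in range(len(rows))]
    df.columns = [f"o{j}" for j in range(df.shape[1])]
    return CommunityMatrix(df)


class TestAlpha:
    def test_uniform_four_otus(self):
        a = alpha_diversity(cm_from_rows([[2, 2, 2, 2]])).iloc[0]
        assert a["shannon"] == pytest.approx(np.log(4), abs=1e-12)
        assert a["inv_simpson"] == pytest.approx(4.0, abs=1e-12)
        assert a["chao1"] == pytest.approx(4.0)

    def test_chao1_closed_form(self):
        # S_obs=6, F1=2, F2=2 -> 6 + 2*1/(2*3) = 6.3333
        a = alpha_diversity(cm_from_rows([[5, 1, 1, 2, 2, 3]])).iloc[0]
        assert a["chao1"] == pytest.approx(6 + 1 / 3, abs=1e-10)

    def test_single_otu_degenerate(self):
        a = alpha_diversity(cm_from_rows([[100]])).iloc[0]
        assert a["shannon"] == 0.0
        assert a["inv_simpson"] == pytest.approx(1.0)

    def test_matches_skbio(self, small_dataset):
        cm, _, _ = small_dataset
        ours = alpha_diversity(cm)
        for sid in cm.sample_ids[:5]:
            counts = cm.data.loc[sid].to_numpy()
            assert ours.loc[sid, "chao1"] == pytest.approx(
                skbio_chao1(counts, bias_corrected=True))
            assert ours.loc[sid, "shannon"] == pytest.approx(
                skbio_shannon(counts, base=np.e))

    def test_chao1_equals_richness_without_singletons(self):
        a = alpha_diversity(cm_from_rows([[4, 5, 2, 3]])).iloc[0]
        assert a["chao1"] == a["richness"]

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError, match="empty"):
            alpha_diversity(cm_from_rows([[0, 0]]))


class TestRarefactionCurve:
    def test_full_depth_recovers_observed(self):
        cm = cm_from_rows([[5, 1, 1, 2, 2, 3]])
        obs = alpha_diversity(cm).iloc[0]["chao1"]
        curve = rarefaction_curve(cm, [14], reps=3, seed=0)
        assert curve.iloc[0, 0] == pytest.approx(obs)

    def test_monotone_in_expectation(self):
        rng = np.random.default_rng(5)
        cm = cm_from_rows([rng.multinomial(500, np.full(50, 0.02))])
        curve = rarefaction_curve(cm, [10, 50, 500], reps=30, seed=1,
                                  metric="richness")
        vals = curve.iloc[0].to_numpy()
        assert vals[0] <= vals[1] <= vals[2]

    def test_deterministic_given_seed(self, small_dataset):
        cm, _, _ = small_dataset
        c1 = rarefaction_curve(cm, [50, 200], reps=2, seed=9)
        c2 = rarefaction_curve(cm, [50, 200], reps=2, seed=9)
        pd.testing.assert_frame_equal(c1, c2)


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        cm = cm_from_rows([[3, 1], [3, 1], [0, 4]])
        D = bray_curtis_matrix(cm)
        assert D.values[0, 1] == pytest.approx(0.0)
        cm2 = cm_from_rows([[1, 0], [0, 1]])
        assert bray_curtis_matrix(cm2).values[0, 1] == pytest.approx(1.0)

    def test_closed_form(self):
        D = bray_curtis_matrix(cm_from_rows([[6, 2], [2, 2]]))
        assert D.values[0, 1] == pytest.approx(4 / 12, abs=1e-12)

    def test_bounds_and_symmetry(self, small_dataset):
        cm, _, _ = small_dataset
        D = bray_curtis_matrix(cm)
        assert (D.values >= 0).all() and (D.values <= 1).all()
        assert np.allclose(D.values, D.values.T)
        assert np.allclose(np.diag(D.values), 0.0)

    def test_zero_total_sample_raises(self):
        df = pd.DataFrame([[0, 0], [1, 2]], index=["a", "b"],
                          columns=["o1", "o2"])
        with pytest.raises(ValueError, match="zero total"):
            bray_curtis_matrix(CommunityMatrix(df))


class TestGroupOverlap:
    def test_single_group(self):
        cm = cm_from_rows([[1, 0, 2], [0, 3, 2]])
        res = group_overlap(cm, pd.Series({"s0": "g", "s1": "g"}))
        assert res["shared_by_all"] == 3
        assert res["per_group"]["g"]["exclusive"] == 3

    def test_enumerated_four_group_toy(self):
        # 11 OTUs: 3 present in all 4 groups, 2 exclusive per group
        rows, groups = [], {}
        for g in range(4):
            row = [1, 1, 1] + [0] * 8
            row[3 + 2 * g] = row[4 + 2 * g] = 1
            rows.append(row)
            groups[f"s{g}"] = f"g{g}"
        res = group_overlap(cm_from_rows(rows), pd.Series(groups))
        assert res["total_otus"] == 11
        assert res["shared_by_all"] == 3
        for g in range(4):
            assert res["per_group"][f"g{g}"]["exclusive"] == 2
        total_exclusive = sum(v["exclusive"]
                              for v in res["per_group"].values())
        assert total_exclusive + res["shared_by_all"] == 11

    def test_unlabeled_sample_raises(self):
        cm = cm_from_rows([[1], [1]])
        with pytest.raises(ValueError):
            group_overlap(cm, pd.Series({"s0": "g"}))


class TestWithinGroupBeta:
    def test_constant_distances(self):
        vals = np.full((3, 3), 0.5)
        np.fill_diagonal(vals, 0.0)
        D = DistanceMatrix(["a", "b", "c"], vals)
        res = within_group_beta(D, pd.Series({"a": "g", "b": "g", "c": "g"}))
        assert res.loc["g", "mean"] == pytest.approx(0.5)
        assert res.loc["g", "sd"] == pytest.approx(0.0)

    def test_hand_computed_sd(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = 0.2
        vals[0, 2] = vals[2, 0] = 0.4
        vals[1, 2] = vals[2, 1] = 0.6
        D = DistanceMatrix(["a", "b", "c"], vals)
        res = within_group_beta(D, pd.Series({"a": "g", "b": "g", "c": "g"}))
        assert res.loc["g", "mean"] == pytest.approx(0.4)
        assert res.loc["g", "sd"] == pytest.approx(0.2)  # sample SD

    def test_between_group_values_ignored(self):
        vals = np.zeros((4, 4))
        vals[0, 1] = vals[1, 0] = 0.3
        vals[2, 3] = vals[3, 2] = 0.7
        for i in (0, 1):
            for j in (2, 3):
                vals[i, j] = vals[j, i] = 0.99
        D = DistanceMatrix(list("abcd"), vals)
        groups = pd.Series({"a": "x", "b": "x", "c": "y", "d": "y"})
        res = within_group_beta(D, groups)
        assert res.loc["x", "mean"] == pytest.approx(0.3)
        assert res.loc["y", "mean"] == pytest.approx(0.7)

    def test_singleton_group_is_missing(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = 0.2
        D = DistanceMatrix(["a", "b", "c"], vals)
        res = within_group_beta(D, pd.Series({"a": "g", "b": "g", "c": "h"}))
        assert np.isnan(res.loc["h", "mean"])


class TestUpgma:
    def test_two_leaves(self):
        vals = np.array([[0.0, 0.4], [0.4, 0.0]])
        tree = TreeNode.read([upgma_tree(DistanceMatrix(["a", "b"], vals))])
        tips = {t.name: t.length for t in tree.tips()}
        assert tips["a"] == pytest.approx(0.2)
        assert tips["b"] == pytest.approx(0.2)

    def test_three_point_topology(self):
        vals = np.array([[0.0, 0.2, 0.6],
                         [0.2, 0.0, 0.6],
                         [0.6, 0.6, 0.0]])
        tree = TreeNode.read([upgma_tree(DistanceMatrix(list("ABC"), vals))])
        # A and B must be sisters
        lca = tree.lca(["A", "B"])
        assert {t.name for t in lca.tips()} == {"A", "B"}

    def test_ultrametric_heights_recovered(self):
        # ((a:1,b:1):2,(c:2,d:2):1) -> cophenetic distances 2, 6, 4
        ids = list("abcd")
        vals = np.array([[0, 2, 6, 6],
                         [2, 0, 6, 6],
                         [6, 6, 0, 4],
                         [6, 6, 4, 0]], dtype=float)
        tree = TreeNode.read([upgma_tree(DistanceMatrix(ids, vals))])
        # root-to-tip distance = half the maximum cophenetic distance
        depths = {t.name: t.accumulate_to_ancestor(tree) for t in tree.tips()}
        assert all(abs(d - 3.0) < 1e-10 for d in depths.values())

    def test_nan_rejected(self):
        vals = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], vals)
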