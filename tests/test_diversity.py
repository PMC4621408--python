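"""Alpha/beta diversity metrics, PCoA and UPGMA against closed forms and
brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from microsync.diversity import (
    Dendrogram,
    DiversityError,
    faith_pd,
    jaccard_matrix,
    observed_species,
    pcoa,
    rarefaction_curves,
    shannon,
    simpson,
    unweighted_unifrac,
    upgma,
)
from microsync.table import OtuTable

from oracles import faith_pd_bruteforce, unifrac_bruteforce


class TestAlphaMetrics:
    @pytest.mark.parametrize(
        "counts,expected", [([5, 0, 2, 1], 3), ([0, 0], 0), ([7], 1)]
    )
    def test_observed_species(self, counts, expected):
        assert observed_species(counts) == expected

    def test_shannon_simpson_closed_forms(self):
        assert shannon([10, 10, 10, 10]) == pytest.approx(2.0)
        assert simpson([10, 10, 10, 10]) == pytest.approx(0.75)
        assert shannon([42]) == pytest.approx(0.0)
        assert simpson([42]) == pytest.approx(0.0)
        # counts [3,1]: H = 2 - 0.75*log2(3)
        assert shannon([3, 1]) == pytest.approx(2 - 0.75 * np.log2(3), abs=1e-9)
        assert simpson([3, 1]) == pytest.approx(1 - (9 + 1) / 16)

    def test_all_zero_errors(self):
        for metric in (shannon, simpson):
            with pytest.raises(DiversityError):
                metric([0, 0, 0])


class TestFaithPD:
    def test_all_leaves_observed_is_total_length(self, random_tree):
        otus, tree = random_tree(n_leaves=8, seed=1)
        total = sum(n.length or 0.0 for n in tree.postorder() if n.parent is not None)
        counts = np.ones(len(otus))
        assert faith_pd(counts, otus, tree) == pytest.approx(total)

    def test_single_leaf_includes_root_path(self):
        from skbio import TreeNode

        tree = TreeNode.read(["((a:0.7,b:0.4):1.0,c:2.0);"])
        pd_a = faith_pd([1, 0, 0], ["a", "b", "c"], tree)
        assert pd_a == pytest.approx(1.7)

    def test_missing_otu_named_in_error(self, random_tree):
        otus, tree = random_tree(n_leaves=4, seed=0)
        with pytest.raises(DiversityError, match="ghost"):
            faith_pd([1], ["ghost"], tree)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_root_path_union_oracle(self, random_tree, seed):
        otus, tree = random_tree(n_leaves=12, seed=seed)
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 2, size=len(otus))
        if counts.sum() == 0:
            counts[0] = 1
        observed = {o for o, c in zip(otus, counts) if c}
        assert faith_pd(counts, otus, tree) == pytest.approx(
            faith_pd_bruteforce(observed, tree), rel=1e-9
        )

    def test_monotone_in_observed_set(self, random_tree):
        otus, tree = random_tree(n_leaves=9, seed=3)
        counts = np.zeros(len(otus), dtype=int)
        prev = 0.0
        for j in range(len(otus)):
            counts[j] = 1
            cur = faith_pd(counts, otus, tree)
            assert cur >= prev - 1e-12
            prev = cur


class TestBetaDiversity:
    def test_jaccard_identical_disjoint_partial(self):
        table = OtuTable(pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 1, 1, 0]],
            index=["a", "b", "c", "d"], columns=["w", "x", "y", "z"],
        ))
        dm = jaccard_matrix(table)
        assert dm["a", "b"] == 0.0
        assert dm["a", "c"] == 1.0
        # {w,x} vs {x,y}: 1 - 1/3
        assert dm["a", "d"] == pytest.approx(2 / 3)

    def test_jaccard_empty_sample_errors(self):
        table = OtuTable(pd.DataFrame(
            [[1, 0], [0, 0]], index=["a", "b"], columns=["x", "y"]
        ))
        with pytest.raises(DiversityError):
            jaccard_matrix(table)

    def test_unifrac_identical_samples_zero(self, random_tree):
        otus, tree = random_tree(n_leaves=6, seed=2)
        table = OtuTable(pd.DataFrame(
            [[1, 0, 1, 0, 1, 0]] * 2, index=["a", "b"], columns=otus
        ))
        assert unweighted_unifrac(table, tree)["a", "b"] == pytest.approx(0.0)

    def test_unifrac_disjoint_root_subtrees_is_one(self):
        from skbio import TreeNode

        tree = TreeNode.read(["((a:1,b:1):1,(c:1,d:1):1);"])
        table = OtuTable(pd.DataFrame(
            [[1, 1, 0, 0], [0, 0, 1, 1]], index=["s1", "s2"],
            columns=["a", "b", "c", "d"],
        ))
        assert unweighted_unifrac(table, tree)["s1", "s2"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(15))
    def test_unifrac_matches_branch_enumeration_oracle(self, random_tree, seed):
        otus, tree = random_tree(n_leaves=10, seed=seed)
        rng = np.random.default_rng(seed + 100)
        pres = rng.integers(0, 2, size=(3, len(otus)))
        pres[pres.sum(axis=1) == 0, 0] = 1
        table = OtuTable(pd.DataFrame(
            pres, index=["s1", "s2", "s3"], columns=otus
        ))
        dm = unweighted_unifrac(table, tree)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            expected = unifrac_bruteforce(pres[i], pres[j], otus, tree)
            assert dm[i, j] == pytest.approx(expected, rel=1e-9)

    def test_distances_bounded_symmetric(self, random_table, random_tree):
        otus, tree = random_tree(n_leaves=12, seed=7)
        table = random_table(n_samples=5, n_otus=12, seed=7)
        table = OtuTable(table.data.set_axis(otus, axis=1))
        for dm in (jaccard_matrix(table), unweighted_unifrac(table, tree)):
            assert np.all(dm.data >= 0) and np.all(dm.data <= 1 + 1e-12)
            assert np.allclose(dm.data, dm.data.T)
            assert np.allclose(np.diag(dm.data), 0)


class TestRarefactionCurves:
    def test_depth_at_total_reproduces_raw_metric(self):
        table = OtuTable(pd.DataFrame(
            [[10, 5, 0, 5]], index=["s"], columns=list("abcd")
        ))
        curves = rarefaction_curves(table, [10, 20], reps=3, seed=0)
        assert curves.loc["s", 20] == observed_species([10, 5, 0, 5])

    def test_unreachable_depth_is_nan_and_means_nondecreasing(self, random_table):
        table = random_table(n_samples=3, n_otus=15, seed=4, max_count=30)
        totals = table.sample_totals()
        depths = [5, 20, 50, int(totals.max()) + 1000]
        curves = rarefaction_curves(table, depths, reps=20, seed=1)
        assert curves[depths[-1]].isna().all()
        reachable = curves.loc[:, curves.columns != depths[-1]]
        diffs = reachable.diff(axis=1).iloc[:, 1:]
        assert (diffs.fillna(0) >= -0.5).all().all()  # up to Monte-Carlo noise


class TestPcoa:
    def test_recovers_points_on_a_line(self):
        pos = np.array([0.0, 1.0, 3.0, 6.0])
        d = np.abs(pos[:, None] - pos[None, :])
        res = pcoa(DistanceMatrix(d, ids=list("abcd")))
        axis1 = res.coordinates.iloc[:, 0].to_numpy()
        rec = np.abs(axis1[:, None] - axis1[None, :])
        assert np.allclose(rec, d, atol=1e-8)

    def test_euclidean_input_fully_reconstructed(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(7, 3))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix(d, ids=[f"p{i}" for i in range(7)]))
        assert res.eigenvalues.min() > -1e-9
        coords = res.coordinates.to_numpy()
        rec = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        assert np.allclose(rec, d, atol=1e-8)


class TestUpgma:
    def test_duplicate_samples_merge_first_at_zero(self):
        d = np.array([[0, 0, 5.0], [0, 0, 5.0], [5.0, 5.0, 0]])
        dendro = upgma(DistanceMatrix(d, ids=["a", "b", "c"]))
        assert dendro.merges[0][:2] == ("a", "b")
        assert dendro.merges[0][2] == pytest.approx(0.0)

    def test_hand_agglomeration_three_samples(self):
        """d(A,B)=2, d(A,C)=d(B,C)=6: AB merges at height 1, root at 3."""
        d = np.array([[0, 2, 6.0], [2, 0, 6.0], [6.0, 6.0, 0]])
        dendro = upgma(DistanceMatrix(d, ids=["A", "B", "C"]))
        assert dendro.heights() == pytest.approx([1.0, 3.0])

    def test_ultrametric_input_reproduced_cophenetically(self):
        d = np.array([
            [0, 2, 8, 8.0],
            [2, 0, 8, 8.0],
            [8, 8, 0, 4.0],
            [8, 8, 4, 0.0],
        ])
        dendro = upgma(DistanceMatrix(d, ids=list("abcd")))
        coph = dendro.cophenetic()
        expected = DistanceMatrix(d, ids=list("abcd")).filter(list(coph.ids))
        assert np.allclose(coph.data, expected.data, atol=1e-9)

    def test_heights_nondecreasing_and_cut_partitions(self, random_table):
        table = random_table(n_samples=7, n_otus=20, seed=11)
        dm = jaccard_matrix(table)
        dendro = upgma(dm)
        heights = dendro.heights()
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, sorted(heights)))
        for k in (1, 3, 7):
            groups = dendro.cut(k)
            assert sorted(groups) == sorted(dm.ids)
            assert len(set(groups.values())) == k

    def test_newick_export_parses(self, random_table):
        from skbio import TreeNode

        table = random_table(n_samples=5, n_otus=12, seed=2)
        dendro = upgma(jaccard_matrix(table))
        tree = TreeNode.read([dendro.to_newick()])
        assert {t.name for t in tree.tips()} == set(dendro.leaves)
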