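"""Welch tests, group summaries, NJ trees and Newick round-trips."""

import io

import numpy as np
import pytest
from scipy import stats as sps

from acascan.family_stats import (
    DistanceMatrix,
    TreeNode,
    PhyloTree,
    distances_from_identity,
    nj_tree,
    summarize_family,
    tree_path_distances,
    welch_t_test,
    write_newick,
)
from acascan.genomic_context import AssociationRecord
from acascan.homology import HomologHit


class TestWelch:
    def test_hand_computed_example(self):
        t, df, p = welch_t_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674234614, abs=1e-8)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.021312, abs=1e-5)

    def test_identical_groups_null_result(self):
        t, _, p = welch_t_test([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_swapping_groups_negates_t_keeps_p(self):
        t1, df1, p1 = welch_t_test([1, 2, 3, 9], [4, 5, 6])
        t2, df2, p2 = welch_t_test([4, 5, 6], [1, 2, 3, 9])
        assert t1 == pytest.approx(-t2)
        assert df1 == pytest.approx(df2)
        assert p1 == pytest.approx(p2)

    def test_agrees_with_scipy_on_random_inputs(self, rng):
        for _ in range(200):
            x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), int(rng.integers(2, 30)))
            y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), int(rng.integers(2, 30)))
            t, df, p = welch_t_test(x, y)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_degenerate_zero_variance_equal_means_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([2.0, 2.0], [2.0, 2.0])

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [2.0, 3.0])


def _hit(cid, coverage=1.0, identity=0.8, length=60):
    return HomologHit(cid, "c1", "AcaS1", 50.0, coverage, identity, length)


def _rec(cid, label):
    return AssociationRecord(_hit(cid), label, "none", [], "op1")


class TestSummarizeFamily:
    def test_coverage_filter_is_strict(self):
        hits = [
            _hit("a", coverage=0.40),
            _hit("b", coverage=0.41),
            _hit("c", coverage=0.41),
        ]
        recs = [_rec("a", "acr_associated"), _rec("b", "acr_associated"), _rec("c", "solo")]
        s = summarize_family(hits, recs)
        assert s.n_associated == 1  # the 0.40 hit is excluded
        assert s.n_solo == 1

    def test_proximal_excluded_by_default(self):
        hits = [_hit(c) for c in "abc"]
        recs = [_rec("a", "acr_associated"), _rec("b", "proximal"), _rec("c", "solo")]
        s = summarize_family(hits, recs)
        assert s.n_associated == 1 and s.n_solo == 1

    def test_parameter_recovery_on_constructed_groups(self, rng):
        assoc = [
            _hit(f"a{i}", identity=float(np.clip(rng.normal(0.75, 0.05), 0, 1)))
            for i in range(30)
        ]
        solo = [
            _hit(f"s{i}", identity=float(np.clip(rng.normal(0.45, 0.05), 0, 1)))
            for i in range(30)
        ]
        recs = [_rec(h.cds_id, "acr_associated") for h in assoc] + [
            _rec(h.cds_id, "solo") for h in solo
        ]
        s = summarize_family(assoc + solo, recs)
        ga, gs = s.identity_stats["associated"], s.identity_stats["solo"]
        assert abs(ga.mean - 0.75) <= 2 * ga.ci95_half_width
        assert abs(gs.mean - 0.45) <= 2 * gs.ci95_half_width
        assert s.t_test_identity[2] < 0.001

    def test_means_invariant_to_hit_order(self, rng):
        hits = [_hit(f"h{i}", identity=rng.uniform(0.3, 1.0)) for i in range(10)]
        recs = [
            _rec(h.cds_id, "acr_associated" if i % 2 else "solo")
            for i, h in enumerate(hits)
        ]
        s1 = summarize_family(hits, recs)
        s2 = summarize_family(list(reversed(hits)), recs)
        assert s1.identity_stats == s2.identity_stats

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            summarize_family([], [])


class TestDistances:
    def test_identical_sequences_zero_distance(self):
        dm = distances_from_identity({"a": "MKLV", "b": "MKLV"})
        assert dm.values[0, 1] == 0.0

    def test_disjoint_alphabets_distance_one(self):
        dm = distances_from_identity({"a": "MMMM", "b": "KKKK"})
        assert dm.values[0, 1] == 1.0

    def test_all_entries_in_unit_interval(self, rng):
        seqs = {
            f"s{i}": "".join(rng.choice(list("MKLVAERS"), size=12)) for i in range(4)
        }
        dm = distances_from_identity(seqs)
        assert np.all(dm.values >= 0) and np.all(dm.values <= 1)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


def random_binary_tree(rng, n_leaves):
    nodes = [TreeNode(f"L{i}") for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        merged = TreeNode(
            children=[(a, float(rng.uniform(0.1, 2.0))), (b, float(rng.uniform(0.1, 2.0)))]
        )
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    root = TreeNode(
        children=[(nodes[0], float(rng.uniform(0.1, 2.0))), (nodes[1], float(rng.uniform(0.1, 2.0)))]
    )
    return PhyloTree(root)


def leaf_splits(tree: PhyloTree) -> set[frozenset]:
    all_leaves = frozenset(tree.leaf_names())
    splits = set()

    def walk(node):
        for child, _ in node.children:
            below = frozenset(child.leaf_names())
            if 1 < len(below) < len(all_leaves) - 1:
                splits.add(frozenset((below, all_leaves - below)))
            walk(child)

    walk(tree.root)
    return splits


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        tree = nj_tree(dm)
        assert write_newick(tree) == "(A:0.5,B:0.5);"

    def test_three_equidistant_taxa_star(self):
        d = np.full((3, 3), 2.0)
        np.fill_diagonal(d, 0.0)
        tree = nj_tree(DistanceMatrix(["A", "B", "C"], d))
        lengths = [bl for _, bl in tree.root.children]
        assert lengths == pytest.approx([1.0, 1.0, 1.0])

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4)): path-sum distance matrix
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0.0, 3.0, 5.0, 6.0],
                [3.0, 0.0, 6.0, 7.0],
                [5.0, 6.0, 0.0, 7.0],
                [6.0, 7.0, 7.0, 0.0],
            ]
        )
        tree = nj_tree(DistanceMatrix(labels, d))
        back = tree_path_distances(tree)
        np.testing.assert_allclose(back.values, d, atol=1e-9)
        assert leaf_splits(tree) == {
            frozenset((frozenset({"A", "B"}), frozenset({"C", "D"})))
        }

    def test_additive_roundtrip_random_trees(self, rng):
        for _ in range(15):
            n = int(rng.integers(4, 11))
            true = random_binary_tree(rng, n)
            dm = tree_path_distances(true)
            rebuilt = nj_tree(dm)
            np.testing.assert_allclose(
                tree_path_distances(rebuilt).values, dm.values, atol=1e-9
            )
            assert leaf_splits(rebuilt) == leaf_splits(true)

    def test_matches_scikit_bio_on_random_matrix(self, rng):
        import skbio

        n = 7
        tree = random_binary_tree(rng, n)
        dm = tree_path_distances(tree)
        sym = (dm.values + dm.values.T) / 2.0  # shed float asymmetry ~1e-15
        sk = skbio.tree.nj(skbio.DistanceMatrix(sym, ids=dm.labels))
        mine = nj_tree(dm)
        sk_d = {
            frozenset((a, b)): sk.find(a).distance(sk.find(b))
            for i, a in enumerate(dm.labels)
            for b in dm.labels[i + 1 :]
        }
        my_back = tree_path_distances(mine)
        for i, a in enumerate(dm.labels):
            for b in dm.labels[i + 1 :]:
                assert my_back.values[
                    my_back.labels.index(a), my_back.labels.index(b)
                ] == pytest.approx(sk_d[frozenset((a, b))], abs=1e-6)


class TestNewick:
    def test_roundtrip_through_biopython(self, rng):
        from Bio import Phylo

        tree = random_binary_tree(rng, 10)
        text = write_newick(tree)
        parsed = Phylo.read(io.StringIO(text), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == sorted(tree.leaf_names())
        # branch lengths survive the round trip
        dm = tree_path_distances(tree)
        for i, a in enumerate(dm.labels):
            for b in dm.labels[i + 1 :]:
                assert parsed.distance(a, b) == pytest.approx(
                    dm.values[dm.labels.index(a), dm.labels.index(b)], abs=1e-9
                )

    def test_labels_with_spaces_quoted(self):
        root = TreeNode(children=[(TreeNode("taxon one"), 0.5), (TreeNode("B"), 0.5)])
        assert write_newick(PhyloTree(root)) == "('taxon one':0.5,B:0.5);"
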