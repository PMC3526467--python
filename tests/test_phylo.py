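"""Distances, neighbor joining, rooting, clade queries, bootstrap."""

import numpy as np
import pytest
from scipy.stats import binom
from skbio import DistanceMatrix

import cladecarve as cc
from cladecarve.phylo import _nontrivial_bipartitions
from cladecarve.records import ValidationError
from cladecarve.tree import leafsets
from oracles import random_binary_tree, tree_leaf_distances, tree_splits


def _rec(i, s):
    return cc.SequenceRecord(i, s)


# ---------------------------------------------------------------------------
# p-distance


def test_p_distance_of_identical_rows_is_zero():
    dm = cc.p_distance_matrix([_rec("a", "ACDE"), _rec("b", "ACDE")])
    assert dm["a", "b"] == 0.0


def test_p_distance_of_disjoint_rows_is_one():
    dm = cc.p_distance_matrix([_rec("a", "AAAA"), _rec("b", "WWWW")])
    assert dm["a", "b"] == 1.0


def test_p_distance_excludes_gap_and_ambiguous_columns_pairwise():
    # "AC-DE" vs "ACQDF": 4 comparable columns, 1 mismatch
    dm = cc.p_distance_matrix([_rec("a", "AC-DE"), _rec("b", "ACQDF")])
    assert dm["a", "b"] == pytest.approx(0.25)


def test_p_distance_hard_errors():
    with pytest.raises(ValidationError, match="ragged"):
        cc.p_distance_matrix([_rec("a", "ACDE"), _rec("b", "ACD")])
    with pytest.raises(ValidationError, match="no comparable"):
        cc.p_distance_matrix([_rec("a", "A--"), _rec("b", "-WW")])


# ---------------------------------------------------------------------------
# Neighbor joining


def test_nj_three_point_branch_lengths_exact():
    dm = DistanceMatrix([[0, 2, 4], [2, 0, 4], [4, 4, 0]], ids=list("ABC"))
    tree = cc.nj_tree(dm)
    lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
    assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}


def test_nj_two_taxa_single_edge():
    dm = DistanceMatrix([[0, 0.4], [0.4, 0]], ids=["A", "B"])
    tree = cc.nj_tree(dm)
    a, b = tree.leaves()
    assert a.length + b.length == pytest.approx(0.4)


def test_nj_requires_two_taxa():
    with pytest.raises(ValidationError):
        cc.nj_tree(DistanceMatrix([[0]], ids=["A"]))


def test_nj_recovers_quartet_by_four_point_condition():
    """Additive matrix from ((A,B),(C,D)) with unit branches: of the three
    quartet topologies only AB|CD satisfies the four-point condition, and
    NJ returns exactly that split."""
    labels = list("ABCD")
    d = {
        ("A", "B"): 2, ("C", "D"): 2,
        ("A", "C"): 3, ("A", "D"): 3, ("B", "C"): 3, ("B", "D"): 3,
    }
    mat = [[0 if i == j else d[tuple(sorted((x, y)))] for j, y in enumerate(labels)]
           for i, x in enumerate(labels)]
    # four-point oracle over the 3 pairings
    sums = {
        "AB|CD": d[("A", "B")] + d[("C", "D")],
        "AC|BD": d[("A", "C")] + d[("B", "D")],
        "AD|BC": d[("A", "D")] + d[("B", "C")],
    }
    assert min(sums, key=sums.get) == "AB|CD"
    tree = cc.nj_tree(DistanceMatrix(mat, ids=labels))
    splits = set(_nontrivial_bipartitions(tree, tree.leaf_names(), "A"))
    assert splits == {frozenset({"C", "D"})}


def test_nj_consistency_on_random_additive_matrices():
    """NJ recovers the true unrooted topology from additive distances
    (50 random trees with up to 12 leaves)."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        n = int(rng.integers(4, 13))
        shape = random_binary_tree(rng, n)
        dists = tree_leaf_distances(shape)
        labels = sorted({x for pair in dists for x in pair})
        mat = [
            [0.0 if a == b else dists[tuple(sorted((a, b)))] for b in labels]
            for a in labels
        ]
        tree = cc.nj_tree(DistanceMatrix(mat, ids=labels))
        got = set(_nontrivial_bipartitions(tree, tree.leaf_names(), labels[0]))
        want = tree_splits(shape, frozenset(labels), labels[0])
        assert got == want


# ---------------------------------------------------------------------------
# Midpoint rooting


def test_midpoint_two_leaves_splits_path_in_half():
    rooted = cc.midpoint_root(cc.parse_newick("(A:1,B:3);"))
    assert {l.name: l.length for l in rooted.leaves()} == {"A": 2.0, "B": 2.0}


def test_midpoint_on_caterpillar():
    rooted = cc.midpoint_root(cc.parse_newick("(((A:1,B:2):3,C:1):2,D:4);"))
    # longest path is B..D of length 11; each end is 5.5 from the root
    ls = leafsets(rooted)
    depth = {l.name: rooted.depth_of(l) for l in rooted.leaves()}
    assert depth["B"] == pytest.approx(5.5)
    assert depth["D"] == pytest.approx(5.5)


def test_midpoint_is_idempotent():
    rooted = cc.midpoint_root(cc.parse_newick("((A:1,B:2)0.9:3,(C:1,D:4)0.8:2);"))
    again = cc.midpoint_root(rooted)
    assert cc.write_newick(again) == cc.write_newick(rooted)


def test_midpoint_preserves_supports_on_bipartitions():
    tree = cc.parse_newick("((A:1,B:1)0.9:1,(C:1,D:1)0.8:1);")
    rooted = cc.midpoint_root(tree)
    sup_by_clade = {
        ls: n.support
        for n, ls in leafsets(rooted).items()
        if not n.is_leaf and n is not rooted
    }
    assert sup_by_clade.get(frozenset("AB")) == 0.9 or sup_by_clade.get(frozenset("CD")) == 0.8


def test_midpoint_all_zero_lengths_warns():
    with pytest.warns(UserWarning, match="all-zero"):
        cc.midpoint_root(cc.parse_newick("((A:0,B:0):0,C:0);"))


# ---------------------------------------------------------------------------
# MRCA


def test_mrca_examples():
    tree = cc.parse_newick("((A:1,B:1):1,C:1);")
    ls = leafsets(tree)
    assert cc.mrca(tree, {"A"}).name == "A"
    assert ls[cc.mrca(tree, {"A", "B"})] == frozenset("AB")
    assert cc.mrca(tree, {"A", "C"}) is tree
    assert cc.mrca(tree, tree.leaf_names()) is tree
    with pytest.raises(ValidationError, match="unknown leaf"):
        cc.mrca(tree, {"A", "Z"})


def test_mrca_is_monotone_under_leaf_addition():
    rng = np.random.default_rng(3)
    tree = cc.parse_newick("(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,G:1):1);")
    names = sorted(tree.leaf_names())
    ls = leafsets(tree)
    for _ in range(25):
        k = int(rng.integers(1, len(names)))
        subset = set(rng.choice(names, size=k, replace=False))
        extra = subset | set(rng.choice(names, size=1))
        small = ls[cc.mrca(tree, subset)]
        big = ls[cc.mrca(tree, extra)]
        assert small <= big  # adding leaves never yields a deeper node


# ---------------------------------------------------------------------------
# Bootstrap


def _quartet_alignment(n_ab: int, n_ac: int):
    """Columns supporting AB|CD vs AC|BD."""
    rows = {"A": [], "B": [], "C": [], "D": []}
    for _ in range(n_ab):
        rows["A"].append("A"); rows["B"].append("A")
        rows["C"].append("R"); rows["D"].append("R")
    for _ in range(n_ac):
        rows["A"].append("A"); rows["C"].append("A")
        rows["B"].append("R"); rows["D"].append("R")
    return [_rec(k, "".join(v)) for k, v in sorted(rows.items())]


def test_bootstrap_unanimous_signal_gives_support_one():
    aln = _quartet_alignment(30, 0)
    tree = cc.bootstrap_support(aln, n_replicates=50, seed=1)
    sups = [n.support for n in tree.preorder() if not n.is_leaf and n is not tree]
    assert sups and all(s == 1.0 for s in sups)


def test_bootstrap_is_deterministic_given_seed():
    aln = _quartet_alignment(20, 10)
    t1 = cc.bootstrap_support(aln, n_replicates=30, seed=9)
    t2 = cc.bootstrap_support(aln, n_replicates=30, seed=9)
    assert cc.write_newick(t1) == cc.write_newick(t2)


def test_bootstrap_single_replicate_supports_are_binary():
    aln = _quartet_alignment(20, 10)
    tree = cc.bootstrap_support(aln, n_replicates=1, seed=2)
    sups = [n.support for n in tree.preorder() if not n.is_leaf and n is not tree]
    assert sups and all(s in (0.0, 1.0) for s in sups)


def test_bootstrap_mixed_signal_matches_binomial_model():
    """With 53 vs 48 conflicting columns (odd total: no ties), a replicate
    keeps the reference split iff the resampled majority does, so the
    support should sit near P(Binom(101, 53/101) >= 51), within a 99%
    binomial interval of the replicate count."""
    n_ab, n_ac = 53, 48
    total = n_ab + n_ac
    aln = _quartet_alignment(n_ab, n_ac)
    n_rep = 400
    tree = cc.bootstrap_support(aln, n_replicates=n_rep, seed=5)
    bips = _nontrivial_bipartitions(tree, tree.leaf_names(), "A")
    (side, node), = bips.items()
    assert side == frozenset({"C", "D"})  # reference split is AB|CD
    p_theory = float(binom.sf(total // 2, total, n_ab / total))
    margin = 2.576 * np.sqrt(p_theory * (1 - p_theory) / n_rep)
    assert abs(node.support - p_theory) <= margin + 1e-9


def test_bootstrap_rejects_bad_replicate_count():
    with pytest.raises(ValidationError):
        cc.bootstrap_support(_quartet_alignment(5, 0), n_replicates=0, seed=0)
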