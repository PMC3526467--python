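"""Anchoring, self-containment, tree carving, subfamily naming."""

import pytest

import cladecarve as cc
from cladecarve.cluster import DictIdentities
from cladecarve.delineate import AnchoredClade, Subfamily
from cladecarve.records import ValidationError
from cladecarve.tree import TreeNode, leafsets


def _meta(names, organisms=None, anchors=None):
    organisms = organisms or {}
    anchors = anchors or {}
    return [
        cc.MetadataRecord(
            n, organisms.get(n, f"Organism {n}"), "Bacteria", "uncharacterized",
            anchor=anchors.get(n),
        )
        for n in names
    ]


def _two_clade_tree(support=1.0, names=("a", "b")):
    """((a1..a5)S:1,(b1..b5)S:1); with tight within-clade branches."""
    inner_a = ",".join(f"{names[0]}{i}:0.05" for i in range(1, 6))
    inner_b = ",".join(f"{names[1]}{i}:0.05" for i in range(1, 6))
    return cc.parse_newick(f"(({inner_a}){support}:1,({inner_b}){support}:1);")


def _two_group_identities(group_a, group_b, within=0.9, between=0.4):
    ids = list(group_a) + list(group_b)
    table = {}
    for i, x in enumerate(ids):
        for y in ids[i + 1 :]:
            same = (x in group_a) == (y in group_a)
            table[frozenset((x, y))] = within if same else between
    return DictIdentities(ids, table)


A_IDS = [f"a{i}" for i in range(1, 6)]
B_IDS = [f"b{i}" for i in range(1, 6)]


# ---------------------------------------------------------------------------
# Anchoring


def test_anchor_groups_in_disjoint_clades():
    tree = _two_clade_tree()
    meta = _meta(A_IDS + B_IDS, anchors={"a1": "A1", "a3": "A1", "b2": "A2", "b5": "A2"})
    clades = cc.anchor_historical(tree, meta)
    assert [(c.numeral, sorted(c.leaf_ids)) for c in clades] == [
        (1, sorted(A_IDS)),
        (2, sorted(B_IDS)),
    ]


def test_interleaved_anchor_tokens_merge_into_their_fused_numeral():
    """A3- and A4-tagged leaves inside one clade become a single anchored
    clade carrying the fused numeral 4."""
    tree = _two_clade_tree()
    meta = _meta(A_IDS + B_IDS, anchors={"a1": "A3", "a2": "A4", "a4": "A3"})
    clades = cc.anchor_historical(tree, meta)
    assert len(clades) == 1
    assert clades[0].numeral == 4
    assert clades[0].leaf_ids <= frozenset(A_IDS)


def test_overlapping_anchor_groups_merge_dynamically():
    tree = _two_clade_tree()
    # A1 and A2 tags interleaved in the same clade: MRCAs overlap -> merged
    meta = _meta(A_IDS + B_IDS, anchors={"a1": "A1", "a5": "A1", "a2": "A2", "a3": "A2"})
    clades = cc.anchor_historical(tree, meta)
    assert len(clades) == 1
    assert clades[0].numeral == 1  # smallest numeral wins for undeclared fusions


def test_anchor_leaf_absent_from_tree_is_hard_error():
    tree = _two_clade_tree()
    meta = _meta(A_IDS + B_IDS + ["ghost"], anchors={"ghost": "A1"})
    with pytest.raises(ValidationError, match="absent from tree"):
        cc.anchor_historical(tree, meta)


# ---------------------------------------------------------------------------
# Self-containment


def test_tight_groups_are_self_contained():
    identities = _two_group_identities(A_IDS, B_IDS)
    assert cc.is_self_contained(frozenset(A_IDS), identities)
    assert cc.is_self_contained(frozenset(B_IDS), identities)


def test_member_with_outside_nearest_neighbor_breaks_containment():
    identities = _two_group_identities(A_IDS, B_IDS)
    # pull a1's nearest neighbor outside the candidate
    identities._table[frozenset(("a1", "b1"))] = 0.95
    params = cc.DelineationParams()
    assert not cc.is_self_contained(frozenset(A_IDS), identities, params)
    # at 80% required containment the four remaining members suffice
    relaxed = cc.DelineationParams(self_containment_frac=0.8)
    assert cc.is_self_contained(frozenset(A_IDS), identities, relaxed)


def test_self_containment_needs_two_members():
    identities = _two_group_identities(A_IDS, B_IDS)
    with pytest.raises(ValidationError):
        cc.is_self_contained(frozenset(["a1"]), identities)


def test_tie_resolution_favors_containment_within_margin():
    identities = _two_group_identities(A_IDS, B_IDS, within=0.8, between=0.8)
    # exact ties everywhere: containment wins with margin 0
    assert cc.is_self_contained(frozenset(A_IDS), identities)


# ---------------------------------------------------------------------------
# Delineation


def test_two_clean_clades_become_two_subfamilies():
    tree = _two_clade_tree()
    meta = _meta(A_IDS + B_IDS)
    identities = _two_group_identities(A_IDS, B_IDS)
    partition = cc.delineate(tree, meta, None, cc.DelineationParams(), identities)
    assert len(partition.subfamilies) == 2
    assert partition.unassigned == frozenset()
    assert {s.leaf_ids for s in partition.subfamilies} == {
        frozenset(A_IDS),
        frozenset(B_IDS),
    }


def test_clade_with_too_few_organisms_stays_unassigned():
    tree = _two_clade_tree()
    organisms = {n: "Same organism" for n in A_IDS}
    organisms.update({n: "Other organism" for n in A_IDS[3:]})  # only 2 distinct
    meta = _meta(A_IDS + B_IDS, organisms=organisms)
    identities = _two_group_identities(A_IDS, B_IDS)
    partition = cc.delineate(tree, meta, None, cc.DelineationParams(), identities)
    names = {s.leaf_ids for s in partition.subfamilies}
    assert frozenset(B_IDS) in names
    assert frozenset(A_IDS) not in names
    assert partition.unassigned == frozenset(A_IDS)


def test_low_support_blocks_all_subfamilies():
    tree = _two_clade_tree(support=0.5)
    meta = _meta(A_IDS + B_IDS)
    identities = _two_group_identities(A_IDS, B_IDS)
    partition = cc.delineate(tree, meta, None, cc.DelineationParams(), identities)
    assert partition.subfamilies == []
    assert partition.unassigned == frozenset(A_IDS + B_IDS)


def test_whole_tree_is_never_a_subfamily():
    """Even when every leaf is mutually similar, the root clade (no stem,
    no complement) cannot be carved out as a subfamily."""
    tree = _two_clade_tree()
    meta = _meta(A_IDS + B_IDS)
    identities = _two_group_identities(A_IDS, B_IDS, within=0.9, between=0.89)
    partition = cc.delineate(tree, meta, None, cc.DelineationParams(), identities)
    assert all(s.leaf_ids != frozenset(A_IDS + B_IDS) for s in partition.subfamilies)


def test_raising_support_threshold_never_adds_subfamilies():
    inner_a = ",".join(f"a{i}:0.05" for i in range(1, 6))
    inner_b = ",".join(f"b{i}:0.05" for i in range(1, 6))
    inner_c = ",".join(f"c{i}:0.05" for i in range(1, 6))
    c_ids = [f"c{i}" for i in range(1, 6)]
    tree = cc.parse_newick(f"(({inner_a})0.95:1,({inner_b})0.75:1,({inner_c})0.6:1);")
    meta = _meta(A_IDS + B_IDS + c_ids)
    ids = A_IDS + B_IDS + c_ids
    table = {}
    for i, x in enumerate(ids):
        for y in ids[i + 1 :]:
            table[frozenset((x, y))] = 0.9 if x[0] == y[0] else 0.4
    identities = DictIdentities(ids, table)
    counts = []
    for smin in (0.0, 0.7, 0.8, 0.99):
        partition = cc.delineate(
            tree, meta, None, cc.DelineationParams(support_min=smin), identities
        )
        partition.validate(tree)
        counts.append(len(partition.subfamilies))
    assert counts == sorted(counts, reverse=True)
    assert counts[0] == 3 and counts[-1] == 0


def test_delineation_recovers_planted_partition():
    cfg = cc.SimulationConfig(n_subfamilies=3, sizes=(8, 10, 12), seed=77)
    sim = cc.simulate_family(cfg)
    model = cc.SubfamilyModel(
        sim.records, sim.meta, alignment=sim.aligned,
        do_cluster=False, family_label="SIM", reserved=frozenset(),
    )
    results = model.fit()
    outcome = cc.evaluate_recovery(sim.truth, results.partition)
    assert outcome.ari == 1.0
    assert results.partition.unassigned == frozenset({"out1", "out2", "out3"})


def test_delineation_is_deterministic():
    cfg = cc.SimulationConfig(n_subfamilies=3, sizes=(6, 7, 8), seed=5)
    sim = cc.simulate_family(cfg)

    def run():
        return cc.SubfamilyModel(
            sim.records, sim.meta, alignment=sim.aligned,
            do_cluster=False, family_label="SIM", reserved=frozenset(),
        ).fit()

    r1, r2 = run(), run()
    assert r1.manifest["partition_sha256"] == r2.manifest["partition_sha256"]
    assert cc.write_newick(r1.tree) == cc.write_newick(r2.tree)


def test_anchored_numerals_survive_extra_nonanchor_leaves():
    base = _two_clade_tree()
    extended = cc.parse_newick(
        "((a1:0.05,a2:0.05,a3:0.05,a4:0.05,a5:0.05)1:1,"
        "(b1:0.05,b2:0.05,b3:0.05,b4:0.05,b5:0.05)1:1,x1:2,x2:2);"
    )
    anchors = {"a1": "A1", "a4": "A1", "b1": "A2", "b3": "A2"}
    for tree, extra in ((base, []), (extended, ["x1", "x2"])):
        meta = _meta(A_IDS + B_IDS + extra, anchors=anchors)
        clades = cc.anchor_historical(tree, meta)
        assert [(c.numeral, sorted(c.leaf_ids)) for c in clades] == [
            (1, sorted(A_IDS)),
            (2, sorted(B_IDS)),
        ]


# ---------------------------------------------------------------------------
# Naming


def _partition_with(n_new, anchored_numerals=()):
    top = TreeNode()
    subs = []
    for numeral in anchored_numerals:
        node = top.add_child(TreeNode(None, 1.0))
        leaf = node.add_child(TreeNode(f"anch{numeral}", 0.1))
        subs.append(Subfamily(None, numeral, frozenset([leaf.name]), node, anchored=True))
    for i in range(n_new):
        node = top.add_child(TreeNode(None, 1.0))
        leaf = node.add_child(TreeNode(f"new{i}", 0.1))
        subs.append(Subfamily(None, None, frozenset([leaf.name]), node, anchored=False))
    return cc.SubfamilyPartition(subs, frozenset())


def test_new_subfamilies_numbered_after_anchors_skipping_reserved():
    partition = _partition_with(3, anchored_numerals=(1, 2))
    named = cc.assign_names(partition, None, "GH5", reserved={3, 6})
    new = [s.numeral for s in named.subfamilies if not s.anchored]
    assert new == [4, 5, 7]
    assert [s.name for s in named.subfamilies if s.anchored] == ["GH5_1", "GH5_2"]


def test_full_anchor_set_numbers_new_clades_from_eleven():
    partition = _partition_with(2, anchored_numerals=(1, 2, 4, 5, 7, 8, 9, 10))
    named = cc.assign_names(partition, cc.AnchorTable(), "GH5")
    new = [s.name for s in named.subfamilies if not s.anchored]
    assert new == ["GH5_11", "GH5_12"]


def test_no_new_clades_keeps_anchor_names_only():
    partition = _partition_with(0, anchored_numerals=(1, 2))
    named = cc.assign_names(partition, cc.AnchorTable(), "GH5")
    assert [s.name for s in named.subfamilies] == ["GH5_1", "GH5_2"]


def test_new_subfamilies_named_in_preorder_of_clade_roots():
    partition = _partition_with(3)
    named = cc.assign_names(partition, None, "FAM", reserved=set())
    order = {s.name: min(s.leaf_ids) for s in named.subfamilies}
    assert order == {"FAM_1": "new0", "FAM_2": "new1", "FAM_3": "new2"}
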