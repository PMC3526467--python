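"""Tree algorithms: p-distances, neighbor joining, rooting, clade queries.

Tree inference here is deliberately simple -- an uncorrected-distance
neighbor-joining tree is a desk-scale stand-in for externally supplied
maximum-likelihood trees, which the pipeline accepts as newick input.
The delineation logic downstream is agnostic to how the tree was built.
"""

from __future__ import annotations

import warnings

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .records import SequenceRecord, ValidationError
from .tree import TreeNode, leafsets

# ---------------------------------------------------------------------------
# Distances


def p_distance_matrix(alignment: list[SequenceRecord]) -> DistanceMatrix:
    """Uncorrected pairwise distance over comparable alignment columns.

    Columns holding a gap or an ambiguous X in either row of a pair are
    excluded pairwise; a pair with no comparable column is an error.
    """
    if len(alignment) < 2:
        raise ValidationError("need at least 2 aligned sequences")
    lengths = {len(r.sequence) for r in alignment}
    if len(lengths) != 1:
        raise ValidationError("ragged alignment: rows have unequal lengths")
    ids = [r.id for r in alignment]
    arr = np.frombuffer(
        "".join(r.sequence for r in alignment).encode("ascii"), dtype=np.uint8
    ).reshape(len(alignment), -1)
    valid = (arr != ord("-")) & (arr != ord("X"))
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise ValidationError(
                    f"no comparable columns between {ids[i]!r} and {ids[j]!r}"
                )
            mism = int((arr[i][both] != arr[j][both]).sum())
            d[i, j] = d[j, i] = mism / m
    return DistanceMatrix(d, ids)


# ---------------------------------------------------------------------------
# Neighbor joining


def _from_skbio(node) -> TreeNode:
    length = float(node.length) if node.length is not None else 0.0
    out = TreeNode(node.name if not node.children else None, max(length, 0.0), None)
    for child in node.children:
        out.add_child(_from_skbio(child))
    return out


def nj_tree(dist: DistanceMatrix) -> TreeNode:
    """Classical neighbor joining; negative branch estimates clamped to 0.

    The returned tree is the usual rooted representation of an unrooted
    topology (root of degree >= 2 with zero-length stem).
    """
    n = len(dist.ids)
    if n < 2:
        raise ValidationError("neighbor joining needs at least 2 taxa")
    if n == 2:
        root = TreeNode()
        half = float(dist[0, 1]) / 2.0
        root.add_child(TreeNode(dist.ids[0], half))
        root.add_child(TreeNode(dist.ids[1], half))
        return root
    return _from_skbio(_skbio_nj(dist))


# ---------------------------------------------------------------------------
# Midpoint rooting

_Edge = tuple[object, object, float, float | None]


def _adjacency(root: TreeNode):
    """Undirected edge map; supports ride edges so rerooting keeps them."""
    adj: dict[TreeNode, list[tuple[TreeNode, float, float | None]]] = {}
    for node in root.preorder():
        adj.setdefault(node, [])
        for child in node.children:
            adj.setdefault(child, [])
            adj[node].append((child, child.length, child.support))
            adj[child].append((node, child.length, child.support))
    return adj


def _farthest(adj, start: TreeNode):
    """Farthest leaf from start by (distance, name); returns (leaf, dist, parents)."""
    dist = {start: 0.0}
    parent: dict[TreeNode, TreeNode | None] = {start: None}
    stack = [start]
    while stack:
        node = stack.pop()
        for nb, length, _ in adj[node]:
            if nb not in dist:
                dist[nb] = dist[node] + length
                parent[nb] = node
                stack.append(nb)
    leaves = [n for n in dist if len(adj[n]) == 1 and n.name is not None]
    best = max(leaves, key=lambda n: (dist[n], n.name or ""))
    return best, dist[best], parent


def _rebuild(adj, node: TreeNode, come_from: TreeNode | None, length: float, support):
    """Rebuild a rooted TreeNode from the adjacency, away from come_from."""
    nbrs = [(nb, ln, sup) for nb, ln, sup in adj[node] if nb is not come_from]
    if not nbrs:
        return TreeNode(node.name, length, None)
    if len(nbrs) == 1 and come_from is not None:
        # suppress the unary pass-through (e.g. the old root): merge branches
        nb, ln, sup2 = nbrs[0]
        return _rebuild(adj, nb, node, length + ln, sup2 if sup2 is not None else support)
    out = TreeNode(None, length, support)
    children = [_rebuild(adj, nb, node, ln, sup) for nb, ln, sup in nbrs]
    children.sort(key=lambda c: min(c.leaf_names()))
    for c in children:
        out.add_child(c)
    return out


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root the tree at the midpoint of its longest leaf-to-leaf path.

    Supports stay attached to the same bipartitions. With all-zero
    branch lengths the tree is rooted at the first traversal node with
    a warning.
    """
    if len(tree.leaves()) < 2:
        return tree.copy()
    adj = _adjacency(tree)
    any_leaf = min(tree.leaves(), key=lambda n: n.name or "")
    u, _, _ = _farthest(adj, any_leaf)
    v, diameter, parent = _farthest(adj, u)
    if diameter <= 0:
        warnings.warn("all-zero branch lengths: rooting at first traversal node")
        return _rebuild(adj, tree, None, 0.0, None)
    # walk the u->v path from v back to u, then locate the midpoint from u
    path = [v]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    path.reverse()  # now u ... v
    half = diameter / 2.0
    acc = 0.0
    for a, b in zip(path, path[1:]):
        step = next(ln for nb, ln, _ in adj[a] if nb is b)
        sup = next(sup for nb, ln, sup in adj[a] if nb is b)
        if acc + step >= half - 1e-12:
            offset = half - acc
            if abs(offset) < 1e-12:  # midpoint exactly at node a
                return _rebuild(adj, a, None, 0.0, None)
            if abs(offset - step) < 1e-12:  # exactly at node b
                return _rebuild(adj, b, None, 0.0, None)
            root = TreeNode()
            left = _rebuild(adj, a, b, offset, sup)
            right = _rebuild(adj, b, a, step - offset, sup)
            for c in sorted((left, right), key=lambda c: min(c.leaf_names())):
                root.add_child(c)
            return root
        acc += step
    raise AssertionError("midpoint not found on diameter path")  # pragma: no cover


# ---------------------------------------------------------------------------
# Clade queries


def mrca(tree: TreeNode, leaves: set[str] | frozenset[str]) -> TreeNode:
    """Deepest node whose clade contains all the given leaf labels."""
    if not leaves:
        raise ValidationError("mrca of an empty leaf set")
    by_name = {n.name: n for n in tree.leaves()}
    nodes = []
    for name in leaves:
        if name not in by_name:
            raise ValidationError(f"unknown leaf label {name!r}")
        nodes.append(by_name[name])
    if len(nodes) == 1:
        return nodes[0]

    def path_to_root(node: TreeNode) -> list[TreeNode]:
        path = [node]
        while path[-1].parent is not None:
            path.append(path[-1].parent)
        return path[::-1]

    paths = [path_to_root(n) for n in nodes]
    deepest = paths[0][0]
    for i in range(min(len(p) for p in paths)):
        first = paths[0][i]
        if all(p[i] is first for p in paths):
            deepest = first
        else:
            break
    return deepest


# ---------------------------------------------------------------------------
# Bootstrap


def _nontrivial_bipartitions(root: TreeNode, all_leaves: frozenset[str], ref: str):
    """Map of normalized internal bipartitions -> node (side without ref taxon)."""
    out = {}
    for node, ls in leafsets(root).items():
        if node is root or node.is_leaf:
            continue
        side = ls if ref not in ls else all_leaves - ls
        if len(side) >= 2 and len(all_leaves - side) >= 2:
            out[side] = node
    return out


def bootstrap_support(
    alignment: list[SequenceRecord], n_replicates: int = 100, seed: int = 0
) -> TreeNode:
    """NJ tree with supports from column-resampling bootstrap.

    The support of each internal bipartition of the reference NJ tree is
    the fraction of replicate NJ trees containing the same (unrooted)
    bipartition. Deterministic given the seed.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    reference = nj_tree(p_distance_matrix(alignment))
    all_leaves = reference.leaf_names()
    ref_taxon = min(all_leaves)
    ref_bips = _nontrivial_bipartitions(reference, all_leaves, ref_taxon)
    counts = {side: 0 for side in ref_bips}
    rng = np.random.default_rng(seed)
    length = len(alignment[0].sequence)
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        resampled = [
            SequenceRecord(r.id, "".join(r.sequence[c] for c in cols))
            for r in alignment
        ]
        rep = nj_tree(p_distance_matrix(resampled))
        rep_bips = _nontrivial_bipartitions(rep, all_leaves, ref_taxon)
        for side in counts:
            if side in rep_bips:
                counts[side] += 1
    for side, node in ref_bips.items():
        node.support = counts[side] / n_replicates
    return reference
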