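"""A minimal rooted phylogenetic tree.

Nodes carry a branch length (to the parent), an optional support value
in [0, 1] attached to the bipartition below the branch, and a label for
leaves. Supports are kept separate from names so that they survive
rerooting (a support belongs to a bipartition, not to a node identity).
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator

from .records import ValidationError


def _fmt(x: float) -> str:
    """Render a branch length / support with up to 6 decimals, trimmed."""
    s = f"{x:.6f}".rstrip("0").rstrip(".")
    return s if s else "0"


class TreeNode:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(
        self,
        name: str | None = None,
        length: float = 0.0,
        support: float | None = None,
    ) -> None:
        if length < 0:
            raise ValidationError(f"negative branch length {length}")
        if support is not None and not 0.0 <= support <= 1.0:
            raise ValidationError(f"support {support} outside [0, 1]")
        self.name = name
        self.length = float(length)
        self.support = support
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    # -- construction -------------------------------------------------

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    # -- structure queries --------------------------------------------

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["TreeNode"]:
        out: list[TreeNode] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        yield from reversed(out)

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> frozenset[str]:
        names = []
        for leaf in self.leaves():
            if leaf.name is None:
                raise ValidationError("leaf without a label")
            names.append(leaf.name)
        return frozenset(names)

    def find_leaf(self, name: str) -> "TreeNode":
        for leaf in self.leaves():
            if leaf.name == name:
                return leaf
        raise KeyError(name)

    def depth_of(self, node: "TreeNode") -> float:
        """Sum of branch lengths from self down to ``node``."""
        d = 0.0
        cur = node
        while cur is not self:
            if cur.parent is None:
                raise ValidationError("node is not in this subtree")
            d += cur.length
            cur = cur.parent
        return d

    # -- copying -------------------------------------------------------

    def copy(self) -> "TreeNode":
        clone = TreeNode(self.name, self.length, self.support)
        for child in self.children:
            clone.add_child(child.copy())
        return clone

    # -- serialization -------------------------------------------------

    def to_newick(self) -> str:
        """Canonical newick: lengths always written, supports as internal labels."""
        return f"{self._newick()};"

    def _newick(self) -> str:
        if self.is_leaf:
            label = self.name or ""
            body = label
        else:
            inner = ",".join(c._newick() for c in self.children)
            label = _fmt(self.support) if self.support is not None else ""
            body = f"({inner}){label}"
        if self.is_root:
            return body
        return f"{body}:{_fmt(self.length)}"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = self.name if self.is_leaf else f"internal/{len(self.children)}"
        return f"<TreeNode {kind} len={self.length:g} sup={self.support}>"


def validate_tree(root: TreeNode) -> None:
    """Check leaf-label uniqueness, branch lengths and support ranges."""
    seen: set[str] = set()
    for node in root.preorder():
        if node.length < 0:
            raise ValidationError("negative branch length")
        if node.support is not None and not 0.0 <= node.support <= 1.0:
            raise ValidationError("support outside [0, 1]")
        if node.is_leaf:
            if not node.name:
                raise ValidationError("unlabeled leaf")
            if node.name in seen:
                raise ValidationError(f"duplicate leaf label {node.name!r}")
            seen.add(node.name)


def leafsets(root: TreeNode) -> dict[TreeNode, frozenset[str]]:
    """Leaf-name set of every node, computed in one postorder sweep."""
    out: dict[TreeNode, frozenset[str]] = {}
    for node in root.postorder():
        if node.is_leaf:
            out[node] = frozenset([node.name])  # type: ignore[list-item]
        else:
            acc: set[str] = set()
            for c in node.children:
                acc.update(out[c])
            out[node] = frozenset(acc)
    return out
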