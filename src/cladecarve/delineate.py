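"""Carving a phylogeny into named subfamilies.

The procedure mirrors how curators subdivide a large glycoside
hydrolase family: historical subfamilies are anchored first via tagged
member sequences, then the remaining tree is scanned for clades that

* are well supported (node support >= ``support_min``),
* are large and diverse enough (>= ``min_size`` sequences spanning
  >= ``min_organisms`` distinct organisms),
* stand apart on the phylogram (the clade's stem branch is long
  relative to the diversity inside it: stem >= ``min_stem_ratio`` x
  within-clade leaf-to-leaf diameter), and
* form a self-contained ensemble (each member's highest-identity
  sequence in the whole dataset lies inside the clade).

Valid clades are made maximal (a clade is dropped in favor of any valid
ancestor), which makes the resulting subfamilies pairwise disjoint.
Everything else stays unassigned. New subfamilies are numbered in
discovery order after the anchored numerals, skipping reserved numerals
left by historical mergers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .phylo import mrca
from .records import MetadataRecord, ValidationError, metadata_by_id
from .tree import TreeNode, leafsets


@dataclass(frozen=True)
class DelineationParams:
    min_size: int = 5
    min_organisms: int = 5
    support_min: float = 0.7
    self_containment_frac: float = 1.0
    separation_margin: float = 0.0
    #: a candidate clade's stem must be at least this multiple of its
    #: within-clade leaf-to-leaf diameter (phylogram distinctness)
    min_stem_ratio: float = 0.5
    #: support assumed for nodes that carry none
    missing_support: float = 1.0

    def __post_init__(self) -> None:
        if self.min_size < 2:
            raise ValidationError("min_size must be >= 2")
        if not 1 <= self.min_organisms <= self.min_size:
            raise ValidationError("min_organisms must be in [1, min_size]")
        if not 0.0 <= self.support_min <= 1.0:
            raise ValidationError("support_min must be in [0, 1]")
        if not 0.0 < self.self_containment_frac <= 1.0:
            raise ValidationError("self_containment_frac must be in (0, 1]")
        if self.separation_margin < 0 or self.min_stem_ratio < 0:
            raise ValidationError("separation_margin and min_stem_ratio must be >= 0")


def default_gh5_anchor_groups() -> dict[frozenset[str], int]:
    """Historical GH5 anchor groups: A3+A4 and A5+A6 are pre-merged,
    leaving numerals 3 and 6 reserved."""
    return {
        frozenset({"A1"}): 1,
        frozenset({"A2"}): 2,
        frozenset({"A3", "A4"}): 4,
        frozenset({"A5", "A6"}): 5,
        frozenset({"A7"}): 7,
        frozenset({"A8"}): 8,
        frozenset({"A9"}): 9,
        frozenset({"A10"}): 10,
    }


@dataclass
class AnchorTable:
    groups: dict[frozenset[str], int] = field(default_factory=default_gh5_anchor_groups)
    reserved: frozenset[int] = frozenset({3, 6})

    def __post_init__(self) -> None:
        numerals = list(self.groups.values())
        if len(numerals) != len(set(numerals)):
            raise ValidationError("anchor numerals must be unique")
        if set(numerals) & set(self.reserved):
            raise ValidationError("anchor numerals may not use reserved numerals")

    def numeral_for(self, tokens: frozenset[str]) -> int | None:
        return self.groups.get(frozenset(tokens))


@dataclass
class AnchoredClade:
    node: TreeNode
    numeral: int
    tokens: frozenset[str]
    leaf_ids: frozenset[str]


@dataclass
class Subfamily:
    name: str | None
    numeral: int | None
    leaf_ids: frozenset[str]
    clade_node: TreeNode
    anchored: bool = False
    support: float | None = None


@dataclass
class SubfamilyPartition:
    subfamilies: list[Subfamily]
    unassigned: frozenset[str]

    @property
    def all_leaves(self) -> frozenset[str]:
        acc = set(self.unassigned)
        for s in self.subfamilies:
            acc.update(s.leaf_ids)
        return frozenset(acc)

    @property
    def coverage(self) -> float:
        total = len(self.all_leaves)
        if total == 0:
            return 0.0
        return 1.0 - len(self.unassigned) / total

    def labels(self) -> dict[str, str | None]:
        out: dict[str, str | None] = {leaf: None for leaf in self.unassigned}
        for s in self.subfamilies:
            for leaf in s.leaf_ids:
                out[leaf] = s.name if s.name is not None else f"#{id(s)}"
        return out

    def validate(self, tree: TreeNode, params: DelineationParams | None = None) -> None:
        """Assert the partition invariants against its source tree."""
        ls = leafsets(tree)
        seen: set[str] = set()
        for s in self.subfamilies:
            if s.leaf_ids & seen:
                raise ValidationError("subfamily leaf sets overlap")
            seen.update(s.leaf_ids)
            if ls[s.clade_node] != s.leaf_ids:
                raise ValidationError(f"subfamily {s.name} is not the clade of its node")
        if seen & self.unassigned:
            raise ValidationError("unassigned leaves overlap a subfamily")
        if seen | self.unassigned != tree.leaf_names():
            raise ValidationError("partition does not cover the tree's leaves")


# ---------------------------------------------------------------------------
# Anchoring


def anchor_historical(
    tree: TreeNode,
    meta: list[MetadataRecord],
    anchors: AnchorTable | None = None,
) -> list[AnchoredClade]:
    """Fix the clades of historically named subfamilies.

    Each anchor group's clade is the MRCA of its tagged leaves; groups
    whose MRCA clades overlap are merged and recomputed, mirroring the
    historical subfamily fusions.
    """
    anchors = anchors or AnchorTable()
    all_leaves = tree.leaf_names()
    tagged: dict[str, set[str]] = {}
    for m in meta:
        if m.anchor:
            if m.seq_id not in all_leaves:
                raise ValidationError(f"anchor leaf {m.seq_id!r} absent from tree")
            tagged.setdefault(m.anchor, set()).add(m.seq_id)
    if not tagged:
        return []
    known = {tok for group in anchors.groups for tok in group}
    unknown = set(tagged) - known
    if unknown:
        raise ValidationError(f"unknown anchor token(s): {sorted(unknown)}")

    groups: list[tuple[frozenset[str], int]] = []
    for tokens, numeral in anchors.groups.items():
        present = {t for t in tokens if t in tagged}
        if present:
            groups.append((frozenset(tokens), numeral))

    ls = leafsets(tree)

    def clade_of(tokens: frozenset[str]) -> tuple[TreeNode, frozenset[str]]:
        members = set()
        for t in tokens:
            members.update(tagged.get(t, set()))
        node = mrca(tree, members)
        return node, ls[node]

    while True:
        clades = [clade_of(tokens) for tokens, _ in groups]
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if clades[i][1] & clades[j][1]:
                    tokens = groups[i][0] | groups[j][0]
                    numeral = anchors.numeral_for(tokens)
                    if numeral is None:
                        numeral = min(groups[i][1], groups[j][1])
                    rest = [g for k, g in enumerate(groups) if k not in (i, j)]
                    groups = rest + [(tokens, numeral)]
                    merged = True
                    break
            if merged:
                break
        if not merged:
            break

    out = []
    for (tokens, numeral), (node, leaf_ids) in zip(groups, clades):
        if len(leaf_ids) > 0.9 * len(all_leaves):
            raise ValidationError("anchors unresolvable: merged clade spans >90% of leaves")
        out.append(AnchoredClade(node, numeral, tokens, leaf_ids))
    out.sort(key=lambda a: a.numeral)
    return out


# ---------------------------------------------------------------------------
# Self-containment


def is_self_contained(
    candidate: frozenset[str] | set[str],
    identities,
    params: DelineationParams = DelineationParams(),
) -> bool:
    """True when the candidate's members find their nearest neighbors inside.

    For each member, the highest-identity sequence in the whole dataset
    (excluding itself) must lie inside the candidate; identity ties
    within ``separation_margin`` resolve in favor of containment. At
    least ``self_containment_frac`` of members must satisfy this.
    """
    candidate = frozenset(candidate)
    if len(candidate) < 2:
        raise ValidationError("self-containment needs a candidate of size >= 2")
    universe = list(identities.ids)
    outside = [x for x in universe if x not in candidate]
    ok = 0
    for member in candidate:
        best_in = max(identities.identity(member, x) for x in candidate if x != member)
        best_out = max(
            (identities.identity(member, y) for y in outside), default=float("-inf")
        )
        if best_in >= best_out - params.separation_margin:
            ok += 1
    return ok / len(candidate) >= params.self_containment_frac


# ---------------------------------------------------------------------------
# Delineation


def _clade_diameters(tree: TreeNode) -> dict[TreeNode, float]:
    """Longest leaf-to-leaf path inside every clade (one postorder sweep)."""
    depth: dict[TreeNode, float] = {}
    diam: dict[TreeNode, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            depth[node] = 0.0
            diam[node] = 0.0
            continue
        child_depths = sorted((depth[c] + c.length for c in node.children), reverse=True)
        depth[node] = child_depths[0]
        through = child_depths[0] + child_depths[1] if len(child_depths) > 1 else 0.0
        diam[node] = max([through] + [diam[c] for c in node.children])
    return diam


def delineate(
    tree: TreeNode,
    meta: list[MetadataRecord],
    anchors: AnchorTable | None,
    params: DelineationParams,
    identities,
) -> SubfamilyPartition:
    """Carve a rooted tree into disjoint subfamily clades.

    Anchored clades are fixed first; remaining candidate clades must
    pass the support / size / organisms / distinctness /
    self-containment predicate and are made maximal. Deterministic.
    """
    by_id = metadata_by_id(meta)
    all_leaves = tree.leaf_names()
    for leaf in sorted(all_leaves):
        if leaf not in by_id:
            raise ValidationError(f"metadata missing for leaf {leaf!r}")

    anchored = anchor_historical(tree, meta, anchors) if anchors is not None else []
    anchored_leaves: set[str] = set()
    for a in anchored:
        if len(a.leaf_ids) < params.min_size:
            raise ValidationError(
                f"anchored clade {sorted(a.tokens)} smaller than min_size"
            )
        anchored_leaves.update(a.leaf_ids)

    ls = leafsets(tree)
    diam = _clade_diameters(tree)

    def organisms(leaf_ids: frozenset[str]) -> int:
        return len({by_id[l].organism_key for l in leaf_ids})

    valid: dict[TreeNode, bool] = {}

    def is_valid(node: TreeNode) -> bool:
        if node in valid:
            return valid[node]
        ok = False
        leaf_ids = ls[node]
        if (
            not node.is_leaf
            and not node.is_root
            and len(leaf_ids) >= params.min_size
            and not (leaf_ids & anchored_leaves)
            and (node.support if node.support is not None else params.missing_support)
            >= params.support_min
            and organisms(leaf_ids) >= params.min_organisms
            and node.length >= params.min_stem_ratio * diam[node]
            and node.length > 0
            and is_self_contained(leaf_ids, identities, params)
        ):
            ok = True
        valid[node] = ok
        return ok

    # maximal valid clades: valid nodes with no valid proper ancestor
    chosen: list[TreeNode] = []
    stack: list[TreeNode] = [tree]
    while stack:
        node = stack.pop()
        if is_valid(node):
            chosen.append(node)
            continue  # do not descend: children are covered by this clade
        stack.extend(reversed(node.children))

    subfamilies = [
        Subfamily(None, a.numeral, a.leaf_ids, a.node, anchored=True, support=a.node.support)
        for a in anchored
    ]
    subfamilies.extend(
        Subfamily(None, None, ls[n], n, anchored=False, support=n.support) for n in chosen
    )
    assigned = set().union(*(s.leaf_ids for s in subfamilies)) if subfamilies else set()
    partition = SubfamilyPartition(
        subfamilies=subfamilies, unassigned=frozenset(all_leaves - assigned)
    )
    partition.validate(tree)
    return partition


def assign_names(
    partition: SubfamilyPartition,
    anchors: AnchorTable | None,
    family_label: str = "GH5",
    reserved: frozenset[int] | set[int] | None = None,
) -> SubfamilyPartition:
    """Name subfamilies ``<label>_<numeral>`` in discovery order.

    Anchored subfamilies keep their historical numerals; new ones are
    numbered by the pre-order position of their clade root, starting
    after the highest anchored numeral and skipping reserved numerals.
    """
    if reserved is None:
        reserved = anchors.reserved if anchors is not None else frozenset()
    used = {s.numeral for s in partition.subfamilies if s.numeral is not None}
    if len(used) != len([s for s in partition.subfamilies if s.numeral is not None]):
        raise ValidationError("anchored numeral collision")

    # pre-order rank of every clade node, from any subfamily's tree
    order: dict[TreeNode, int] = {}
    roots = {s.clade_node for s in partition.subfamilies}
    if roots:
        top = next(iter(roots))
        while top.parent is not None:
            top = top.parent
        order = {node: i for i, node in enumerate(top.preorder())}

    next_numeral = max(used, default=0) + 1
    named: list[Subfamily] = []
    for s in sorted(
        partition.subfamilies,
        key=lambda s: (not s.anchored, s.numeral or 0, order.get(s.clade_node, 0)),
    ):
        if s.numeral is not None:
            numeral = s.numeral
        else:
            while next_numeral in reserved or next_numeral in used:
                next_numeral += 1
            numeral = next_numeral
            used.add(numeral)
        named.append(replace(s, numeral=numeral, name=f"{family_label}_{numeral}"))
    return SubfamilyPartition(subfamilies=named, unassigned=partition.unassigned)
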