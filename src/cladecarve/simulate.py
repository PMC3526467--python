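"""Synthetic protein families with planted subfamily structure.

The generator emulates the statistical shape a curated glycoside
hydrolase family is assumed to have: a handful of divergent clades
(long stems, shallow within-clade divergence), at least five organisms
per subfamily, subfamily-specific EC labels with controllable
polyspecificity, a characterized subset, designated subfamilies with a
knocked-out catalytic machinery, and a few long-branch outliers that
stand in for the unassignable fraction of real families.

Sequences evolve site-independently under a lazy uniform-replacement
model: substitution events are Poisson with rate 1 per site per unit
branch length, and each event replaces the residue with a uniform draw
over all 20, so the probability a site is unchanged over a path of
length t is 1/20 + (19/20) e^(-t). Branch lengths are therefore in
expected substitution events per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .delineate import Subfamily, SubfamilyPartition
from .records import MetadataRecord, SequenceRecord, ValidationError
from .tree import TreeNode

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

DEFAULT_EC_POOL = (
    "3.2.1.4",
    "3.2.1.78",
    "3.2.1.8",
    "3.2.1.73",
    "3.2.1.25",
    "3.2.1.58",
    "3.2.1.75",
    "3.2.1.21",
    "3.2.1.151",
    "3.2.1.123",
)


@dataclass(frozen=True)
class SimulationConfig:
    n_subfamilies: int
    sizes: tuple[int, ...]
    n_outliers: int = 3
    root_length: int = 300
    within_depth: float = 0.1
    between_depth: float = 1.0
    outlier_depth: float = 2.0
    organisms_per_subfamily: int = 5
    frac_characterized: float = 0.3
    ec_pool: tuple[str, ...] = DEFAULT_EC_POOL
    polyspecific_prob: float = 0.3
    knockout_subfamilies: frozenset[int] = frozenset()  # 1-based numerals
    catalytic_columns: tuple[int, ...] = (131, 230)
    catalytic_residue: str = "E"
    indels: bool = False
    indel_rate: float = 0.3  # expected deletion events per leaf when indels on
    organism_pool: tuple[str, ...] | None = None
    family_label: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sizes", tuple(int(s) for s in self.sizes))
        object.__setattr__(self, "knockout_subfamilies", frozenset(self.knockout_subfamilies))
        object.__setattr__(self, "catalytic_columns", tuple(self.catalytic_columns))
        object.__setattr__(self, "ec_pool", tuple(self.ec_pool))
        if self.n_subfamilies < 1 or len(self.sizes) != self.n_subfamilies:
            raise ValidationError("sizes must list one size per subfamily")
        if any(s < 1 for s in self.sizes):
            raise ValidationError("subfamily sizes must be positive")
        if min(self.within_depth, self.between_depth, self.outlier_depth) < 0:
            raise ValidationError("depths must be >= 0")
        for p in (self.frac_characterized, self.polyspecific_prob):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must be in [0, 1]")
        if any(c >= self.root_length or c < 0 for c in self.catalytic_columns):
            raise ValidationError("catalytic columns must be < root_length")
        if self.organisms_per_subfamily < 1:
            raise ValidationError("organisms_per_subfamily must be >= 1")
        if self.organism_pool is not None and len(self.organism_pool) < (
            self.organisms_per_subfamily * self.n_subfamilies + self.n_outliers
        ):
            raise ValidationError("organism_pool too small for the requested layout")
        if not self.knockout_subfamilies <= set(range(1, self.n_subfamilies + 1)):
            raise ValidationError("knockout_subfamilies must reference existing subfamilies")


@dataclass
class SimulatedFamily:
    records: list[SequenceRecord]  # ungapped
    aligned: list[SequenceRecord]  # true alignment (equal to records when no indels)
    meta: list[MetadataRecord]
    true_tree: TreeNode
    truth: SubfamilyPartition
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Tree construction


def _yule_subtree(names: list[str], depth: float, rng: np.random.Generator) -> TreeNode:
    """Random ultrametric subtree whose tips sit exactly ``depth`` below its root."""
    if len(names) == 1:
        return TreeNode(names[0], depth)
    k = len(names)
    u = np.sort(rng.uniform(0.0, 1.0, size=k - 1))
    heights = u / u[-1] * depth if u[-1] > 0 else np.full(k - 1, depth)
    pool: list[tuple[TreeNode, float]] = [(TreeNode(n, 0.0), 0.0) for n in names]
    for h in heights:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        (a, ha), (b, hb) = pool[i], pool[j]
        parent = TreeNode(None, 0.0)
        a.length = h - ha
        b.length = h - hb
        parent.add_child(a)
        parent.add_child(b)
        pool = [p for k2, p in enumerate(pool) if k2 not in (i, j)] + [(parent, float(h))]
    root, _ = pool[0]
    return root


# ---------------------------------------------------------------------------
# Sequence evolution


def _mutate(seq_idx: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve residue indices over a branch of length t (events/site)."""
    if t <= 0:
        return seq_idx.copy()
    hits = rng.poisson(t, size=seq_idx.shape) > 0
    out = seq_idx.copy()
    out[hits] = rng.integers(0, 20, size=int(hits.sum()))
    return out


def _evolve(root: TreeNode, root_idx: np.ndarray, rng: np.random.Generator):
    """Depth-first simulation; returns {leaf name: residue index array}."""
    leaves: dict[str, np.ndarray] = {}
    stack: list[tuple[TreeNode, np.ndarray]] = [(root, root_idx)]
    while stack:
        node, seq = stack.pop()
        if node.is_leaf:
            leaves[node.name] = seq  # type: ignore[index]
            continue
        for child in reversed(node.children):
            stack.append((child, _mutate(seq, child.length, rng)))
    return leaves


# ---------------------------------------------------------------------------
# Main generator


def simulate_family(config: SimulationConfig) -> SimulatedFamily:
    """Generate a family with planted subfamilies; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    aa_of = {c: i for i, c in enumerate(AA)}
    cat_res_idx = aa_of[config.catalytic_residue]

    root_idx = rng.integers(0, 20, size=config.root_length)
    root_idx[list(config.catalytic_columns)] = cat_res_idx

    # --- tree with one stem per subfamily, outliers straight off the root
    tree = TreeNode()
    leaf_subfamily: dict[str, int] = {}
    sub_nodes: list[TreeNode] = []
    for i, size in enumerate(config.sizes, start=1):
        names = [f"sf{i}_s{j:02d}" for j in range(1, size + 1)]
        for n in names:
            leaf_subfamily[n] = i
        sub = _yule_subtree(names, config.within_depth, rng)
        sub.length = config.between_depth
        tree.add_child(sub)
        sub_nodes.append(sub)
    outlier_names = [f"out{j}" for j in range(1, config.n_outliers + 1)]
    for n in outlier_names:
        tree.add_child(TreeNode(n, config.outlier_depth))

    # --- sequences
    leaf_idx = _evolve(tree, root_idx, rng)
    knockout_leaves = {
        n for n, i in leaf_subfamily.items() if i in config.knockout_subfamilies
    }
    non_cat = rng.integers(0, 20)
    while AA[non_cat] == config.catalytic_residue:
        non_cat = rng.integers(0, 20)
    for name, idx in leaf_idx.items():
        target = non_cat if name in knockout_leaves else cat_res_idx
        idx[list(config.catalytic_columns)] = target

    # --- optional deletions (the true alignment keeps the root frame)
    deletions: dict[str, np.ndarray] = {}
    if config.indels:
        forbidden = set(config.catalytic_columns)
        for name in leaf_idx:
            mask = np.zeros(config.root_length, dtype=bool)
            for _ in range(rng.poisson(config.indel_rate)):
                length = int(min(1 + rng.geometric(0.4), 20, config.root_length - 1))
                start = int(rng.integers(0, config.root_length - length))
                window = set(range(start, start + length))
                if window & forbidden:
                    continue
                mask[start : start + length] = True
            if mask.all():  # never delete a whole sequence
                mask[:] = False
            deletions[name] = mask

    ordered = [n for n in leaf_subfamily] + outlier_names
    records: list[SequenceRecord] = []
    aligned: list[SequenceRecord] = []
    for name in ordered:
        chars = AA[leaf_idx[name]]
        if config.indels:
            mask = deletions[name]
            row = "".join("-" if m else c for c, m in zip(chars, mask))
            seq = "".join(c for c, m in zip(chars, mask) if not m)
        else:
            row = seq = "".join(chars)
        records.append(SequenceRecord(name, seq))
        aligned.append(SequenceRecord(name, row))

    # --- metadata
    meta: list[MetadataRecord] = []
    pool = config.organism_pool
    sub_ecs: dict[int, tuple[str, ...]] = {}
    for i in range(1, config.n_subfamilies + 1):
        n_ec = 2 if rng.random() < config.polyspecific_prob else 1
        sub_ecs[i] = tuple(rng.choice(config.ec_pool, size=n_ec, replace=False))
    for i, size in enumerate(config.sizes, start=1):
        names = [n for n, s in leaf_subfamily.items() if s == i]
        if pool is not None:
            orgs = pool[(i - 1) * config.organisms_per_subfamily : i * config.organisms_per_subfamily]
        else:
            orgs = tuple(
                f"Simulobacter subfam{i} sp{j}" for j in range(1, config.organisms_per_subfamily + 1)
            )
        n_char = int(round(config.frac_characterized * size))
        char_members = set(rng.choice(names, size=n_char, replace=False)) if n_char else set()
        for j, name in enumerate(names):
            characterized = name in char_members
            meta.append(
                MetadataRecord(
                    seq_id=name,
                    organism=orgs[j % len(orgs)],
                    tax_group="Bacteria",
                    characterized="characterized" if characterized else "uncharacterized",
                    ec_numbers=sub_ecs[i] if characterized else (),
                )
            )
    for j, name in enumerate(outlier_names, start=1):
        if pool is not None:
            org = pool[config.organisms_per_subfamily * config.n_subfamilies + j - 1]
        else:
            org = f"Singletonia outlier sp{j}"
        meta.append(
            MetadataRecord(
                seq_id=name,
                organism=org,
                tax_group="Bacteria",
                characterized="uncharacterized",
            )
        )

    # --- planted truth
    subfamilies = [
        Subfamily(
            name=f"{config.family_label}_{i}",
            numeral=i,
            leaf_ids=frozenset(n for n, s in leaf_subfamily.items() if s == i),
            clade_node=sub_nodes[i - 1],
            anchored=False,
            support=None,
        )
        for i in range(1, config.n_subfamilies + 1)
    ]
    truth = SubfamilyPartition(subfamilies=subfamilies, unassigned=frozenset(outlier_names))
    truth.validate(tree)
    return SimulatedFamily(records, aligned, meta, tree, truth, config)


def standard_scenario(seed: int, knockout_first: bool = False) -> SimulationConfig:
    """The standard planted-recovery scenario: 3-6 subfamilies of 5-40
    sequences (>= 5 organisms each), 3 long-branch outliers, within-clade
    identity >= 0.8 and between-clade identity <= 0.55."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(3, 7))
    sizes = tuple(int(s) for s in rng.integers(5, 41, size=k))
    return SimulationConfig(
        n_subfamilies=k,
        sizes=sizes,
        knockout_subfamilies=frozenset({1}) if knockout_first else frozenset(),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# Recovery scoring


@dataclass
class RecoveryResult:
    ari: float
    mapping: dict[str, str | None]  # inferred subfamily -> best-overlap truth


def evaluate_recovery(truth: SubfamilyPartition, inferred: SubfamilyPartition) -> RecoveryResult:
    """Adjusted Rand index between a planted and a recovered partition.

    Unassigned leaves count as singleton blocks, so spuriously grouping
    outliers is penalized while leaving them unassigned is not.
    """
    if truth.all_leaves != inferred.all_leaves:
        raise ValidationError("partitions are over different leaf universes")
    leaves = sorted(truth.all_leaves)

    def label_vector(partition: SubfamilyPartition) -> list[str]:
        lab = partition.labels()
        return [lab[l] if lab[l] is not None else f"__singleton_{l}" for l in leaves]

    ari = float(adjusted_rand_score(label_vector(truth), label_vector(inferred)))
    mapping: dict[str, str | None] = {}
    for s in inferred.subfamilies:
        best, best_overlap = None, 0
        for t in truth.subfamilies:
            overlap = len(s.leaf_ids & t.leaf_ids)
            if overlap > best_overlap:
                best, best_overlap = t.name, overlap
        mapping[s.name or "?"] = best
    return RecoveryResult(ari, mapping)
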