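"""Independent reference implementations used only by the tests.

These deliberately re-derive results from first principles (exhaustive
enumeration, plain DP, direct pair counting) so the package code paths
are checked against something that shares none of their machinery.
"""

from __future__ import annotations

from functools import lru_cache
from math import comb

from Bio.Align import substitution_matrices

GAP_OPEN = -10.0
GAP_EXTEND = -0.5


@lru_cache(maxsize=1)
def blosum62():
    return substitution_matrices.load("BLOSUM62")


# ---------------------------------------------------------------------------
# Exhaustive alignment enumeration (tiny sequences only)


def enumerate_alignments(n: int, m: int):
    """All global alignments of an n- and an m-residue sequence.

    Each alignment is a tuple of columns: 'M' (consume both),
    'D' (consume first only -> gap in second row), 'I' (consume second
    only -> gap in first row).
    """

    def rec(i: int, j: int):
        if i == n and j == m:
            yield ()
            return
        if i < n and j < m:
            for rest in rec(i + 1, j + 1):
                yield ("M",) + rest
        if i < n:
            for rest in rec(i + 1, j):
                yield ("D",) + rest
        if j < m:
            for rest in rec(i, j + 1):
                yield ("I",) + rest

    yield from rec(0, 0)


def _gap_runs(cols):
    """(start, length, kind) for every maximal gap run."""
    runs = []
    i = 0
    while i < len(cols):
        if cols[i] in ("D", "I"):
            kind = cols[i]
            j = i
            while j < len(cols) and cols[j] == kind:
                j += 1
            runs.append((i, j - i, kind))
            i = j
        else:
            i += 1
    return runs


def score_alignment(cols, a: str, b: str) -> float:
    """Score one enumerated alignment: BLOSUM62, affine gaps (a gap of
    length L costs 10 + 0.5*(L-1)), gap runs touching either alignment
    end are free."""
    m = blosum62()
    score = 0.0
    i = j = 0
    for c in cols:
        if c == "M":
            score += m[a[i], b[j]]
            i += 1
            j += 1
        elif c == "D":
            i += 1
        else:
            j += 1
    for start, length, _ in _gap_runs(cols):
        if start == 0 or start + length == len(cols):
            continue  # terminal gap run: free
        score += GAP_OPEN + GAP_EXTEND * (length - 1)
    return score


def identity_of_alignment(cols, a: str, b: str) -> float:
    """Identity fraction: identical pairs over columns excluding the
    terminal-gap overhangs."""
    lead = trail = 0
    runs = _gap_runs(cols)
    for start, length, _ in runs:
        if start == 0:
            lead = length
        if start + length == len(cols) and start != 0:
            trail = length
    denom = len(cols) - lead - trail
    if denom <= 0:
        return 0.0
    ident = 0
    i = j = 0
    for c in cols:
        if c == "M":
            if a[i] == b[j]:
                ident += 1
            i += 1
            j += 1
        elif c == "D":
            i += 1
        else:
            j += 1
    return ident / denom


def optimal_alignment_stats(a: str, b: str):
    """(best score, set of identity fractions achieved by optimal alignments)."""
    best = None
    fractions: set[float] = set()
    for cols in enumerate_alignments(len(a), len(b)):
        s = score_alignment(cols, a, b)
        if best is None or s > best + 1e-9:
            best = s
            fractions = {identity_of_alignment(cols, a, b)}
        elif abs(s - best) <= 1e-9:
            fractions.add(identity_of_alignment(cols, a, b))
    return best, fractions


# ---------------------------------------------------------------------------
# DP score oracle (free end gaps, affine) for moderately sized pairs


def dp_score(a: str, b: str) -> float:
    m62 = blosum62()
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    D = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    I = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        D[i][0] = 0.0  # free leading gap in b
    for j in range(1, m + 1):
        I[0][j] = 0.0  # free leading gap in a
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = m62[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], D[i - 1][j - 1], I[i - 1][j - 1]) + s
            D[i][j] = max(
                M[i - 1][j] + GAP_OPEN, D[i - 1][j] + GAP_EXTEND, I[i - 1][j] + GAP_OPEN
            )
            I[i][j] = max(
                M[i][j - 1] + GAP_OPEN, I[i][j - 1] + GAP_EXTEND, D[i][j - 1] + GAP_OPEN
            )
    best = NEG
    for i in range(n + 1):  # free trailing gap in b
        best = max(best, M[i][m], D[i][m], I[i][m])
    for j in range(m + 1):  # free trailing gap in a
        best = max(best, M[n][j], D[n][j], I[n][j])
    return best


# ---------------------------------------------------------------------------
# Adjusted Rand index by direct pair counting


def pair_count_ari(labels_a: list, labels_b: list) -> float:
    assert len(labels_a) == len(labels_b)
    n = len(labels_a)
    from collections import Counter

    contingency = Counter(zip(labels_a, labels_b))
    a_counts = Counter(labels_a)
    b_counts = Counter(labels_b)
    index = sum(comb(c, 2) for c in contingency.values())
    sum_a = sum(comb(c, 2) for c in a_counts.values())
    sum_b = sum(comb(c, 2) for c in b_counts.values())
    total = comb(n, 2)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return (index - expected) / (max_index - expected)


# ---------------------------------------------------------------------------
# Greedy clustering replay


def greedy_replay(ordered_ids, identity_fn, threshold: float):
    """Naive replay of the greedy centroid clustering definition."""
    clusters: list[tuple[str, list[str]]] = []
    for sid in ordered_ids:
        for centroid, members in clusters:
            if identity_fn(sid, centroid) >= threshold:
                members.append(sid)
                break
        else:
            clusters.append((sid, [sid]))
    return [(c, tuple(m)) for c, m in clusters]


# ---------------------------------------------------------------------------
# Random additive trees for NJ consistency


def random_binary_tree(rng, n_leaves: int):
    """Random topology with branch lengths in [0.1, 1.0]; returns
    (children maps as a nested tuple structure, leaf names)."""
    nodes = [(f"L{i}",) for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
        nodes.append((a, b, float(rng.uniform(0.1, 1.0)), float(rng.uniform(0.1, 1.0))))
    return nodes[0]


def tree_leaf_distances(tree):
    """Leaf-to-leaf additive distances of a random_binary_tree structure."""
    dists: dict[tuple[str, str], float] = {}

    def collect(node):
        if len(node) == 1:
            return {node[0]: 0.0}
        a, b, la, lb = node
        left = {k: v + la for k, v in collect(a).items()}
        right = {k: v + lb for k, v in collect(b).items()}
        for x, dx in left.items():
            for y, dy in right.items():
                key = (x, y) if x < y else (y, x)
                dists[key] = dx + dy
        left.update(right)
        return left

    collect(tree)
    return dists


def tree_splits(tree, all_leaves: frozenset[str], ref: str):
    """Nontrivial bipartitions of a random_binary_tree structure,
    normalized to the side not containing ``ref``."""
    splits: set[frozenset[str]] = set()

    def leafset(node) -> frozenset[str]:
        if len(node) == 1:
            return frozenset([node[0]])
        a, b, _, _ = node
        la, lb = leafset(a), leafset(b)
        for side in (la, lb):
            norm = side if ref not in side else all_leaves - side
            if len(norm) >= 2 and len(all_leaves - norm) >= 2:
                splits.add(norm)
        return la | lb

    leafset(tree)
    return splits
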