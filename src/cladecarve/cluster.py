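"""Pairwise global identity, sequence filtering and greedy centroid clustering.

The identity metric is a Needleman-Wunsch global alignment under
BLOSUM62 with affine gaps (open 10, extend 0.5 per additional position)
and free terminal gaps; identity is the fraction of identical aligned
residue pairs over the alignment columns excluding terminal-gap
overhangs (internal gap columns count in the denominator).

Clustering is single-pass greedy centroid clustering: sequences are
processed longest-first and join the first centroid at or above the
identity threshold, otherwise they found a new cluster. The dataset
preparation step keeps every characterized sequence and replaces the
uncharacterized remainder by its cluster centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

from .records import MetadataRecord, SequenceRecord, ValidationError, metadata_by_id


@dataclass(frozen=True)
class ClusterParams:
    identity_threshold: float = 0.75
    min_length: int = 150
    max_ambig_frac: float = 0.05
    ordering: str = "length_desc"  # or "input_order"

    def __post_init__(self) -> None:
        if not 0.0 < self.identity_threshold <= 1.0:
            raise ValidationError("identity_threshold must be in (0, 1]")
        if self.min_length < 1:
            raise ValidationError("min_length must be >= 1")
        if not 0.0 <= self.max_ambig_frac <= 1.0:
            raise ValidationError("max_ambig_frac must be in [0, 1]")
        if self.ordering not in ("length_desc", "input_order"):
            raise ValidationError("ordering must be 'length_desc' or 'input_order'")


@dataclass
class Cluster:
    centroid_id: str
    member_ids: list[str]
    identities: dict[str, float] = field(default_factory=dict)


@dataclass
class DatasetSplit:
    characterized_ids: list[str]
    representative_uncharacterized_ids: list[str]
    combined_ids: list[str]
    cluster_map: dict[str, str]
    clusters: list[Cluster]


# ---------------------------------------------------------------------------
# Global identity


@lru_cache(maxsize=1)
def _aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    # terminal gaps are free
    aligner.open_end_insertion_score = 0.0
    aligner.extend_end_insertion_score = 0.0
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


def _identity_from_rows(row_a: str, row_b: str) -> float:
    """Identity fraction from two gapped alignment rows."""
    n = len(row_a)
    lead = 0
    if row_a.startswith("-"):
        while lead < n and row_a[lead] == "-":
            lead += 1
    elif row_b.startswith("-"):
        while lead < n and row_b[lead] == "-":
            lead += 1
    trail = 0
    if row_a.endswith("-"):
        while trail < n - lead and row_a[n - 1 - trail] == "-":
            trail += 1
    elif row_b.endswith("-"):
        while trail < n - lead and row_b[n - 1 - trail] == "-":
            trail += 1
    denom = n - lead - trail
    if denom <= 0:
        return 0.0
    ident = sum(
        1
        for i in range(lead, n - trail)
        if row_a[i] == row_b[i] and row_a[i] != "-"
    )
    return ident / denom


def global_identity(a: SequenceRecord | str, b: SequenceRecord | str) -> float:
    """Global percent identity between two ungapped sequences, in [0, 1].

    Symmetric by construction: the pair is aligned in a canonical order.
    Among co-optimal alignments the aligner's deterministic first
    traceback is used.
    """
    sa = (a.ungapped if isinstance(a, SequenceRecord) else a.replace("-", "")).upper()
    sb = (b.ungapped if isinstance(b, SequenceRecord) else b.replace("-", "")).upper()
    if not sa or not sb:
        raise ValidationError("global_identity requires non-empty sequences")
    if sa > sb:
        sa, sb = sb, sa
    if sa == sb:
        return 1.0
    aln = _aligner().align(sa, sb)[0]
    return _identity_from_rows(str(aln[0]), str(aln[1]))


def alignment_score(a: str, b: str) -> float:
    """Optimal global alignment score under the package's scoring scheme."""
    if not a or not b:
        raise ValidationError("alignment_score requires non-empty sequences")
    return float(_aligner().score(a.upper(), b.upper()))


class PairwiseIdentities:
    """Lazy symmetric cache of global identities over a fixed dataset."""

    def __init__(self, records: list[SequenceRecord]):
        self._seq = {r.id: r.ungapped for r in records}
        if len(self._seq) != len(records):
            raise ValidationError("duplicate sequence ids")
        self._cache: dict[tuple[str, str], float] = {}

    @property
    def ids(self) -> list[str]:
        return list(self._seq)

    def identity(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = (a, b) if a < b else (b, a)
        val = self._cache.get(key)
        if val is None:
            val = global_identity(self._seq[a], self._seq[b])
            self._cache[key] = val
        return val


class DictIdentities:
    """Identity provider backed by an explicit table (testing / toy data)."""

    def __init__(self, ids: list[str], table: dict[frozenset, float], default: float = 0.0):
        self.ids = list(ids)
        self._table = table
        self._default = default

    def identity(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._table.get(frozenset((a, b)), self._default)


# ---------------------------------------------------------------------------
# Filtering


@dataclass
class FilterResult:
    kept: list[SequenceRecord]
    discarded: list[tuple[SequenceRecord, str]]


def filter_sequences(
    records: list[SequenceRecord], params: ClusterParams = ClusterParams()
) -> FilterResult:
    """Drop obviously incomplete or erroneous sequences.

    A sequence is discarded when its ungapped length is below
    ``min_length`` ("too short") or when the fraction of ambiguous X
    residues exceeds ``max_ambig_frac`` ("ambiguity").
    """
    kept: list[SequenceRecord] = []
    discarded: list[tuple[SequenceRecord, str]] = []
    for rec in records:
        seq = rec.ungapped
        if len(seq) < params.min_length:
            discarded.append((rec, f"too short ({len(seq)} < {params.min_length})"))
        elif seq.count("X") / len(seq) > params.max_ambig_frac:
            frac = seq.count("X") / len(seq)
            discarded.append((rec, f"ambiguity ({frac:.3f} > {params.max_ambig_frac})"))
        else:
            kept.append(rec)
    return FilterResult(kept, discarded)


# ---------------------------------------------------------------------------
# Greedy centroid clustering


def _greedy_order(records: list[SequenceRecord], params: ClusterParams) -> list[SequenceRecord]:
    if params.ordering == "input_order":
        return list(records)
    return sorted(records, key=lambda r: (-len(r.ungapped), r.id))


def cluster_greedy(
    records: list[SequenceRecord],
    params: ClusterParams = ClusterParams(),
    identities: PairwiseIdentities | None = None,
) -> list[Cluster]:
    """Single-pass greedy centroid clustering at the identity threshold.

    Each sequence joins the first existing cluster (in creation order)
    whose centroid identity meets the threshold, otherwise it founds a
    new cluster; every new centroid is therefore below the threshold to
    all earlier centroids. Deterministic given the configured order.
    """
    if identities is None:
        identities = PairwiseIdentities(records)
    clusters: list[Cluster] = []
    for rec in _greedy_order(records, params):
        placed = False
        for cl in clusters:
            ident = identities.identity(rec.id, cl.centroid_id)
            if ident >= params.identity_threshold:
                cl.member_ids.append(rec.id)
                cl.identities[rec.id] = ident
                placed = True
                break
        if not placed:
            clusters.append(Cluster(rec.id, [rec.id], {rec.id: 1.0}))
    return clusters


def prepare_dataset(
    records: list[SequenceRecord],
    meta: list[MetadataRecord],
    params: ClusterParams = ClusterParams(),
    identities: PairwiseIdentities | None = None,
) -> DatasetSplit:
    """Two-set dataset preparation.

    Characterized and activity-tested sequences bypass clustering and
    are retained in full; the uncharacterized remainder is reduced to
    its greedy cluster centroids. The combined list is their union in
    input order.
    """
    by_id = metadata_by_id(meta)
    for rec in records:
        if rec.id not in by_id:
            raise ValidationError(f"no metadata for sequence {rec.id!r}")
    characterized = [r.id for r in records if by_id[r.id].characterized != "uncharacterized"]
    unchar = [r for r in records if by_id[r.id].characterized == "uncharacterized"]
    clusters = cluster_greedy(unchar, params, identities) if unchar else []
    cluster_map = {m: cl.centroid_id for cl in clusters for m in cl.member_ids}
    representatives = {cl.centroid_id for cl in clusters}
    combined = [
        r.id for r in records if by_id[r.id].characterized != "uncharacterized" or r.id in representatives
    ]
    return DatasetSplit(
        characterized_ids=characterized,
        representative_uncharacterized_ids=sorted(representatives),
        combined_ids=combined,
        cluster_map=cluster_map,
        clusters=clusters,
    )
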