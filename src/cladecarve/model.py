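"""Model/Results facade over the subfamily-classification pipeline.

`SubfamilyModel` holds the data (sequences, metadata, and a tree or an
alignment to build one from) together with the protocol parameters;
`fit()` runs filter -> dataset preparation -> tree (given, or p-distance
NJ with optional bootstrap) -> midpoint rooting -> anchoring ->
delineation -> naming -> annotation, and returns a `SubfamilyResults`
carrying the partition, the per-subfamily report, stage logs and a
reproducibility manifest. Reruns with identical inputs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import io as _stdio
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io as cio
from .annotate import CatalyticSpec, FamilyReport, IntegrityResult, catalytic_integrity, family_report
from .cluster import (
    ClusterParams,
    DatasetSplit,
    FilterResult,
    PairwiseIdentities,
    filter_sequences,
    prepare_dataset,
)
from .delineate import (
    AnchorTable,
    DelineationParams,
    SubfamilyPartition,
    assign_names,
    delineate,
)
from .phylo import bootstrap_support, midpoint_root, nj_tree, p_distance_matrix
from .records import MetadataRecord, SequenceRecord, ValidationError, metadata_by_id
from .tree import TreeNode


def shear(tree: TreeNode, keep: set[str] | frozenset[str]) -> TreeNode:
    """Restrict a tree to a leaf subset, suppressing unary nodes.

    Branch lengths along suppressed chains are summed; the surviving
    child's support (its bipartition persists) is kept.
    """
    keep = set(keep)
    missing = keep - tree.leaf_names()
    if missing:
        raise ValidationError(f"tree lacks leaves: {sorted(missing)[:5]} ...")

    def rec(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            return TreeNode(node.name, node.length) if node.name in keep else None
        kids = [k for k in (rec(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            child = kids[0]
            child.length += node.length
            return child
        out = TreeNode(None, node.length, node.support)
        for k in kids:
            out.add_child(k)
        return out

    root = rec(tree)
    if root is None or len(keep) < 2:
        raise ValidationError("cannot shear to fewer than 2 leaves")
    root.length = 0.0
    root.parent = None
    return root


@dataclass
class StageLog:
    stage: str
    n_in: int
    n_out: int
    note: str = ""


@dataclass
class SubfamilyResults:
    """Fitted subfamily classification: partition, annotation, diagnostics."""

    partition: SubfamilyPartition
    report: FamilyReport
    tree: TreeNode
    integrity: IntegrityResult | None
    split: DatasetSplit | None
    filtered: FilterResult
    log: list[StageLog]
    manifest: dict

    # -- convenience frames -------------------------------------------

    def partition_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.partition.subfamilies:
            for leaf in sorted(s.leaf_ids):
                rows.append({"seq_id": leaf, "subfamily": s.name, "support": s.support})
        for leaf in sorted(self.partition.unassigned):
            rows.append({"seq_id": leaf, "subfamily": "UNASSIGNED", "support": None})
        return pd.DataFrame(rows)

    def report_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subfamily": r.subfamily,
                    "n_sequences": r.n_sequences,
                    "tax_distribution": r.tax_distribution,
                    "ec_list": ";".join(r.ec_list) or "ND",
                    "pdb": r.pdb or "",
                    "specificity": r.specificity,
                    "catalytic_status": r.catalytic_status or "",
                }
                for r in self.report.rows
            ]
        )

    # -- presentation ---------------------------------------------------

    def summary(self) -> str:
        c = self.report.counts
        lines = [
            "Subfamily delineation results",
            "=" * 64,
            f"sequences in            {self.manifest['counts']['input']:>6}",
            f"discarded by filters    {self.manifest['counts']['discarded']:>6}",
            f"clustered away          {self.manifest['counts']['clustered_away']:>6}",
            f"assigned to subfamilies {self.manifest['counts']['assigned']:>6}",
            f"unassigned              {self.manifest['counts']['unassigned']:>6}",
            f"coverage                {self.report.coverage:>9.2%}",
            "-" * 64,
            f"subfamilies {c.n_subfamilies}  (monospecific {c.n_monospecific}, "
            f"polyspecific {c.n_polyspecific}, uncharacterized {c.n_uncharacterized})",
            "-" * 64,
            f"{'subfamily':<12}{'n':>5}  {'specificity':<16}{'EC numbers'}",
        ]
        for r in self.report.rows:
            ecs = ";".join(r.ec_list) or "ND"
            qual = "*" if r.partial_ec_only else ""
            lines.append(f"{r.subfamily:<12}{r.n_sequences:>5}  {r.specificity + qual:<16}{ecs}")
        if any(r.partial_ec_only for r in self.report.rows):
            lines.append("* only an unresolved (partial) EC is known")
        return "\n".join(lines)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cio.write_partition_tsv(self.partition, out / "partition.tsv")
        cio.write_report_tsv(self.report, out / "report.tsv")
        cio.write_newick(self.tree, out / "tree.nwk")
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        (out / "log.txt").write_text(
            "\n".join(f"{l.stage}\tin={l.n_in}\tout={l.n_out}\t{l.note}" for l in self.log) + "\n"
        )


class SubfamilyModel:
    """Phylogeny-based subfamily classification of one protein family.

    Parameters
    ----------
    records, metadata : the family's catalytic-module sequences and their
        per-sequence annotation.
    tree : an externally inferred phylogeny (newick-derived); when absent
        an NJ stand-in is built from ``alignment``.
    alignment : aligned rows covering the sequences (also used by the
        catalytic-machinery screen).
    do_cluster : reduce the uncharacterized set to 75%-identity cluster
        centroids before tree building (the characterized set is always
        retained in full).
    """

    def __init__(
        self,
        records: list[SequenceRecord],
        metadata: list[MetadataRecord],
        *,
        tree: TreeNode | None = None,
        alignment: list[SequenceRecord] | None = None,
        anchor_table: AnchorTable | None = None,
        cluster_params: ClusterParams | None = None,
        delineation_params: DelineationParams | None = None,
        catalytic_spec: CatalyticSpec | None = None,
        family_label: str = "GH5",
        reserved: frozenset[int] | set[int] | None = None,
        do_cluster: bool = True,
        bootstrap_replicates: int = 0,
        seed: int = 0,
    ) -> None:
        self.records = list(records)
        self.metadata = list(metadata)
        self.tree = tree
        self.alignment = list(alignment) if alignment is not None else None
        self.anchor_table = anchor_table
        self.cluster_params = cluster_params or ClusterParams()
        self.delineation_params = delineation_params or DelineationParams()
        self.catalytic_spec = catalytic_spec
        self.family_label = family_label
        self.reserved = frozenset(reserved) if reserved is not None else None
        self.do_cluster = do_cluster
        self.bootstrap_replicates = bootstrap_replicates
        self.seed = seed
        if tree is None and alignment is None:
            raise ValidationError("need a tree or an alignment to build one from")

    @classmethod
    def from_files(
        cls,
        fasta: str | Path,
        meta: str | Path,
        tree: str | Path | None = None,
        alignment: str | Path | None = None,
        **kwargs,
    ) -> "SubfamilyModel":
        return cls(
            cio.read_fasta(fasta),
            cio.read_metadata(meta),
            tree=cio.read_newick(tree) if tree else None,
            alignment=cio.read_fasta(alignment) if alignment else None,
            **kwargs,
        )

    # ------------------------------------------------------------------

    def fit(self) -> SubfamilyResults:
        log: list[StageLog] = []
        by_id = metadata_by_id(self.metadata)
        n_input = len(self.records)

        filtered = filter_sequences(self.records, self.cluster_params)
        log.append(StageLog("filter", n_input, len(filtered.kept)))

        split: DatasetSplit | None = None
        if self.do_cluster:
            split = prepare_dataset(filtered.kept, self.metadata, self.cluster_params)
            combined_ids = split.combined_ids
        else:
            for rec in filtered.kept:
                if rec.id not in by_id:
                    raise ValidationError(f"no metadata for sequence {rec.id!r}")
            combined_ids = [r.id for r in filtered.kept]
        log.append(StageLog("prepare_dataset", len(filtered.kept), len(combined_ids)))

        combined = [r for r in filtered.kept if r.id in set(combined_ids)]
        aln_rows = None
        if self.alignment is not None:
            rows = {r.id: r for r in self.alignment}
            missing = [r.id for r in combined if r.id not in rows]
            if missing:
                raise ValidationError(f"alignment rows missing for {missing[:5]} ...")
            aln_rows = [rows[r.id] for r in combined]

        if self.tree is not None:
            tree = self.tree
            if tree.leaf_names() != frozenset(combined_ids):
                tree = shear(tree, set(combined_ids))
            log.append(StageLog("tree", len(tree.leaves()), len(tree.leaves()), "external"))
        else:
            if self.bootstrap_replicates > 0:
                tree = bootstrap_support(aln_rows, self.bootstrap_replicates, self.seed)
                note = f"nj+bootstrap({self.bootstrap_replicates})"
            else:
                tree = nj_tree(p_distance_matrix(aln_rows))
                note = "nj"
            log.append(StageLog("tree", len(combined), len(tree.leaves()), note))

        rooted = midpoint_root(tree)
        log.append(StageLog("midpoint_root", len(rooted.leaves()), len(rooted.leaves())))

        anchors = self.anchor_table
        if anchors is None and any(by_id[i].anchor for i in combined_ids if i in by_id):
            anchors = AnchorTable()

        identities = PairwiseIdentities(combined)
        partition = delineate(rooted, self.metadata, anchors, self.delineation_params, identities)
        partition = assign_names(partition, anchors, self.family_label, self.reserved)
        log.append(StageLog("delineate", len(combined), len(partition.subfamilies)))

        integrity = None
        if self.catalytic_spec is not None:
            if aln_rows is None:
                raise ValidationError("catalytic screen requires an alignment")
            integrity = catalytic_integrity(aln_rows, self.catalytic_spec, partition)
            log.append(
                StageLog(
                    "catalytic_integrity",
                    len(aln_rows),
                    len(integrity.non_catalytic_subfamilies()),
                    "non-catalytic subfamilies",
                )
            )

        report = family_report(partition, self.metadata, integrity)
        log.append(StageLog("report", len(partition.subfamilies), len(report.rows)))

        n_discarded = len(filtered.discarded)
        n_clustered_away = len(filtered.kept) - len(combined_ids)
        n_assigned = report.n_assigned
        n_unassigned = len(partition.unassigned)
        if n_discarded + n_clustered_away + n_assigned + n_unassigned != n_input:
            raise AssertionError("stage-count conservation violated")

        manifest = {
            "family_label": self.family_label,
            "seed": self.seed,
            "bootstrap_replicates": self.bootstrap_replicates,
            "do_cluster": self.do_cluster,
            "cluster_params": asdict(self.cluster_params),
            "delineation_params": asdict(self.delineation_params),
            "counts": {
                "input": n_input,
                "discarded": n_discarded,
                "clustered_away": n_clustered_away,
                "assigned": n_assigned,
                "unassigned": n_unassigned,
                "subfamilies": len(partition.subfamilies),
            },
            "partition_sha256": _partition_hash(partition),
        }
        return SubfamilyResults(
            partition=partition,
            report=report,
            tree=rooted,
            integrity=integrity,
            split=split,
            filtered=filtered,
            log=log,
            manifest=manifest,
        )


def _partition_hash(partition: SubfamilyPartition) -> str:
    buf = _stdio.StringIO()
    for s in sorted(partition.subfamilies, key=lambda s: s.name or ""):
        buf.write(f"{s.name}:{','.join(sorted(s.leaf_ids))}\n")
    buf.write("UNASSIGNED:" + ",".join(sorted(partition.unassigned)))
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()
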