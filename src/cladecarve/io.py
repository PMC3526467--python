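"""Readers and writers for every external format the pipeline touches.

FASTA goes through Bio.SeqIO, newick through scikit-bio (converted into
the package's own :class:`~cladecarve.tree.TreeNode`), tabular files are
TSV with a header row. The bundled GH5 subfamily summary table ships as
``data/table1_gh5.tsv``.
"""

from __future__ import annotations

import csv
import io as _stdio
from importlib import resources
from pathlib import Path

from Bio import SeqIO

from .records import (
    ND,
    FormatError,
    MetadataRecord,
    SequenceRecord,
    Table1Row,
    ValidationError,
)
from .tree import TreeNode, validate_tree

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of validated records.

    Duplicate ids, an empty file, and characters outside the amino-acid
    alphabet are hard errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        try:
            records.append(SequenceRecord(rec.id, str(rec.seq), desc))
        except ValidationError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Metadata TSV

_REQUIRED_META_COLS = ("seq_id", "organism", "tax_group", "characterized", "ec_numbers")


def _split_list(cell: str) -> tuple[str, ...]:
    return tuple(tok.strip() for tok in cell.split(";") if tok.strip())


def read_metadata(path: str | Path) -> list[MetadataRecord]:
    """Read the per-sequence metadata TSV (see README for the columns)."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in _REQUIRED_META_COLS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
        out: list[MetadataRecord] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(
                    MetadataRecord(
                        seq_id=row["seq_id"].strip(),
                        organism=row["organism"].strip(),
                        tax_group=row["tax_group"].strip(),
                        characterized=row["characterized"].strip(),
                        ec_numbers=_split_list(row.get("ec_numbers") or ""),
                        pdb_codes=_split_list(row.get("pdb_codes") or ""),
                        anchor=(row.get("anchor") or "").strip() or None,
                    )
                )
            except ValidationError as exc:
                raise FormatError(f"{path} row {lineno}: {exc}") from exc
    return out


def write_metadata(meta: list[MetadataRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["seq_id", "organism", "tax_group", "characterized", "ec_numbers", "pdb_codes", "anchor"]
        )
        for m in meta:
            writer.writerow(
                [
                    m.seq_id,
                    m.organism,
                    m.tax_group,
                    m.characterized,
                    ";".join(m.ec_numbers),
                    ";".join(m.pdb_codes),
                    m.anchor or "",
                ]
            )


# ---------------------------------------------------------------------------
# Newick


def parse_newick(text: str) -> TreeNode:
    """Parse newick text into a rooted :class:`TreeNode`.

    Internal node labels are interpreted as supports, never as names:
    numeric labels in [0, 1] are SH-like supports, values in (1, 100]
    are bootstrap percentages and are divided by 100. Missing branch
    lengths default to 0.
    """
    import skbio

    stripped = text.strip()
    if ";" in stripped:
        head, _, tail = stripped.partition(";")
        if tail.strip():
            raise FormatError(
                f"trailing garbage after newick terminator at offset {len(head) + 1}"
            )
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sk = skbio.TreeNode.read(
                _stdio.StringIO(stripped), format="newick", convert_underscores=False
            )
    except Exception as exc:
        raise FormatError(f"malformed newick: {exc}") from exc

    def convert(node) -> TreeNode:
        length = float(node.length) if node.length is not None else 0.0
        if node.children:
            support = None
            if node.name is not None:
                try:
                    value = float(node.name)
                except ValueError:
                    raise FormatError(
                        f"internal node label {node.name!r} is not a numeric support"
                    ) from None
                if value > 100 or value < 0:
                    raise FormatError(f"support {value} outside [0, 100]")
                support = value / 100.0 if value > 1.0 else value
            out = TreeNode(None, length, support)
            for child in node.children:
                out.add_child(convert(child))
            return out
        return TreeNode(node.name, length, None)

    root = convert(sk)
    validate_tree(root)
    return root


def read_newick(path: str | Path) -> TreeNode:
    return parse_newick(Path(path).read_text())


def write_newick(tree: TreeNode, path: str | Path | None = None) -> str:
    text = tree.to_newick()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# Bundled GH5 subfamily table


def load_table1_fixture() -> list[Table1Row]:
    """Load the bundled transcription of the GH5 subfamily summary table.

    51 rows; EC cells are ";"-separated tokens or the marker ND (no
    assayed activity); subfamily numerals span 1..53 minus the two
    reserved numerals 3 and 6 left by historical subfamily mergers.
    """
    ref = resources.files("cladecarve").joinpath("data/table1_gh5.tsv")
    try:
        text = ref.read_text()
    except FileNotFoundError as exc:  # pragma: no cover
        raise FormatError("bundled table1_gh5.tsv fixture is missing") from exc
    rows: list[Table1Row] = []
    seen: set[str] = set()
    reader = csv.DictReader(_stdio.StringIO(text), delimiter="\t")
    for lineno, row in enumerate(reader, start=2):
        name = row["subfamily"].strip()
        if name in seen:
            raise FormatError(f"table1 fixture row {lineno}: duplicate subfamily {name}")
        seen.add(name)
        ec_cell = (row.get("ec_list") or "").strip()
        ec_list = () if ec_cell == ND else _split_list(ec_cell)
        if ec_cell != ND and not ec_list:
            raise FormatError(f"table1 fixture row {lineno}: empty EC cell without ND marker")
        try:
            rows.append(
                Table1Row(
                    subfamily=name,
                    historical=(row.get("historical") or "").strip() or None,
                    n_sequences=int(row["n_sequences"]),
                    tax_distribution=row["tax_distribution"].strip(),
                    ec_list=ec_list,
                    pdb=(row.get("pdb") or "").strip() or None,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise FormatError(f"table1 fixture row {lineno}: {exc}") from exc
    if not rows:
        raise FormatError("table1 fixture is empty")
    return rows


# ---------------------------------------------------------------------------
# Partition / report TSV


def write_partition_tsv(partition, path: str | Path) -> None:
    """Write one row per sequence: seq_id, subfamily (or UNASSIGNED), support."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["seq_id", "subfamily", "clade_support"])
        for sub in partition.subfamilies:
            sup = "" if sub.support is None else f"{sub.support:.4f}"
            for seq_id in sorted(sub.leaf_ids):
                writer.writerow([seq_id, sub.name, sup])
        for seq_id in sorted(partition.unassigned):
            writer.writerow([seq_id, "UNASSIGNED", ""])


def write_report_tsv(report, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "subfamily",
                "n_sequences",
                "tax_distribution",
                "ec_list",
                "pdb",
                "specificity",
                "catalytic_status",
            ]
        )
        for row in report.rows:
            writer.writerow(
                [
                    row.subfamily,
                    row.n_sequences,
                    row.tax_distribution,
                    ";".join(row.ec_list) if row.ec_list else ND,
                    row.pdb or "",
                    row.specificity,
                    row.catalytic_status or "",
                ]
            )
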