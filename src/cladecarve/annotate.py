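"""Functional annotation of a subfamily partition.

Maps EC numbers and taxonomy onto subfamilies, classifies each
subfamily's substrate specificity, screens the catalytic machinery of
clan GH-A style active sites (two catalytic glutamates by default), and
renders a summary report in the style of a family subfamily table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import (
    ND,
    MetadataRecord,
    SequenceRecord,
    Table1Row,
    ValidationError,
    metadata_by_id,
)
from .delineate import SubfamilyPartition

MONOSPECIFIC = "monospecific"
POLYSPECIFIC = "polyspecific"
UNCHARACTERIZED = "uncharacterized"


def specificity_class(ec_sets: list[tuple[str, ...]] | list[list[str]]) -> str:
    """Classify a subfamily from its members' EC lists.

    The union of member EC tokens decides: none -> uncharacterized, one
    distinct activity token -> monospecific, two or more ->
    polyspecific. A partial token like ``3.2.1.-`` counts as one
    distinct activity.
    """
    union: set[str] = set()
    for ecs in ec_sets:
        union.update(ecs)
    if not union:
        return UNCHARACTERIZED
    return MONOSPECIFIC if len(union) == 1 else POLYSPECIFIC


def has_only_partial_ec(ec_sets) -> bool:
    """True when every observed activity token has an unresolved last field."""
    union = {ec for ecs in ec_sets for ec in ecs}
    return bool(union) and all(ec.endswith(".-") for ec in union)


# ---------------------------------------------------------------------------
# Catalytic-machinery screen


@dataclass(frozen=True)
class CatalyticSpec:
    """Alignment columns that must hold the catalytic residues.

    Columns are 0-based alignment indices; the default allowed set {E}
    matches the two catalytic glutamates (acid/base and nucleophile) of
    clan GH-A enzymes.
    """

    columns: tuple[int, ...]
    allowed_residues: tuple[frozenset[str], ...] = ()

    def __post_init__(self) -> None:
        if not self.columns:
            raise ValidationError("CatalyticSpec needs at least one column")
        allowed = self.allowed_residues or tuple(frozenset("E") for _ in self.columns)
        if len(allowed) != len(self.columns):
            raise ValidationError("allowed_residues must match columns")
        if any(not s for s in allowed):
            raise ValidationError("allowed residue sets must be non-empty")
        object.__setattr__(self, "allowed_residues", tuple(frozenset(s) for s in allowed))


@dataclass
class IntegrityResult:
    intact: dict[str, bool]
    subfamily_status: dict[str, str]  # catalytic | non_catalytic | mixed
    offenders: dict[str, list[str]]  # subfamily -> members lacking residues

    def non_catalytic_subfamilies(self) -> list[str]:
        return sorted(k for k, v in self.subfamily_status.items() if v == "non_catalytic")


def catalytic_integrity(
    alignment: list[SequenceRecord],
    spec: CatalyticSpec,
    partition: SubfamilyPartition,
) -> IntegrityResult:
    """Flag sequences and subfamilies lacking the catalytic machinery.

    A sequence is intact iff every catalytic column holds an allowed
    residue (a gap or any other residue counts as lacking); a subfamily
    is non-catalytic iff every member is lacking.
    """
    rows = {r.id: r.sequence for r in alignment}
    width = min(len(s) for s in rows.values()) if rows else 0
    for col in spec.columns:
        if col >= width:
            raise ValidationError(f"catalytic column {col} outside alignment width {width}")
    intact: dict[str, bool] = {}
    for s in partition.subfamilies:
        for leaf in s.leaf_ids:
            if leaf not in rows:
                raise ValidationError(f"alignment row missing for {leaf!r}")
    for seq_id, row in rows.items():
        intact[seq_id] = all(
            row[col] in allowed for col, allowed in zip(spec.columns, spec.allowed_residues)
        )
    status: dict[str, str] = {}
    offenders: dict[str, list[str]] = {}
    for s in partition.subfamilies:
        name = s.name or f"subfamily@{id(s)}"
        lacking = sorted(l for l in s.leaf_ids if not intact[l])
        offenders[name] = lacking
        if len(lacking) == len(s.leaf_ids):
            status[name] = "non_catalytic"
        elif lacking:
            status[name] = "mixed"
        else:
            status[name] = "catalytic"
    return IntegrityResult(intact, status, offenders)


# ---------------------------------------------------------------------------
# Family report


@dataclass
class ReportRow:
    subfamily: str
    n_sequences: int
    tax_distribution: str
    ec_list: tuple[str, ...]
    pdb: str | None
    specificity: str
    partial_ec_only: bool = False
    catalytic_status: str | None = None


@dataclass
class FamilyCounts:
    n_subfamilies: int
    n_uncharacterized: int
    n_characterized: int
    n_monospecific: int
    n_polyspecific: int
    n_with_structure: int
    n_fungal_only: int
    largest_subfamily: str
    largest_subfamily_size: int

    def __post_init__(self) -> None:
        total = self.n_monospecific + self.n_polyspecific + self.n_uncharacterized
        if total != self.n_subfamilies:
            raise ValidationError("specificity counts do not sum to n_subfamilies")


@dataclass
class FamilyReport:
    rows: list[ReportRow]
    counts: FamilyCounts
    coverage: float
    n_assigned: int
    n_total: int


FUNGAL_ONLY = "Eukaryota (Fungi)"


def _counts_from_rows(rows: list[ReportRow]) -> FamilyCounts:
    largest = max(rows, key=lambda r: r.n_sequences) if rows else None
    return FamilyCounts(
        n_subfamilies=len(rows),
        n_uncharacterized=sum(1 for r in rows if r.specificity == UNCHARACTERIZED),
        n_characterized=sum(1 for r in rows if r.specificity != UNCHARACTERIZED),
        n_monospecific=sum(1 for r in rows if r.specificity == MONOSPECIFIC),
        n_polyspecific=sum(1 for r in rows if r.specificity == POLYSPECIFIC),
        n_with_structure=sum(1 for r in rows if r.pdb),
        n_fungal_only=sum(1 for r in rows if r.tax_distribution == FUNGAL_ONLY),
        largest_subfamily=largest.subfamily if largest else "",
        largest_subfamily_size=largest.n_sequences if largest else 0,
    )


def _render_tax(groups: set[str]) -> str:
    """Deterministic rendering of a union of tax_group strings."""
    majors: list[str] = []
    sublineages: set[str] = set()
    for g in sorted(groups):
        if "(" in g:
            major, _, rest = g.partition("(")
            major = major.strip()
            sublineages.update(s.strip() for s in rest.rstrip(")").split(";") if s.strip())
        else:
            major = g.strip()
        if major not in majors:
            majors.append(major)
    majors.sort()
    out = " ".join(majors)
    if sublineages:
        out += f" ({';'.join(sorted(sublineages))})"
    return out


def family_report(
    partition: SubfamilyPartition,
    meta: list[MetadataRecord],
    integrity: IntegrityResult | None = None,
) -> FamilyReport:
    """One row per subfamily plus family-level counters and coverage.

    A pure function of its inputs: rows are ordered by subfamily
    numeral, tax distributions and EC unions render deterministically,
    the representative PDB code is the lexicographically first one.
    """
    by_id = metadata_by_id(meta)
    rows: list[ReportRow] = []
    for s in sorted(partition.subfamilies, key=lambda s: (s.numeral or 0, s.name or "")):
        members = [by_id[l] for l in sorted(s.leaf_ids)]
        ec_sets = [m.ec_numbers for m in members]
        ecs = tuple(sorted({ec for ecs in ec_sets for ec in ecs}))
        pdbs = sorted({p for m in members for p in m.pdb_codes})
        rows.append(
            ReportRow(
                subfamily=s.name or "?",
                n_sequences=len(s.leaf_ids),
                tax_distribution=_render_tax({m.tax_group for m in members}),
                ec_list=ecs,
                pdb=pdbs[0] if pdbs else None,
                specificity=specificity_class(ec_sets),
                partial_ec_only=has_only_partial_ec(ec_sets),
                catalytic_status=(
                    integrity.subfamily_status.get(s.name or "") if integrity else None
                ),
            )
        )
    n_total = len(partition.all_leaves)
    n_assigned = n_total - len(partition.unassigned)
    return FamilyReport(
        rows=rows,
        counts=_counts_from_rows(rows),
        coverage=partition.coverage,
        n_assigned=n_assigned,
        n_total=n_total,
    )


def report_from_table1(rows: list[Table1Row]) -> FamilyReport:
    """Replay the report counters over rows of a published summary table."""
    report_rows = [
        ReportRow(
            subfamily=r.subfamily,
            n_sequences=r.n_sequences,
            tax_distribution=r.tax_distribution,
            ec_list=r.ec_list,
            pdb=r.pdb,
            specificity=specificity_class([r.ec_list]),
            partial_ec_only=has_only_partial_ec([r.ec_list]),
        )
        for r in rows
    ]
    total = sum(r.n_sequences for r in rows)
    return FamilyReport(
        rows=report_rows,
        counts=_counts_from_rows(report_rows),
        coverage=1.0,
        n_assigned=total,
        n_total=total,
    )
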