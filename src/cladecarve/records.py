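"""Core record types shared across the pipeline.

A dataset is a list of :class:`SequenceRecord` (one catalytic-module
amino-acid sequence each) plus one :class:`MetadataRecord` per sequence
carrying organism, taxonomy, characterization status, EC numbers, PDB
codes and an optional historical-subfamily anchor tag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: residues allowed in an ungapped sequence (X = ambiguous)
SEQ_ALPHABET = AA20 | {"X"}
#: residues allowed in an alignment row
ALN_ALPHABET = SEQ_ALPHABET | {"-"}

#: EC tokens are four dotted fields, "-" allowed only in the last one
EC_PATTERN = re.compile(r"^\d+\.\d+\.\d+\.(\d+|-)$")

CHARACTERIZATION_LEVELS = ("characterized", "activity_only", "uncharacterized")

#: Table-1 marker for a subfamily with no assayed activity at all
ND = "ND"


class FormatError(ValueError):
    """A file or text input could not be parsed."""


class ValidationError(ValueError):
    """Parsed data violates a dataset invariant."""


def normalize_organism(organism: str) -> str:
    """Canonical form used when counting distinct organisms."""
    return " ".join(organism.split()).casefold()


@dataclass(frozen=True)
class SequenceRecord:
    """One amino-acid sequence with a stable identifier.

    The sequence is case-folded to upper on construction and restricted
    to the 20 canonical residues plus ``X`` (ambiguous) and ``-`` (gap,
    meaningful only in alignment context).
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValidationError(f"sequence id must be a non-empty token, got {self.id!r}")
        if not self.sequence:
            raise ValidationError(f"empty sequence for id {self.id!r}")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        for pos, c in enumerate(seq):
            if c not in ALN_ALPHABET:
                raise ValidationError(
                    f"invalid character {c!r} at position {pos} in sequence {self.id!r}"
                )

    @property
    def ungapped(self) -> str:
        return self.sequence.replace("-", "")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MetadataRecord:
    """Per-sequence annotation: organism, taxonomy, characterization, ECs."""

    seq_id: str
    organism: str
    tax_group: str
    characterized: str = "uncharacterized"
    ec_numbers: tuple[str, ...] = ()
    pdb_codes: tuple[str, ...] = ()
    anchor: str | None = None

    def __post_init__(self) -> None:
        if self.characterized not in CHARACTERIZATION_LEVELS:
            raise ValidationError(
                f"characterized must be one of {CHARACTERIZATION_LEVELS}, "
                f"got {self.characterized!r} for {self.seq_id!r}"
            )
        object.__setattr__(self, "ec_numbers", tuple(self.ec_numbers))
        object.__setattr__(self, "pdb_codes", tuple(self.pdb_codes))
        for ec in self.ec_numbers:
            if not EC_PATTERN.match(ec):
                raise ValidationError(f"malformed EC token {ec!r} for {self.seq_id!r}")
        if self.characterized == "uncharacterized" and self.ec_numbers:
            raise ValidationError(
                f"uncharacterized sequence {self.seq_id!r} must have an empty EC list"
            )

    @property
    def organism_key(self) -> str:
        return normalize_organism(self.organism)


@dataclass(frozen=True)
class Table1Row:
    """One row of the bundled GH5 subfamily summary table."""

    subfamily: str
    historical: str | None
    n_sequences: int
    tax_distribution: str
    ec_list: tuple[str, ...] = ()
    pdb: str | None = None

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValidationError(f"{self.subfamily}: n_sequences must be >= 1")
        object.__setattr__(self, "ec_list", tuple(self.ec_list))
        for ec in self.ec_list:
            if not EC_PATTERN.match(ec):
                raise ValidationError(f"{self.subfamily}: malformed EC token {ec!r}")

    @property
    def is_nd(self) -> bool:
        """True when the row has no assayed activity (Table-1 marker ND)."""
        return not self.ec_list

    @property
    def numeral(self) -> int:
        return int(self.subfamily.rsplit("_", 1)[1])


def metadata_by_id(meta: list[MetadataRecord]) -> dict[str, MetadataRecord]:
    out: dict[str, MetadataRecord] = {}
    for m in meta:
        if m.seq_id in out:
            raise ValidationError(f"duplicate metadata for seq_id {m.seq_id!r}")
        out[m.seq_id] = m
    return out
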