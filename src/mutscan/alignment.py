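"""Aligned protein families and alignment-column ↔ residue coordinate maps.

The unit of analysis is a pre-computed multiple sequence alignment of a
transporter family (e.g. the AzgA-like subfamily of the NAT/NCS2
nucleobase transporters), with one taxonomic group label per sequence.
All downstream conservation, motif and candidate-selection steps operate
on this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import AlignIO

AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"

#: taxonomic groups used for per-group conservation flags
GROUPS = ("known", "prokaryote", "plant", "ascomycete", "basidiomycete", "other")


class AlignmentFormatError(ValueError):
    """Raised when an input alignment cannot be parsed or has unequal lengths."""


class AlignmentValidationError(ValueError):
    """Raised when a parsed alignment contains illegal characters."""


@dataclass(frozen=True)
class AlignedRecord:
    id: str
    group: str
    aligned_seq: str


@dataclass
class AlignedFamily:
    """An aligned protein family with per-sequence group labels.

    Invariants: all sequences share the same length ``n_columns`` >= 1,
    ids are unique, and only the 20 amino-acid letters plus ``-`` appear.
    Ambiguity codes (B, Z, X) are rejected so that the motif wildcard 'X'
    stays unambiguous.
    """

    records: list[AlignedRecord]
    n_columns: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentValidationError("alignment contains no sequences")
        lengths = {len(r.aligned_seq) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"unequal alignment lengths: {sorted(lengths)}"
            )
        self.n_columns = lengths.pop()
        if self.n_columns < 1:
            raise AlignmentValidationError("alignment has zero columns")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentValidationError(f"duplicate sequence ids: {dup}")
        for r in self.records:
            for col, ch in enumerate(r.aligned_seq, start=1):
                if ch != GAP and ch not in AA_LETTERS:
                    raise AlignmentValidationError(
                        f"illegal character {ch!r} in sequence {r.id!r} "
                        f"at column {col}"
                    )
        self._by_id = {r.id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, seq_id: str) -> AlignedRecord:
        try:
            return self._by_id[seq_id]
        except KeyError:
            raise KeyError(f"unknown sequence id {seq_id!r}") from None

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def groups_present(self) -> list[str]:
        seen: list[str] = []
        for r in self.records:
            if r.group not in seen:
                seen.append(r.group)
        return seen

    def ungapped(self, seq_id: str) -> str:
        return self[seq_id].aligned_seq.replace(GAP, "")


def read_alignment(
    path: str | Path,
    format: str = "fasta",
    group_map: Mapping[str, str] | None = None,
) -> AlignedFamily:
    """Read an aligned FASTA or Clustal file into an :class:`AlignedFamily`.

    ``group_map`` assigns a taxonomic group per sequence id; ids without a
    label default to ``"other"``. Record order is preserved.
    """
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {format!r}")
    group_map = dict(group_map or {})
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise AlignmentFormatError(
            f"could not parse {path} as {format}: "
            f"unequal alignment lengths or malformed file ({exc})"
        ) from exc
    records = [
        AlignedRecord(
            id=rec.id,
            group=group_map.get(rec.id, "other"),
            aligned_seq=str(rec.seq).upper(),
        )
        for rec in msa
    ]
    return AlignedFamily(records)


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (id<TAB>group) into a group map."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"expected 'id<TAB>group', got {line!r}")
        out[fields[0]] = fields[1]
    return out


def write_alignment(family: AlignedFamily, path: str | Path) -> None:
    """Write the family as aligned FASTA."""
    with open(path, "w") as fh:
        for r in family.records:
            fh.write(f">{r.id}\n{r.aligned_seq}\n")


def column_to_residue(
    family: AlignedFamily, seq_id: str, column: int
) -> int | None:
    """Map a 1-based alignment column to the sequence's own 1-based residue
    number, or ``None`` if the sequence has a gap at that column.

    This is the coordinate convention used to name mutations (e.g. residue
    124 of the target protein is "L124" regardless of alignment gaps).
    """
    rec = family[seq_id]
    if not 1 <= column <= family.n_columns:
        raise IndexError(
            f"column {column} out of range 1..{family.n_columns}"
        )
    prefix = rec.aligned_seq[:column]
    if prefix[-1] == GAP:
        return None
    return len(prefix) - prefix.count(GAP)


def residue_to_column(family: AlignedFamily, seq_id: str, residue: int) -> int:
    """Inverse of :func:`column_to_residue`: 1-based residue number to the
    1-based alignment column holding it."""
    rec = family[seq_id]
    if residue < 1:
        raise IndexError(f"residue number {residue} must be >= 1")
    count = 0
    for col, ch in enumerate(rec.aligned_seq, start=1):
        if ch != GAP:
            count += 1
            if count == residue:
                return col
    raise IndexError(
        f"sequence {seq_id!r} has only {count} residues; "
        f"residue {residue} out of range"
    )
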