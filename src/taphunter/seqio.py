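"""Peptide and protein I/O plus sliding-window cleavage.

Peptides live on the standard 20-letter amino-acid alphabet. Proteins read
from FASTA may additionally carry the ambiguity code ``X``; windows containing
``X`` are skipped at cleavage time (they cannot be encoded) without disturbing
the 1-based coordinate frame.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from .errors import ParseError, ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)
_AA_OR_X = _AA_SET | {"X"}

#: Length window for direct peptide prediction (the server's peptide mode).
MIN_PEPTIDE_LENGTH = 4
MAX_PEPTIDE_LENGTH = 21
#: Window-length bounds for protein scanning (the server's protein mode).
MIN_SCAN_LENGTH = 4
MAX_SCAN_LENGTH = 12


@dataclass(frozen=True)
class Peptide:
    """A validated peptide sequence (uppercase, 4-21 residues)."""

    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not (MIN_PEPTIDE_LENGTH <= len(seq) <= MAX_PEPTIDE_LENGTH):
            raise ValidationError(
                f"peptide length {len(seq)} outside allowed range "
                f"[{MIN_PEPTIDE_LENGTH}, {MAX_PEPTIDE_LENGTH}]: {seq!r}"
            )
        bad = set(seq) - _AA_SET
        if bad:
            raise ValidationError(
                f"illegal residue(s) {sorted(bad)} in peptide {seq!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence


@dataclass(frozen=True)
class ProteinRecord:
    """A FASTA protein record; unbounded length, may contain 'X'."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record with empty id")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _AA_OR_X
        if bad:
            raise ValidationError(
                f"illegal residue(s) {sorted(bad)} in protein {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledPeptideSet:
    """Ordered peptides with binary binder (+1) / non-binder (-1) labels.

    A sequence may appear at most once; re-insertion with a conflicting label
    is rejected so the set can never contain contradictory training records.
    """

    records: list[tuple[Peptide, int]] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for pep, label in self.records:
            if label not in (+1, -1):
                raise ValidationError(f"label must be +1 or -1, got {label!r}")
            prev = seen.get(pep.sequence)
            if prev is not None:
                kind = "conflicting" if prev != label else "duplicate"
                raise ValidationError(
                    f"{kind} record for peptide {pep.sequence!r}"
                )
            seen[pep.sequence] = label

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[Peptide, int]]:
        return iter(self.records)

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p, _ in self.records]

    @property
    def labels(self) -> list[int]:
        return [y for _, y in self.records]

    @property
    def n_pos(self) -> int:
        return sum(1 for _, y in self.records if y == +1)

    @property
    def n_neg(self) -> int:
        return sum(1 for _, y in self.records if y == -1)

    def require_both_classes(self) -> None:
        if self.n_pos == 0 or self.n_neg == 0:
            raise ValidationError(
                f"both classes required: n_pos={self.n_pos}, n_neg={self.n_neg}"
            )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record protein FASTA file.

    Sequences are uppercased; whitespace and trailing ``*`` stop codons are
    stripped. ``X`` is accepted (handled downstream at cleavage). Any other
    non-standard letter is a parse error naming the record and its line.
    """
    path = Path(path)
    # Record -> first line number, so parse errors can point at the file.
    start_lines: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                start_lines.append(lineno)
    if not start_lines:
        raise ParseError(f"{path}: no FASTA records found")

    records: list[ProteinRecord] = []
    seen_ids: set[str] = set()
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        line = start_lines[idx] if idx < len(start_lines) else -1
        seq = str(rec.seq).upper().replace(" ", "").rstrip("*")
        if not rec.id:
            raise ParseError(f"{path}:{line}: record {idx + 1} has empty id")
        if rec.id in seen_ids:
            raise ParseError(
                f"{path}:{line}: duplicate record id {rec.id!r} (record {idx + 1})"
            )
        if not seq:
            raise ParseError(
                f"{path}:{line}: record {idx + 1} ({rec.id!r}) has no sequence"
            )
        bad = set(seq) - _AA_OR_X
        if bad:
            raise ParseError(
                f"{path}:{line}: record {idx + 1} ({rec.id!r}) contains "
                f"illegal residue(s) {sorted(bad)}"
            )
        seen_ids.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


_LABEL_ALIASES = {
    "1": +1, "+1": +1, "binder": +1,
    "-1": -1, "nonbinder": -1, "non-binder": -1,
}


def _sniff_delimiter(header: str) -> str:
    return "\t" if "\t" in header else ","


def read_labeled_peptides(path: str | Path, name: str = "") -> LabeledPeptideSet:
    """Read a labeled peptide table (CSV or TSV, columns sequence,label).

    Labels may be ``1``/``-1`` or ``binder``/``nonbinder``. Row numbers in
    error messages are 1-based file lines.
    """
    path = Path(path)
    records: list[tuple[Peptide, int]] = []
    seen: dict[str, tuple[int, int]] = {}
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise ParseError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        header = [c.strip().lower() for c in first.strip().split(delim)]
        has_header = "sequence" in header
        rows = csv.reader(fh, delimiter=delim)
        pending: list[tuple[int, list[str]]] = []
        if not has_header:
            pending.append((1, [c.strip() for c in first.strip().split(delim)]))
        for lineno, row in enumerate(rows, start=2):
            if row and any(c.strip() for c in row):
                pending.append((lineno, row))
        for lineno, row in pending:
            if len(row) < 2:
                raise ParseError(f"{path}:{lineno}: expected sequence,label")
            seq_raw, label_raw = row[0].strip(), row[1].strip().lower()
            label = _LABEL_ALIASES.get(label_raw)
            if label is None:
                raise ParseError(
                    f"{path}:{lineno}: malformed label {row[1].strip()!r} "
                    "(expected 1/-1 or binder/nonbinder)"
                )
            try:
                pep = Peptide(seq_raw)
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            prev = seen.get(pep.sequence)
            if prev is not None:
                prev_line, prev_label = prev
                kind = "conflicting labels" if prev_label != label else "duplicate"
                raise ParseError(
                    f"{path}:{lineno}: {kind} for peptide {pep.sequence!r} "
                    f"(first seen at line {prev_line})"
                )
            seen[pep.sequence] = (lineno, label)
            records.append((pep, label))
    if not records:
        raise ParseError(f"{path}: no peptide records found")
    return LabeledPeptideSet(records=records, name=name or path.stem)


def write_labeled_peptides(pset: LabeledPeptideSet, path: str | Path) -> None:
    """Write a labeled set as CSV with header ``sequence,label``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sequence", "label"])
        for pep, label in pset:
            writer.writerow([pep.sequence, label])


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def cleave_protein(
    protein: ProteinRecord, k: int
) -> list[tuple[Peptide, int]]:
    """Cleave a protein into all overlapping k-mers, N to C.

    Returns ``(peptide, start)`` pairs with 1-based inclusive starts; for a
    protein of length L there are L - k + 1 windows. Windows containing the
    ambiguity code 'X' are skipped with a warning (they cannot be encoded)
    but do not shift the coordinates of later windows.
    """
    if not (MIN_SCAN_LENGTH <= k <= MAX_SCAN_LENGTH):
        raise ValidationError(
            f"scan window length k={k} outside allowed range "
            f"[{MIN_SCAN_LENGTH}, {MAX_SCAN_LENGTH}]"
        )
    seq = protein.sequence
    if len(seq) < k:
        warnings.warn(
            f"protein {protein.id!r} shorter than window ({len(seq)} < {k}); "
            "no peptides produced",
            stacklevel=2,
        )
        return []
    out: list[tuple[Peptide, int]] = []
    for start0 in range(len(seq) - k + 1):
        window = seq[start0 : start0 + k]
        if "X" in window:
            warnings.warn(
                f"protein {protein.id!r}: window at {start0 + 1} contains 'X'; "
                "skipped",
                stacklevel=2,
            )
            continue
        out.append((Peptide(window), start0 + 1))
    return out
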