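"""FASTA / label-table I/O and labeled protein datasets.

Sequences are validated against the 20 standard amino-acid one-letter
codes; ambiguity codes (B, Z, X, J, U, O) are rejected by default
because every downstream encoding is defined only on the standard
alphabet.  Label tables are two-column tab-separated text mapping
sequence ids to class names; class order is first appearance in the
label file so that per-class reports are reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AMINO_ACIDS)


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed."""


class SequenceValidationError(ValueError):
    """Raised when a sequence contains characters outside the standard alphabet."""


class LabelError(ValueError):
    """Raised for malformed or inconsistent label tables."""


def _validate_sequence(record_id: str, sequence: str) -> str:
    seq = sequence.upper()
    if not seq:
        raise SequenceValidationError(f"record {record_id!r}: empty sequence")
    bad = sorted(set(seq) - _STANDARD_SET)
    if bad:
        raise SequenceValidationError(
            f"record {record_id!r}: non-standard amino-acid character(s) {', '.join(bad)}"
        )
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier with a validated amino-acid sequence.

    Parameters
    ----------
    id : str
        Unique sequence identifier.
    sequence : str
        Amino-acid sequence over the 20 standard one-letter codes;
        case-normalized to upper on construction.
    label : str, optional
        Subcellular-location class name, when known.
    """

    id: str
    sequence: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _validate_sequence(self.id, self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)

    def with_label(self, label: str) -> "ProteinRecord":
        return replace(self, label=label)


@dataclass(frozen=True)
class LabeledDataset:
    """An ordered collection of protein records with a stable class order.

    ``classes`` lists the distinct class names in first-appearance order;
    every labeled record's class must be a member.
    """

    records: tuple[ProteinRecord, ...]
    classes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        records = tuple(self.records)
        object.__setattr__(self, "records", records)
        seen_ids: set[str] = set()
        for rec in records:
            if rec.id in seen_ids:
                raise ValueError(f"duplicate record id {rec.id!r} in dataset")
            seen_ids.add(rec.id)
        if not self.classes:
            inferred: list[str] = []
            for rec in records:
                if rec.label is not None and rec.label not in inferred:
                    inferred.append(rec.label)
            object.__setattr__(self, "classes", tuple(inferred))
        else:
            object.__setattr__(self, "classes", tuple(self.classes))
            known = set(self.classes)
            for rec in records:
                if rec.label is not None and rec.label not in known:
                    raise ValueError(
                        f"record {rec.id!r} has label {rec.label!r} not in classes"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def labels(self) -> tuple[Optional[str], ...]:
        return tuple(rec.label for rec in self.records)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.classes}
        for rec in self.records:
            if rec.label is not None:
                counts[rec.label] += 1
        return counts


def read_fasta(path: str | os.PathLike, *, drop_invalid: bool = False) -> list[ProteinRecord]:
    """Read a FASTA file into a list of :class:`ProteinRecord`.

    Order is preserved and sequences are upper-cased.  Records containing
    non-standard characters raise :class:`SequenceValidationError` naming
    the record and offending characters, unless ``drop_invalid`` is set,
    in which case they are silently dropped.
    """
    records: list[ProteinRecord] = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # biopython signals malformed input with ValueError
        raise FastaParseError(f"{path}: {exc}") from exc
    for entry in parsed:
        try:
            records.append(ProteinRecord(id=entry.id, sequence=str(entry.seq)))
        except SequenceValidationError:
            if not drop_invalid:
                raise
    return records


def write_fasta(path: str | os.PathLike, records: Iterable[ProteinRecord], *, width: int = 60) -> None:
    """Write records as multi-line FASTA wrapped at ``width`` characters."""
    with open(path, "w", encoding="utf-8") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for start in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[start : start + width] + "\n")


def read_labels(
    path: str | os.PathLike,
    records: Sequence[ProteinRecord],
    *,
    require_all: bool = True,
) -> LabeledDataset:
    """Attach class labels from a two-column tab-separated table.

    Classes are ordered by first appearance in the label file.  A label
    row naming an unknown record id, conflicting duplicate rows, or (when
    ``require_all``) a record without a label all raise :class:`LabelError`.
    """
    by_id = {rec.id: rec for rec in records}
    assignments: dict[str, str] = {}
    classes: list[str] = []
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise LabelError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            rec_id, cls = parts
            if rec_id not in by_id:
                raise LabelError(f"{path}:{lineno}: label for unknown record id {rec_id!r}")
            if rec_id in assignments and assignments[rec_id] != cls:
                raise LabelError(
                    f"{path}:{lineno}: conflicting labels for {rec_id!r}: "
                    f"{assignments[rec_id]!r} vs {cls!r}"
                )
            assignments[rec_id] = cls
            if cls not in classes:
                classes.append(cls)
    if require_all:
        missing = [rec.id for rec in records if rec.id not in assignments]
        if missing:
            raise LabelError(f"records with no label: {', '.join(missing)}")
    labeled = tuple(
        rec.with_label(assignments[rec.id]) if rec.id in assignments else rec
        for rec in records
    )
    return LabeledDataset(records=labeled, classes=tuple(classes))


def write_labels(path: str | os.PathLike, dataset: LabeledDataset) -> None:
    """Write the label table as tab-separated ``id<TAB>class`` lines."""
    with open(path, "w", encoding="utf-8") as handle:
        for rec in dataset.records:
            if rec.label is not None:
                handle.write(f"{rec.id}\t{rec.label}\n")


def filter_min_length(dataset: LabeledDataset, min_len: int) -> LabeledDataset:
    """Drop records shorter than ``min_len`` residues, preserving order.

    A record of exactly ``min_len`` residues is retained ("less than"
    semantics).  Idempotent; never raises on an empty result.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = tuple(rec for rec in dataset.records if len(rec) >= min_len)
    return LabeledDataset(records=kept, classes=dataset.classes)
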