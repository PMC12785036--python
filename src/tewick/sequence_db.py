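"""Labeled FASTA I/O, sequence sanitation and stratified dataset splits.

Training input is a FASTA file of TE consensus sequences whose headers
carry the class label, RepeatMasker-style: ``>name#Class``.  Sequences
are sanitized to the five-letter alphabet {A,C,G,T,N} and split per
class into train/validation/test partitions (default 75/15/10) with a
deterministic, seeded assignment.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .registry import ClassRegistry, DEFAULT_REGISTRY, RegistryError

logger = logging.getLogger(__name__)

ALPHABET = "ACGTN"
_NON_ACGT = re.compile(r"[^ACGT]")
_WS = re.compile(r"\s+")

DEFAULT_FRACTIONS = (0.75, 0.15, 0.10)


class SequenceError(ValueError):
    """Raised for malformed records (empty sequence, bad header...)."""


@dataclass(frozen=True)
class LabeledSequence:
    """A sanitized DNA sequence with an identifier and optional label."""

    id: str
    sequence: str
    label: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


def sanitize_sequence(raw: str, record_id: str = "<anonymous>") -> str:
    """Uppercase ``raw`` and map every non-ACGT character to N.

    Whitespace is removed first; an input that is empty afterwards is a
    record-level error naming ``record_id``.  Idempotent.
    """
    seq = _WS.sub("", raw).upper()
    if not seq:
        raise SequenceError(f"record {record_id!r}: empty sequence")
    return _NON_ACGT.sub("N", seq)


def parse_labeled_header(header: str, label_separator: str = "#") -> tuple[str, str]:
    """Split ``<id><separator><class>`` into its two parts.

    The last separator wins, so ids may themselves contain the
    separator character.
    """
    if label_separator not in header:
        raise SequenceError(
            f"malformed header (no {label_separator!r} separator): {header!r}")
    seq_id, _, label = header.rpartition(label_separator)
    if not seq_id or not label:
        raise SequenceError(f"malformed header: {header!r}")
    return seq_id, label


def read_labeled_fasta(path: str | Path,
                       label_separator: str = "#",
                       registry: ClassRegistry = DEFAULT_REGISTRY,
                       strict_labels: bool = True) -> list[LabeledSequence]:
    """Read a labeled FASTA file, sanitize and validate every record.

    Parameters
    ----------
    path
        FASTA file; multi-line and single-line bodies both accepted.
    label_separator
        Character separating sequence name from class in the header.
    registry
        Class registry the labels are validated against.
    strict_labels
        If True an unknown class label is a hard error; otherwise the
        record is skipped with a warning.

    Returns
    -------
    Records in file order, one :class:`LabeledSequence` each.
    """
    records: list[LabeledSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id, label = parse_labeled_header(rec.id, label_separator)
        if label not in registry:
            if strict_labels:
                raise RegistryError(
                    f"record {rec.id!r}: unknown class label {label!r}")
            logger.warning("skipping record %r: unknown class label %r",
                           rec.id, label)
            continue
        records.append(LabeledSequence(
            id=seq_id, sequence=sanitize_sequence(str(rec.seq), rec.id),
            label=label))
    return records


def read_fasta(path: str | Path) -> list[LabeledSequence]:
    """Read an unlabeled FASTA file (inference input); headers kept verbatim."""
    return [
        LabeledSequence(id=rec.id, sequence=sanitize_sequence(str(rec.seq), rec.id))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[LabeledSequence], path: str | Path,
                label_separator: str = "#", line_width: int = 70) -> None:
    """Write records as FASTA; labeled records get ``>id<sep>label`` headers."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if rec.label is None else f"{rec.id}{label_separator}{rec.label}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), line_width):
                fh.write(rec.sequence[i:i + line_width] + "\n")


# ---------------------------------------------------------------------------
# stratified splitting


def split_counts(n: int, fractions: Sequence[float] = DEFAULT_FRACTIONS) -> tuple[int, int, int]:
    """Per-class partition sizes for ``n`` members.

    Convention: train = floor(f_train * n); validation = round-half-up
    (f_val * n); test = remainder.  This is the convention the reference
    per-class tables follow.
    """
    f_train, f_val, f_test = fractions
    if abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_train = int(np.floor(f_train * n))
    n_val = int(np.floor(f_val * n + 0.5))  # round half up
    n_test = n - n_train - n_val
    if n_test < 0:  # pathological fractions on tiny classes
        n_val += n_test
        n_test = 0
    return n_train, n_val, n_test


@dataclass(frozen=True)
class DatasetSplits:
    """Disjoint train/validation/test partitions of a labeled dataset."""

    train: tuple[LabeledSequence, ...]
    validation: tuple[LabeledSequence, ...]
    test: tuple[LabeledSequence, ...]
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
    seed: int = 0

    @property
    def parts(self) -> dict[str, tuple[LabeledSequence, ...]]:
        return {"train": self.train, "validation": self.validation,
                "test": self.test}

    def class_counts(self, part: str) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.parts[part]:
            counts[rec.label] = counts.get(rec.label, 0) + 1
        return counts

    def manifest(self) -> list[tuple[str, str, str]]:
        """(id, class, partition) rows, train then validation then test."""
        rows = []
        for part, recs in self.parts.items():
            rows.extend((rec.id, rec.label or "", part) for rec in recs)
        return rows

    def write_manifest(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tclass\tpartition\n")
            for row in self.manifest():
                fh.write("\t".join(row) + "\n")


def split_dataset(data: Sequence[LabeledSequence],
                  fractions: Sequence[float] = DEFAULT_FRACTIONS,
                  seed: int = 0) -> DatasetSplits:
    """Per-class stratified split with a seeded random assignment.

    Every record must be labeled.  Within each class the members are
    shuffled by a generator derived from the master seed, then dealt
    out as train/validation/test according to :func:`split_counts`.
    Identical ``(data, seed)`` give identical splits.
    """
    by_class: dict[str, list[LabeledSequence]] = {}
    for rec in data:
        if rec.label is None:
            raise SequenceError(f"record {rec.id!r} is unlabeled; cannot split")
        by_class.setdefault(rec.label, []).append(rec)

    rng = np.random.default_rng(seed)
    train: list[LabeledSequence] = []
    val: list[LabeledSequence] = []
    test: list[LabeledSequence] = []
    # class iteration order = first-appearance order in the input, which is
    # deterministic for a fixed input
    for label, members in by_class.items():
        n = len(members)
        if n < 3:
            logger.warning("class %r has only %d member(s); some partitions "
                           "will be empty", label, n)
        n_train, n_val, _ = split_counts(n, fractions)
        perm = rng.permutation(n)
        shuffled = [members[i] for i in perm]
        train.extend(shuffled[:n_train])
        val.extend(shuffled[n_train:n_train + n_val])
        test.extend(shuffled[n_train + n_val:])
    return DatasetSplits(tuple(train), tuple(val), tuple(test),
                         tuple(fractions), seed)
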