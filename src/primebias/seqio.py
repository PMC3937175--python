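"""Sequence IO, barcode demultiplexing and insert extraction.

Reads of the synthetic-library construct carry a 4 bp sample barcode near
the 5' end and a 12 nt fully random insert between two fixed anchor
sequences.  This module parses FASTA/FASTQ, splits pooled reads by exact
barcode match, and pulls the random insert out of each read.

All coordinates are 0-based, half-open.  Reads are handled on the strand
as sequenced; no reverse-complement search is attempted, and anchor or
barcode matching is exact (a 4 bp barcode cannot tolerate mismatches).
Extraction failures are data, not exceptions: each failed read gets a
reason code so filtering losses stay accountable.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

READ_ALPHABET = frozenset("ACGTN")

#: reason codes attached to failed insert extractions
ANCHOR_MISSING = "anchor_missing"
ANCHOR_MULTIPLE = "anchor_multiple"
BAD_SPACING = "bad_spacing"
CONTAINS_N = "contains_N"


class ParseError(ValueError):
    """A sequence file record could not be parsed."""


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: identifier plus base string over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"read {self.id!r} has an empty sequence")
        if not READ_ALPHABET.issuperset(self.seq):
            bad = sorted(set(self.seq) - READ_ALPHABET)
            raise ValueError(f"read {self.id!r} contains bases outside ACGTN: {bad}")


@dataclass(frozen=True)
class LibraryDesign:
    """Layout of the synthetic-library read.

    barcode_offset
        0-based position of the 4 bp sample barcode in the read.
    left_anchor / right_anchor
        Fixed sequences immediately 5' and 3' of the random insert.
    insert_len
        Length of the fully random region (12 in the reference design).
    """

    barcode_offset: int = 0
    left_anchor: str = "TCAGTGGCCTCTGCAT"
    insert_len: int = 12
    right_anchor: str = "CTGAGCGATACGGTAG"

    def __post_init__(self):
        if not self.left_anchor or not self.right_anchor:
            raise ValueError("anchors must be non-empty")
        if self.left_anchor in self.right_anchor or self.right_anchor in self.left_anchor:
            raise ValueError("anchors must be disjoint (neither contained in the other)")
        if self.barcode_offset < 0:
            raise ValueError("barcode_offset must be non-negative")
        if self.insert_len < 1:
            raise ValueError("insert_len must be positive")

    @classmethod
    def from_file(cls, path) -> "LibraryDesign":
        """Load from a key=value config file (``#`` starts a comment)."""
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key in ("barcode_offset", "insert_len"):
                kwargs[key] = int(value)
            elif key in ("left_anchor", "right_anchor"):
                kwargs[key] = value.upper()
            else:
                raise ParseError(f"{path}:{lineno}: unknown design key {key!r}")
        return cls(**kwargs)

    def to_file(self, path) -> None:
        Path(path).write_text(
            f"barcode_offset={self.barcode_offset}\n"
            f"left_anchor={self.left_anchor}\n"
            f"insert_len={self.insert_len}\n"
            f"right_anchor={self.right_anchor}\n"
        )


@dataclass(frozen=True)
class BarcodeTable:
    """Sample-name <-> barcode assignments, one row per pooled sample."""

    entries: tuple = ()  # of (sample_name, barcode, description)

    def __post_init__(self):
        barcodes = [barcode for _, barcode, _ in self.entries]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("barcodes must be unique")
        if len({len(barcode) for barcode in barcodes}) > 1:
            raise ValueError("all barcodes must have the same length")
        for _, barcode, _ in self.entries:
            if not set(barcode) <= set("ACGT"):
                raise ValueError(f"barcode {barcode!r} contains a base outside ACGT")

    @property
    def barcode_length(self) -> int:
        return len(self.entries[0][1]) if self.entries else 0

    @property
    def samples(self) -> list[str]:
        return [sample for sample, _, _ in self.entries]

    def barcode_of(self, sample: str) -> str:
        for name, barcode, _ in self.entries:
            if name == sample:
                return barcode
        raise KeyError(sample)

    @classmethod
    def from_csv(cls, path) -> "BarcodeTable":
        with open(path, newline="") as handle:
            reader = csv.DictReader(handle)
            required = {"sample", "barcode"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise ParseError(f"{path}: barcode table needs columns sample,barcode[,description]")
            entries = tuple(
                (row["sample"], row["barcode"].upper(), row.get("description", "") or "")
                for row in reader
            )
        return cls(entries)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(["sample", "barcode", "description"])
            writer.writerows(self.entries)


def read_sequences(path, format: str = None) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a FASTA or 4-line FASTQ file, in file order.

    ``format`` is ``"fasta"`` or ``"fastq"``; inferred from the suffix when
    omitted.  A malformed record raises :class:`ParseError` naming the
    0-based index of the offending record.
    """
    path = Path(path)
    if format is None:
        format = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    index = 0
    parser = SeqIO.parse(str(path), format)
    while True:
        try:
            record = next(parser)
        except StopIteration:
            return
        except ValueError as exc:
            raise ParseError(f"{path}: malformed {format} record at index {index}: {exc}") from exc
        yield ReadRecord(id=record.id, seq=str(record.seq).upper())
        index += 1


def write_sequences(records: Iterable[ReadRecord], path, format: str = None,
                    quality_char: str = "I") -> int:
    """Write records as FASTA or FASTQ (constant quality); returns the count."""
    path = Path(path)
    if format is None:
        format = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    n = 0
    with open(path, "w") as handle:
        for record in records:
            if format == "fastq":
                handle.write(f"@{record.id}\n{record.seq}\n+\n{quality_char * len(record.seq)}\n")
            else:
                handle.write(f">{record.id}\n{record.seq}\n")
            n += 1
    return n


def demultiplex(reads: Iterable[ReadRecord], table: BarcodeTable,
                design: LibraryDesign):
    """Split reads into per-sample buckets by exact barcode match.

    Returns ``(buckets, unassigned)``: every input read lands in exactly
    one sample bucket or in the unassigned list (reads too short to carry
    a barcode, or with no exact match).
    """
    lookup = {barcode: sample for sample, barcode, _ in table.entries}
    blen = table.barcode_length
    offset = design.barcode_offset
    buckets: dict[str, list[ReadRecord]] = {sample: [] for sample in table.samples}
    unassigned: list[ReadRecord] = []
    for read in reads:
        sample = None
        if len(read.seq) >= offset + blen:
            sample = lookup.get(read.seq[offset:offset + blen])
        if sample is None:
            unassigned.append(read)
        else:
            buckets[sample].append(read)
    return buckets, unassigned


def _count_overlapping(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        start = haystack.find(needle, start)
        if start < 0:
            return count
        count += 1
        start += 1


@dataclass(frozen=True)
class InsertResult:
    """Outcome of one insert extraction: the 12-mer or a reason code."""

    insert: str | None = None
    reason: str | None = None

    @property
    def ok(self) -> bool:
        return self.insert is not None


def extract_insert(read: ReadRecord, design: LibraryDesign) -> InsertResult:
    """Pull the random insert out of one read.

    Succeeds only when both anchors occur exactly once, are separated by
    exactly ``insert_len`` bases, and the insert is N-free; otherwise the
    result carries one of the reason codes
    ``anchor_missing | anchor_multiple | bad_spacing | contains_N``.
    """
    seq = read.seq
    n_left = _count_overlapping(seq, design.left_anchor)
    n_right = _count_overlapping(seq, design.right_anchor)
    if n_left == 0 or n_right == 0:
        return InsertResult(reason=ANCHOR_MISSING)
    if n_left > 1 or n_right > 1:
        return InsertResult(reason=ANCHOR_MULTIPLE)
    start = seq.index(design.left_anchor) + len(design.left_anchor)
    end = seq.index(design.right_anchor)
    if end - start != design.insert_len:
        return InsertResult(reason=BAD_SPACING)
    insert = seq[start:end]
    if "N" in insert:
        return InsertResult(reason=CONTAINS_N)
    return InsertResult(insert=insert)


def extract_inserts(reads: Iterable[ReadRecord], design: LibraryDesign):
    """Extract inserts in bulk.

    Returns ``(inserts, failures)`` where ``inserts`` is a numpy array of
    fixed-width byte strings (dtype ``S<insert_len>``) and ``failures``
    counts reads per reason code.
    """
    inserts: list[str] = []
    failures: Counter = Counter()
    for read in reads:
        result = extract_insert(read, design)
        if result.ok:
            inserts.append(result.insert)
        else:
            failures[result.reason] += 1
    return np.asarray(inserts, dtype=f"S{design.insert_len}"), failures
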