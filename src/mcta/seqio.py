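"""Sequence and tabular I/O: FASTA, paired FASTQ, BLAST outfmt-6, truth TSV.

Parsing of FASTA/FASTQ is delegated to Biopython's ``SeqIO``; this module
adds the conventions the pipeline relies on: uppercased sequences over
{A,C,G,T,N}, ``/1``–``/2`` mate suffixes for read pairs, and plain-TSV
carriers for ground truth and precomputed alignment hits.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from itertools import zip_longest
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

from Bio import SeqIO

_ALLOWED = set("ACGTN")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str
    description: str | None = None

    def __post_init__(self):
        if not self.id:
            raise FormatError("empty sequence id")
        if not self.sequence:
            raise FormatError(f"empty sequence for {self.id!r}")


@dataclass(frozen=True)
class ReadPairRecord:
    pair_id: str
    mate1: SequenceRecord
    mate2: SequenceRecord


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth origin of one read: source genome, 0-based start, strand."""

    read_id: str
    genome_id: str
    start: int
    strand: str  # "+" or "-"

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start for {self.read_id!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


def _clean_sequence(seq: str, rec_id: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _ALLOWED
    if bad:
        raise FormatError(f"record {rec_id!r}: illegal characters {sorted(bad)}")
    return seq


def _as_handle(source) -> tuple[TextIO, bool]:
    if isinstance(source, (str, Path)):
        return open(source, "rt", encoding="utf-8", newline=""), True
    return source, False


def read_fasta(source) -> list[SequenceRecord]:
    """Read FASTA records in file order.

    The id is the header token before the first whitespace; the remainder,
    if any, becomes the description.  Multi-line sequences are joined and
    uppercased.  An empty file yields an empty list; sequence data before
    any header is a :class:`FormatError`.
    """
    handle, close = _as_handle(source)
    try:
        text_peeked = handle.read()
    finally:
        if close:
            handle.close()
    stripped = text_peeked.lstrip()
    if stripped and not stripped.startswith(">"):
        raise FormatError("sequence data before first FASTA header")
    out: list[SequenceRecord] = []
    for rec in SeqIO.parse(io.StringIO(text_peeked), "fasta"):
        desc = rec.description[len(rec.id):].strip() or None
        out.append(
            SequenceRecord(
                id=rec.id,
                sequence=_clean_sequence(str(rec.seq), rec.id),
                description=desc,
            )
        )
    return out


def write_fasta(records: Iterable[SequenceRecord], stream: TextIO, width: int = 80) -> None:
    """Write FASTA wrapped to ``width`` columns.

    Note that an id containing whitespace is not round-trippable: only the
    first token is recovered on read.
    """
    for rec in records:
        header = rec.id if not rec.description else f"{rec.id} {rec.description}"
        stream.write(f">{header}\n")
        seq = rec.sequence
        for i in range(0, len(seq), width):
            stream.write(seq[i : i + width] + "\n")


def _fastq_records(source) -> Iterator[SequenceRecord]:
    handle, close = _as_handle(source)
    try:
        for rec in SeqIO.parse(handle, "fastq"):
            yield SequenceRecord(id=rec.id, sequence=_clean_sequence(str(rec.seq), rec.id))
    finally:
        if close:
            handle.close()


def read_fastq_pairs(source1, source2) -> list[ReadPairRecord]:
    """Read two synchronized FASTQ streams into mate pairs.

    Mate ids must be ``<pair_id>/1`` and ``<pair_id>/2``; qualities are
    parsed (Sanger encoding) but discarded.  A record-count mismatch
    between the streams is a :class:`FormatError`.
    """
    pairs: list[ReadPairRecord] = []
    sentinel = object()
    for m1, m2 in zip_longest(_fastq_records(source1), _fastq_records(source2), fillvalue=sentinel):
        if m1 is sentinel or m2 is sentinel:
            raise FormatError("FASTQ mate files have different record counts")
        if not m1.id.endswith("/1") or not m2.id.endswith("/2"):
            raise FormatError(f"mate ids must end in /1 and /2: {m1.id!r}, {m2.id!r}")
        pid1, pid2 = m1.id[:-2], m2.id[:-2]
        if pid1 != pid2:
            raise FormatError(f"unpaired mates {m1.id!r} / {m2.id!r}")
        pairs.append(ReadPairRecord(pair_id=pid1, mate1=m1, mate2=m2))
    return pairs


def write_fastq(records: Iterable[SequenceRecord], stream: TextIO, quality_char: str = "I") -> None:
    """Write FASTQ with a constant placeholder quality (qualities are unused)."""
    for rec in records:
        stream.write(f"@{rec.id}\n{rec.sequence}\n+\n{quality_char * len(rec.sequence)}\n")


def read_tabular_hits(source) -> list[tuple[str, str, float]]:
    """Read BLAST outfmt-6 rows as (query_id, subject_id, bitscore).

    Columns 1, 2 and 12 are used; the rest are ignored.  Rows with fewer
    than 12 columns raise :class:`FormatError`.
    """
    handle, close = _as_handle(source)
    out: list[tuple[str, str, float]] = []
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"line {lineno}: expected 12 columns, got {len(fields)}")
            try:
                score = float(fields[11])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: bad bitscore {fields[11]!r}") from exc
            out.append((fields[0], fields[1], score))
    finally:
        if close:
            handle.close()
    return out


def read_truth(source) -> list[TruthRecord]:
    """Read the truth TSV (read_id, genome_id, start, strand)."""
    handle, close = _as_handle(source)
    out: list[TruthRecord] = []
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"line {lineno}: expected 4 columns, got {len(fields)}")
            out.append(
                TruthRecord(
                    read_id=fields[0],
                    genome_id=fields[1],
                    start=int(fields[2]),
                    strand=fields[3],
                )
            )
    finally:
        if close:
            handle.close()
    return out


def write_truth(records: Sequence[TruthRecord], stream: TextIO) -> None:
    stream.write("#read_id\tgenome_id\tstart\tstrand\n")
    for r in records:
        stream.write(f"{r.read_id}\t{r.genome_id}\t{r.start}\t{r.strand}\n")
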