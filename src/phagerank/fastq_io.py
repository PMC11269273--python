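"""Strict 4-line FASTQ input/output.

This is the only module that touches raw sequencing files.  Records are
read and written in the plain 4-line layout (``@id``, sequence, ``+``,
quality); wrapped/multi-line FASTQ is rejected.  Gzip-compressed files are
accepted transparently when the path ends in ``.gz``.

Quality strings are validated structurally (same length as the sequence)
but are never interpreted: downstream analysis is quality-agnostic.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator


class FastqFormatError(ValueError):
    """Raised when a FASTQ file violates the strict 4-line record layout."""


@dataclass(frozen=True)
class FastqRecord:
    """One sequencing read.

    Attributes
    ----------
    read_id : str
        Identifier as it appears after ``@``, without the ``@``.
    sequence : str
        Nucleotide string, uppercased on ingest.  May contain non-ACGT
        symbols such as ``N``; those are handled downstream.
    quality : str
        Phred string of the same length as ``sequence``.  Kept only for
        round-trip fidelity.
    """

    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("FastqRecord read_id must be non-empty")
        if len(self.quality) != len(self.sequence):
            raise ValueError(
                f"quality length {len(self.quality)} != sequence length "
                f"{len(self.sequence)} for read {self.read_id!r}"
            )


def _open_text(path: Path, mode: str) -> IO[str]:
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, mode + "b"), encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Stream records from a strict 4-line FASTQ file.

    Sequences are uppercased.  An empty file yields an empty stream.

    Raises
    ------
    FastqFormatError
        If a record lacks the ``@``/``+`` markers, the quality line is a
        different length than the sequence, or the file ends mid-record.
        The error message names the 1-based record index.
    """
    path = Path(path)
    with _open_text(path, "r") as handle:
        record_index = 0
        while True:
            header = handle.readline()
            if header == "":
                return
            record_index += 1
            header = header.rstrip("\n")
            if not header.startswith("@") or len(header) < 2:
                raise FastqFormatError(
                    f"record {record_index}: header line must start with '@' "
                    f"followed by an id, got {header!r}"
                )
            seq = handle.readline()
            plus = handle.readline()
            qual = handle.readline()
            if qual == "" and not plus:
                raise FastqFormatError(
                    f"record {record_index}: truncated record (file ends "
                    "before the quality line)"
                )
            seq = seq.rstrip("\n")
            plus = plus.rstrip("\n")
            qual = qual.rstrip("\n")
            if not plus.startswith("+"):
                raise FastqFormatError(
                    f"record {record_index}: separator line must start with "
                    f"'+', got {plus!r} (wrapped multi-line FASTQ is not "
                    "supported)"
                )
            if len(qual) != len(seq):
                raise FastqFormatError(
                    f"record {record_index}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            yield FastqRecord(
                read_id=header[1:], sequence=seq.upper(), quality=qual
            )


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> int:
    """Write records as strict 4-line FASTQ; returns the record count."""
    path = Path(path)
    n = 0
    with _open_text(path, "w") as handle:
        for record in records:
            handle.write(
                f"@{record.read_id}\n{record.sequence}\n+\n{record.quality}\n"
            )
            n += 1
    return n
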