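"""Streaming multi-FASTA input.

Alignments are read sequentially, one record at a time, so memory stays
bounded by a single sequence regardless of how many taxa the file holds.
Gzip compression is detected from the magic bytes (``1f 8b``), never from
the file extension, and a source can be reopened for the algorithm's second
pass. An optional byte counter at the raw file layer lets callers verify
the two-pass I/O envelope.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass
from itertools import chain
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser

GZIP_MAGIC = b"\x1f\x8b"


class FastaIOError(Exception):
    """Base class for alignment input errors."""


class MalformedFastaError(FastaIOError):
    """The input is not well-formed multi-FASTA."""


class UnequalLengthError(FastaIOError):
    """A sequence's length differs from the alignment length."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One named, aligned nucleotide sequence.

    ``id`` is the FASTA header up to the first whitespace; ``sequence`` is
    the full aligned row with original case and gap characters preserved.
    """

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentDimensions:
    """Alignment shape: ``s`` taxa by ``g`` columns."""

    s: int
    g: int


class _CountingRaw(io.RawIOBase):
    """Raw reader that forwards to an underlying file and counts bytes.

    Counting happens below any gzip layer, so for compressed input the
    tally is compressed (on-disk) bytes — the quantity the I/O envelope
    ``2f <= I/O <= 2f + o`` is stated in.
    """

    def __init__(self, raw: IO[bytes], counter: "IOCounter") -> None:
        super().__init__()
        self._raw = raw
        self._counter = counter

    def readable(self) -> bool:  # pragma: no cover - io protocol
        return True

    def readinto(self, b) -> int:
        n = self._raw.readinto(b)
        self._counter.bytes_read += n
        return n

    def close(self) -> None:
        try:
            self._raw.close()
        finally:
            super().close()


class IOCounter:
    """Accumulates bytes read and written across passes."""

    def __init__(self) -> None:
        self.bytes_read = 0
        self.bytes_written = 0


class CountingTextSink:
    """Text sink wrapper that counts characters written to it."""

    def __init__(self, sink: IO[str], counter: IOCounter) -> None:
        self._sink = sink
        self.counter = counter

    def write(self, text: str) -> int:
        n = self._sink.write(text)
        self.counter.bytes_written += len(text)
        return n

    def flush(self) -> None:
        self._sink.flush()


def open_alignment_stream(
    path: Union[str, Path], counter: Optional[IOCounter] = None
) -> IO[str]:
    """Open a plain or gzipped FASTA file as a text stream.

    Compression is recognised by the gzip magic bytes, not the filename.
    Pass an :class:`IOCounter` to tally raw (on-disk) bytes as they are
    consumed.

    Raises
    ------
    FastaIOError
        If the path does not exist or a gzip stream cannot be decoded.
    """
    path = Path(path)
    try:
        raw: IO[bytes] = open(path, "rb", buffering=0)
    except OSError as exc:
        raise FastaIOError(f"cannot open alignment file '{path}': {exc.strerror}") from exc
    if counter is not None:
        raw = io.BufferedReader(_CountingRaw(raw, counter))
    else:
        raw = io.BufferedReader(raw)  # type: ignore[arg-type]
    if raw.peek(2)[:2] == GZIP_MAGIC:
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="ascii")
    return io.TextIOWrapper(raw, encoding="ascii")


class AlignmentSource:
    """A re-openable alignment input for the two-pass algorithm.

    Wraps a file path; each :meth:`open` returns a fresh text stream over
    the (possibly gzip-compressed) FASTA content. ``passes`` counts how
    many times the file has been opened and ``counter.bytes_read`` the raw
    bytes consumed so far, which lets tests pin the algorithm to exactly
    two full reads of the input.
    """

    def __init__(self, path: Union[str, Path]) -> None:
        self.path = Path(path)
        self.counter = IOCounter()
        self.passes = 0

    def open(self) -> IO[str]:
        self.passes += 1
        return open_alignment_stream(self.path, self.counter)

    @property
    def bytes_read(self) -> int:
        return self.counter.bytes_read

    def records(self) -> Iterator[AlignmentRecord]:
        """One full streaming pass over the records."""
        with self.open() as stream:
            yield from iterate_records(stream)


def iterate_records(stream: IO[str]) -> Iterator[AlignmentRecord]:
    """Yield :class:`AlignmentRecord` objects from a FASTA text stream.

    Sequence lines are concatenated with line breaks removed; blank lines
    and CRLF endings are tolerated. Parsing is single pass and buffers one
    record at a time.

    Raises
    ------
    MalformedFastaError
        If the first non-blank character is not ``>``, or a record has an
        empty identifier or empty sequence.
    """
    # SimpleFastaParser silently skips preamble text, but a file whose
    # first non-blank character is not '>' is not FASTA: reject it here.
    first_line = None
    for line in stream:
        if line.strip():
            first_line = line
            break
    if first_line is None:
        return
    if not first_line.lstrip().startswith(">"):
        raise MalformedFastaError(
            "malformed FASTA: first non-blank character is not '>'"
        )

    seen: set[str] = set()
    for title, sequence in SimpleFastaParser(chain([first_line], stream)):
        name = title.split(None, 1)[0] if title.split() else ""
        if not name:
            raise MalformedFastaError("malformed FASTA: record with empty identifier")
        if not sequence:
            raise MalformedFastaError(
                f"malformed FASTA: record '{name}' has an empty sequence"
            )
        if name in seen:
            warnings.warn(
                f"duplicate sample id '{name}' in alignment; output is positional",
                stacklevel=2,
            )
        seen.add(name)
        yield AlignmentRecord(id=name, sequence=sequence)


def validate_alignment(records: Iterable[AlignmentRecord]) -> AlignmentDimensions:
    """Check equal sequence lengths incrementally and return ``(s, g)``.

    Raises
    ------
    UnequalLengthError
        Naming the first record whose length differs from the first
        record's length.
    MalformedFastaError
        If the alignment holds no records.
    """
    s = 0
    g = -1
    for record in records:
        if g < 0:
            g = len(record)
        elif len(record) != g:
            raise UnequalLengthError(
                f"sequence '{record.id}' has length {len(record)}, "
                f"expected alignment length {g}"
            )
        s += 1
    if s == 0:
        raise MalformedFastaError("alignment contains no records")
    return AlignmentDimensions(s=s, g=g)


def write_fasta(records: Iterable[AlignmentRecord], sink: IO[str]) -> None:
    """Serialize records as unwrapped FASTA (one sequence line per record)."""
    for record in records:
        sink.write(f">{record.id}\n{record.sequence}\n")
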