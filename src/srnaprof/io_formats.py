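"""Input/output for the three accepted read encodings.

Small RNA pipelines accept plain FASTQ, plain FASTA, and *read-count FASTA*:
a FASTA file in which every header ends in ``<separator><integer>`` giving the
multiplicity of the (unique) sequence, e.g. ``>read_1#5231``.  Because users
routinely mislabel file extensions, the format is detected from content, never
from the file name.  All downstream stages consume :class:`CollapsedRead`
(unique sequence + count), so plain FASTQ/FASTA streams are collapsed first.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

__all__ = [
    "SequenceRecord",
    "CollapsedRead",
    "Format",
    "FormatKind",
    "CANDIDATE_SEPARATORS",
    "UnrecognizedFormat",
    "AmbiguousReadcount",
    "MalformedRecord",
    "detect_format",
    "read_records",
    "collapse",
    "write_readcount",
]

#: Read-count header separators tried in order. Every header in the sampled
#: file head must parse with the *same* separator for detection to succeed.
#: Bare "_" is deliberately absent: genomic ids like ``chr_region_1`` end in
#: ``_<integer>`` without being counts, so "_" is only honored in the common
#: ``_x<count>`` spelling.
CANDIDATE_SEPARATORS: tuple[str, ...] = ("#", "-", "_x", ":")

_DETECTION_SAMPLE_LINES = 40  # bounded memory on arbitrarily large files

_VALID_SEQ = re.compile(r"^[ACGTNacgtnUu]+$")


class UnrecognizedFormat(ValueError):
    """File head matches none of FASTQ / FASTA / read-count FASTA."""


class AmbiguousReadcount(ValueError):
    """Headers carry count tokens but no single separator fits all of them."""


class MalformedRecord(ValueError):
    """A record violates its format's contract; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message} (line {line})" if line is not None else message)


class Format(Enum):
    FASTQ = "fastq"
    FASTA = "fasta"
    READCOUNT = "readcount"


@dataclass(frozen=True)
class FormatKind:
    """A detected input format; ``separator`` is set iff kind is READCOUNT."""

    kind: Format
    separator: str | None = None

    def __post_init__(self) -> None:
        if (self.kind is Format.READCOUNT) != (self.separator is not None):
            raise ValueError("separator must be set iff kind is READCOUNT")


@dataclass
class SequenceRecord:
    """One read: id, upper-case DNA over {A,C,G,T,N}, optional Phred scores.

    U is normalized to T on read; qualities are present iff the source was
    FASTQ and always match the sequence length.
    """

    id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError("qualities length must equal sequence length")


@dataclass(frozen=True)
class CollapsedRead:
    """A unique read sequence with its multiplicity."""

    sequence: str
    count: int
    rank_id: str = ""

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _open_text(path: str | Path) -> IO[str]:
    """Open possibly-gzipped file as text, sniffing the gzip magic bytes."""
    raw = open(path, "rb")
    head = raw.read(2)
    raw.seek(0)
    if head == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    return io.TextIOWrapper(raw)


def _readcount_separator(headers: Sequence[str]) -> str | None:
    """Return the unique candidate separator under which every header is
    ``token<sep>integer``, or None. Raises AmbiguousReadcount when different
    headers demand different separators."""
    fits: list[str] = []
    for sep in CANDIDATE_SEPARATORS:
        ok = True
        for h in headers:
            name, s, tail = h.rpartition(sep)
            if not s or not name or not tail.isdigit():
                ok = False
                break
        if ok:
            fits.append(sep)
    if fits:
        return fits[0]
    # No unanimous separator: ambiguous if headers individually parse under
    # some separator but disagree on which.
    per_header = []
    for h in headers:
        opts = {
            sep
            for sep in CANDIDATE_SEPARATORS
            if (p := h.rpartition(sep))[1] and p[0] and p[2].isdigit()
        }
        per_header.append(opts)
    if all(per_header) and not set.intersection(*per_header):
        raise AmbiguousReadcount(
            "read-count headers parse under conflicting separators"
        )
    return None


def detect_format(first_bytes: str | bytes) -> FormatKind:
    """Detect FASTQ / FASTA / read-count FASTA from a sample of the file head.

    Detection is content-based (extension-blind). The sample must contain at
    least one complete record. Read-count FASTA requires every sampled header
    to parse as ``>name<sep>count`` with one consistent separator from
    :data:`CANDIDATE_SEPARATORS`.
    """
    if isinstance(first_bytes, bytes):
        if first_bytes[:2] == b"\x1f\x8b":
            first_bytes = gzip.decompress(first_bytes)
        first_bytes = first_bytes.decode("ascii", errors="replace")
    lines = [ln.strip() for ln in first_bytes.splitlines() if ln.strip()]
    lines = lines[:_DETECTION_SAMPLE_LINES]
    if not lines:
        raise UnrecognizedFormat("empty input")

    if lines[0].startswith("@"):
        # FASTQ: 4-line records @id / seq / + / qual
        complete = len(lines) // 4
        ok = complete >= 1 or (
            len(lines) >= 2 and _VALID_SEQ.match(lines[1])
        )
        for i in range(complete):
            rid, seq, plus, qual = lines[4 * i : 4 * i + 4]
            if not (rid.startswith("@") and plus.startswith("+")):
                ok = False
                break
            if not _VALID_SEQ.match(seq) or len(qual) != len(seq):
                ok = False
                break
        if ok:
            return FormatKind(Format.FASTQ)
        raise UnrecognizedFormat("'@' header but not 4-line FASTQ structure")

    if lines[0].startswith(">"):
        headers = [ln[1:].split()[0] for ln in lines if ln.startswith(">")]
        sep = _readcount_separator(headers)
        if sep is not None:
            return FormatKind(Format.READCOUNT, separator=sep)
        return FormatKind(Format.FASTA)

    raise UnrecognizedFormat("input starts with neither '@' nor '>'")


def detect_format_file(path: str | Path) -> FormatKind:
    """Detect the format of a (possibly gzipped) file from its head."""
    with _open_text(path) as fh:
        sample: list[str] = []
        for line in fh:
            if line.strip():
                sample.append(line)
            if len(sample) >= _DETECTION_SAMPLE_LINES:
                break
    return detect_format("".join(sample))


def _iter_fastq(fh: IO[str]) -> Iterator[SequenceRecord]:
    lineno = 0
    while True:
        block: list[str] = []
        start = lineno + 1
        for _ in range(4):
            line = fh.readline()
            if not line:
                break
            lineno += 1
            block.append(line.rstrip("\n"))
        if not block or (len(block) == 1 and not block[0].strip()):
            return
        if len(block) < 4:
            raise MalformedRecord("truncated FASTQ record", start)
        rid, seq, plus, qual = block
        if not rid.startswith("@") or not plus.startswith("+"):
            raise MalformedRecord("FASTQ record lacks '@'/'+' lines", start)
        if len(seq) != len(qual):
            raise MalformedRecord("sequence/quality length mismatch", start)
        yield SequenceRecord(
            id=rid[1:].split()[0] if len(rid) > 1 else "",
            sequence=_normalize(seq),
            qualities=[ord(c) - 33 for c in qual],
        )


def _iter_fasta(fh: IO[str]) -> Iterator[tuple[str, str, int]]:
    """Yield (header, sequence, header_lineno) tuples from wrapped or
    unwrapped FASTA."""
    header: str | None = None
    hline = 0
    chunks: list[str] = []
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            if header is not None:
                yield header, "".join(chunks), hline
            header, hline, chunks = line[1:].split()[0], lineno, []
        else:
            if header is None:
                raise MalformedRecord("sequence data before FASTA header", lineno)
            chunks.append(line.strip())
    if header is not None:
        yield header, "".join(chunks), hline


def read_records(
    path: str | Path, kind: FormatKind | None = None
) -> Iterator[SequenceRecord] | Iterator[CollapsedRead]:
    """Stream records from *path* under *kind* (auto-detected when omitted).

    FASTQ/FASTA yield :class:`SequenceRecord`; read-count FASTA yields
    :class:`CollapsedRead`. Gzip is handled transparently; U is normalized
    to T.
    """
    if kind is None:
        kind = detect_format_file(path)
    if kind.kind is Format.FASTQ:
        def gen_fq() -> Iterator[SequenceRecord]:
            with _open_text(path) as fh:
                yield from _iter_fastq(fh)
        return gen_fq()
    if kind.kind is Format.FASTA:
        def gen_fa() -> Iterator[SequenceRecord]:
            with _open_text(path) as fh:
                for header, seq, lineno in _iter_fasta(fh):
                    if not seq:
                        raise MalformedRecord("empty FASTA record", lineno)
                    yield SequenceRecord(id=header, sequence=_normalize(seq))
        return gen_fa()

    sep = kind.separator
    assert sep is not None

    def gen_rc() -> Iterator[CollapsedRead]:
        with _open_text(path) as fh:
            for header, seq, lineno in _iter_fasta(fh):
                name, s, tail = header.rpartition(sep)
                if not s or not name or not tail.isdigit():
                    raise MalformedRecord(
                        f"header does not match name{sep}count", lineno
                    )
                if not seq:
                    raise MalformedRecord("empty read-count record", lineno)
                yield CollapsedRead(
                    sequence=_normalize(seq), count=int(tail), rank_id=name
                )

    return gen_rc()


def collapse(reads: Iterable[str | SequenceRecord]) -> list[CollapsedRead]:
    """Collapse a stream of sequences into unique reads with counts.

    Output is sorted by descending count, ties broken lexicographically by
    sequence; ``rank_id`` reflects that rank. Total count is conserved.
    """
    counts: dict[str, int] = {}
    for r in reads:
        seq = r.sequence if isinstance(r, SequenceRecord) else _normalize(r)
        counts[seq] = counts.get(seq, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        CollapsedRead(sequence=seq, count=n, rank_id=f"read_{i}")
        for i, (seq, n) in enumerate(ordered, start=1)
    ]


def write_readcount(
    collapsed: Iterable[CollapsedRead],
    path: str | Path,
    separator: str = "#",
) -> None:
    """Write collapsed reads as read-count FASTA: ``>rank_id<sep>count``.

    Round-trips exactly through :func:`read_records` for every candidate
    separator.
    """
    if separator not in CANDIDATE_SEPARATORS:
        raise ValueError(f"separator {separator!r} not in candidate set")
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:  # type: ignore[operator]
        for i, cr in enumerate(collapsed, start=1):
            name = cr.rank_id or f"read_{i}"
            fh.write(f">{name}{separator}{cr.count}\n{cr.sequence}\n")
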