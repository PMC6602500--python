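"""Library-mode alignment of collapsed reads against reference sequences.

Reads are mapped directly to small-RNA reference sequences (miRNA precursors,
tRNAs, rRNAs, ...) rather than to a genome.  Alignment is seeded by an exact
match of the read's first 20 bases (the 5' end of small RNA reads is far less
variable than the 3' end, so a fixed 5' seed with free 3' mismatches is what
lets isomiRs with 3' modifications align); the remainder is extended without
indels, tolerating a bounded number of mismatches.  Only minimum-mismatch
placements are retained.  Reads with more placements than the multiplicity
cap are flagged *Highly Redundant* (HR) and excluded from expression
profiling; reads with no placement are unmapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import CollapsedRead

__all__ = [
    "ReferenceLibrary",
    "MatureAnnotation",
    "Alignment",
    "AlignmentSet",
    "SeedIndex",
    "build_index",
    "align_read",
    "align_sample",
    "read_annotation_table",
    "write_sam",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceLibrary:
    """Named set of reference sequences with an RNA-type priority rank
    (rank 1 wins when a read maps to several libraries)."""

    name: str
    sequences: Mapping[str, str]
    priority_rank: int = 1

    def __post_init__(self) -> None:
        for ref, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty reference sequence {ref!r}")


@dataclass(frozen=True)
class MatureAnnotation:
    """Mature-product window on a precursor, 0-based half-open.

    A mature name may recur on different precursors (multi-copy miRNAs);
    the (mature_name, precursor_name) pair is the unique key.
    """

    mature_name: str
    precursor_name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")


@dataclass
class Alignment:
    """One placement of a collapsed read on a reference.

    ``mismatches`` holds (position_on_read, ref_base, read_base);
    ``multiplicity`` is the number of retained placements of this read across
    all loaded libraries jointly.
    """

    read: CollapsedRead
    ref_name: str
    start: int
    mismatches: list[tuple[int, str, str]] = field(default_factory=list)
    multiplicity: int = 1
    library: str = ""
    strand: str = "+"

    @property
    def end(self) -> int:
        return self.start + len(self.read.sequence)


@dataclass
class AlignmentSet:
    """Partition of the input reads: placed / Highly Redundant / unmapped."""

    alignments: list[Alignment] = field(default_factory=list)
    highly_redundant: list[CollapsedRead] = field(default_factory=list)
    unmapped: list[CollapsedRead] = field(default_factory=list)

    def mapped_reads(self) -> list[CollapsedRead]:
        seen: dict[str, CollapsedRead] = {}
        for a in self.alignments:
            seen.setdefault(a.read.sequence, a.read)
        return list(seen.values())


class SeedIndex:
    """Exact-substring index: every k-mer of every reference -> placements."""

    def __init__(self, libraries: Sequence[ReferenceLibrary], seed_len: int = 20):
        self.seed_len = seed_len
        self.libraries = {lib.name: lib for lib in libraries}
        self.refs: dict[str, tuple[str, str]] = {}  # ref_name -> (library, seq)
        self._kmers: dict[str, list[tuple[str, int]]] = {}
        for lib in libraries:
            for ref_name, seq in lib.sequences.items():
                if ref_name in self.refs:
                    raise ValueError(f"duplicate reference name {ref_name!r}")
                self.refs[ref_name] = (lib.name, seq)
                for off in range(len(seq) - seed_len + 1):
                    self._kmers.setdefault(seq[off : off + seed_len], []).append(
                        (ref_name, off)
                    )

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        if len(kmer) == self.seed_len:
            return self._kmers.get(kmer, [])
        # short seed (read shorter than seed_len): scan prefixes
        hits = []
        for ref_name, (_lib, seq) in self.refs.items():
            start = 0
            while (pos := seq.find(kmer, start)) != -1:
                hits.append((ref_name, pos))
                start = pos + 1
        return hits


def build_index(libraries: Sequence[ReferenceLibrary], seed_len: int = 20) -> SeedIndex:
    """Index all references for exact seed lookup."""
    return SeedIndex(libraries, seed_len=seed_len)


def align_read(
    read: CollapsedRead,
    index: SeedIndex,
    max_mismatches: int = 2,
    max_multiplicity: int = 10,
    both_strands: bool = False,
) -> tuple[list[Alignment], bool]:
    """Align one read; returns (placements, is_highly_redundant).

    Candidate placements are seeded by an exact match of the read's first
    ``seed_len`` bases (whole read when shorter); the remaining 3' bases are
    extended gaplessly with at most ``max_mismatches`` mismatches, and only
    minimum-mismatch placements are retained.  More than ``max_multiplicity``
    retained placements classifies the read HR; none leaves it unmapped
    (empty list, False).
    """
    candidates: list[Alignment] = []
    queries = [(read.sequence, "+")]
    if both_strands:
        queries.append((revcomp(read.sequence), "-"))
    for seq, strand in queries:
        seed = seq[: index.seed_len]
        for ref_name, start in index.lookup(seed):
            lib, ref_seq = index.refs[ref_name]
            if start + len(seq) > len(ref_seq):
                continue
            mism: list[tuple[int, str, str]] = []
            ok = True
            for i in range(index.seed_len, len(seq)):
                rb = ref_seq[start + i]
                if seq[i] != rb:
                    mism.append((i, rb, seq[i]))
                    if len(mism) > max_mismatches:
                        ok = False
                        break
            if ok:
                candidates.append(
                    Alignment(read=read, ref_name=ref_name, start=start,
                              mismatches=mism, library=lib, strand=strand)
                )
    if not candidates:
        return [], False
    best = min(len(a.mismatches) for a in candidates)
    retained = [a for a in candidates if len(a.mismatches) == best]
    if len(retained) > max_multiplicity:
        return [], True
    for a in retained:
        a.multiplicity = len(retained)
    retained.sort(key=lambda a: (a.ref_name, a.start, a.strand))
    return retained, False


def align_sample(
    collapsed_reads: Iterable[CollapsedRead],
    libraries: Sequence[ReferenceLibrary],
    seed_len: int = 20,
    max_mismatches: int = 2,
    max_multiplicity: int = 10,
    both_strands: bool = False,
    index: SeedIndex | None = None,
) -> AlignmentSet:
    """Align a collapsed sample against one or more reference libraries.

    Multiplicity is counted across all loaded libraries jointly.  Output
    order is deterministic: reads in input order, placements sorted by
    (ref_name, start).
    """
    if index is None:
        index = build_index(libraries, seed_len=seed_len)
    out = AlignmentSet()
    for read in collapsed_reads:
        placements, hr = align_read(
            read, index, max_mismatches=max_mismatches,
            max_multiplicity=max_multiplicity, both_strands=both_strands)
        if hr:
            out.highly_redundant.append(read)
        elif not placements:
            out.unmapped.append(read)
        else:
            out.alignments.extend(placements)
    return out


def read_annotation_table(path) -> list[MatureAnnotation]:
    """Read a mature-annotation TSV: mature_name, precursor_name, start, end
    (0-based half-open). Lines starting with '#' are skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            mature, prec, start, end = line.split("\t")[:4]
            out.append(MatureAnnotation(mature, prec, int(start), int(end)))
    return out


def write_sam(alignment_set: AlignmentSet, index: SeedIndex, path) -> None:
    """Export library-mode alignments as SAM (read-count encoded names)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for ref_name, (_lib, seq) in index.refs.items():
            fh.write(f"@SQ\tSN:{ref_name}\tLN:{len(seq)}\n")
        for a in alignment_set.alignments:
            name = f"{a.read.rank_id or 'read'}#{a.read.count}"
            flag = 16 if a.strand == "-" else 0
            seq = a.read.sequence if a.strand == "+" else revcomp(a.read.sequence)
            fh.write(
                f"{name}\t{flag}\t{a.ref_name}\t{a.start + 1}\t255\t"
                f"{len(seq)}M\t*\t0\t0\t{seq}\t*\tNM:i:{len(a.mismatches)}\n"
            )
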