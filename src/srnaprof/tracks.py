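"""Coverage tracks: bedGraph and merged six-column BED.

Per-base coverage is the sum of read counts over all placements covering the
base (full assignment; optionally divided by each read's number of placements
— adjusted).  Tracks are produced irrespective of strand and per strand, and
stratified by read length (19-23 nt and all lengths; additionally 24 nt for
plants, where 24-mers have a distinct biology).  bedGraph intervals are
maximal constant-value runs; contiguously covered regions are merged into
BED6 records whose score is the region's highest coverage value.

All coordinates are 0-based half-open (UCSC convention).  Genome-scale
mapping itself is external: placements are loaded from a SAM file (with
read-count encoded names honored) or taken from library-mode alignments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pysam

from .io_formats import CANDIDATE_SEPARATORS
from .librarymap import AlignmentSet

__all__ = [
    "GenomicPlacement", "CoverageTrack", "BedRecord", "MalformedSam",
    "load_sam", "placements_from_alignments", "make_bedgraph",
    "merge_to_bed", "write_bedgraph", "write_bed",
]

LENGTH_CLASSES = {"all": None, "19-23": (19, 23), "24": (24, 24)}


class MalformedSam(ValueError):
    pass


@dataclass(frozen=True)
class GenomicPlacement:
    """One read placement on a chromosome/reference, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    count: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("require start < end")

    @property
    def read_length(self) -> int:
        return self.end - self.start


@dataclass
class CoverageTrack:
    """Sorted, non-overlapping (chrom, start, end, value) intervals with
    value > 0; adjacent equal-value intervals are merged."""

    intervals: list[tuple[str, int, int, float]]
    scope: str = "all"           # all | plus | minus
    length_class: str = "all"    # all | 19-23 | 24


@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str
    score: float
    strand: str


_COUNT_RE = re.compile(
    "(" + "|".join(re.escape(s) for s in CANDIDATE_SEPARATORS) + r")(\d+)$"
)


def _count_from_name(name: str) -> int:
    """Parse the multiplicity from a read-count encoded name, else 1."""
    m = _COUNT_RE.search(name)
    return int(m.group(2)) if m else 1


def load_sam(path) -> list[GenomicPlacement]:
    """Load mapped primary records from a SAM file as placements.

    Unmapped and secondary/supplementary records are skipped; the read count
    is parsed from read-count encoded names (``r1#5`` -> 5) else 1.
    """
    out: list[GenomicPlacement] = []
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.reference_name is None or rec.reference_end is None:
                    continue
                out.append(GenomicPlacement(
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    count=_count_from_name(rec.query_name or ""),
                    name=rec.query_name or "",
                ))
    except ValueError as exc:
        raise MalformedSam(str(exc)) from exc
    return out


def placements_from_alignments(aset: AlignmentSet) -> list[GenomicPlacement]:
    """Convert library-mode alignments into track placements."""
    return [
        GenomicPlacement(
            chrom=a.ref_name, start=a.start, end=a.end, strand=a.strand,
            count=a.read.count, name=a.read.rank_id or a.read.sequence)
        for a in aset.alignments
    ]


def make_bedgraph(
    placements: Sequence[GenomicPlacement],
    scope: str = "all",
    length_class: str = "all",
    assignment: str = "full",
) -> CoverageTrack:
    """Per-base coverage as maximal constant-value intervals.

    ``scope`` restricts to one strand (``plus``/``minus``) or pools both;
    ``length_class`` restricts read length; ``assignment='adjusted'`` divides
    each placement's count by the read's number of placements (fractional
    values possible).
    """
    if scope not in ("all", "plus", "minus"):
        raise ValueError(f"unknown scope {scope!r}")
    if length_class not in LENGTH_CLASSES:
        raise ValueError(f"unknown length class {length_class!r}")
    if assignment not in ("full", "adjusted"):
        raise ValueError(f"unknown assignment {assignment!r}")

    if assignment == "adjusted":
        mult: dict[str, int] = {}
        for p in placements:
            mult[p.name] = mult.get(p.name, 0) + 1

    bounds = LENGTH_CLASSES[length_class]
    want_strand = {"all": None, "plus": "+", "minus": "-"}[scope]
    used = []
    for p in placements:
        if want_strand is not None and p.strand != want_strand:
            continue
        if bounds is not None and not (bounds[0] <= p.read_length <= bounds[1]):
            continue
        used.append(p)

    intervals: list[tuple[str, int, int, float]] = []
    by_chrom: dict[str, list[GenomicPlacement]] = {}
    for p in used:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom in sorted(by_chrom):
        ps = by_chrom[chrom]
        lo = min(p.start for p in ps)
        hi = max(p.end for p in ps)
        diff = np.zeros(hi - lo + 1)
        for p in ps:
            value = p.count / mult[p.name] if assignment == "adjusted" else p.count
            diff[p.start - lo] += value
            diff[p.end - lo] -= value
        cov = np.cumsum(diff[:-1])
        cov[np.isclose(cov, 0.0, atol=1e-12)] = 0.0
        # maximal constant-value runs
        change = np.nonzero(np.diff(cov))[0] + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(cov)]))
        for s, e in zip(starts, ends):
            v = cov[s]
            if v > 0:
                intervals.append((chrom, int(s + lo), int(e + lo), float(v)))
    return CoverageTrack(intervals=intervals, scope=scope,
                         length_class=length_class)


def merge_to_bed(track: CoverageTrack) -> list[BedRecord]:
    """Merge contiguously covered runs into BED6 records.

    The score is the maximum bedGraph value within the region (coverage is
    rarely constant across a region).  Strand comes from the track scope,
    '.' when strands are pooled.
    """
    strand = {"all": ".", "plus": "+", "minus": "-"}[track.scope]
    out: list[BedRecord] = []
    run: list[tuple[str, int, int, float]] = []
    k = 0

    def flush() -> None:
        nonlocal k
        if run:
            k += 1
            out.append(BedRecord(
                chrom=run[0][0], start=run[0][1], end=run[-1][2],
                name=f"region_{k}", score=max(iv[3] for iv in run),
                strand=strand))

    for iv in track.intervals:
        if run and (iv[0] != run[-1][0] or iv[1] != run[-1][2]):
            flush()
            run = []
        run.append(iv)
    flush()
    return out


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else f"{v:.4f}".rstrip("0")


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{_fmt(value)}\n")


def write_bed(records: Iterable[BedRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t"
                     f"{_fmt(r.score)}\t{r.strand}\n")
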