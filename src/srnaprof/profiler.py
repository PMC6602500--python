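"""Expression quantification, isomiR classification and SNV detection.

Three policies resolve reads mapping to several references:

* ``full``      — every placement receives the read's whole count (column
                  totals can exceed the library size);
* ``adjusted``  — the count is divided by the number of placements;
* ``single``    — the whole count goes to exactly one placement, the
                  reference with the highest provisional expression estimated
                  from uniquely mapping reads.

IsomiRs — sequence/length variants of a mature miRNA — are classified either
hierarchically (each read in exactly one category, in the fixed precedence
canonical > canonical-with-nucleotide-changes > non-templated addition >
5'/3' length variant > multiple length variant) or fuzzily (a read may carry
several labels, e.g. both a 5' and a 3' shift).

Non-templated additions (NTA) are the maximal 3'-terminal run of read bases
that mismatch the precursor at their aligned positions; they are peeled off
before offsets are computed and are excluded from SNV evidence, since an
untemplated tail is a biological modification, not a variant of the
precursor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .librarymap import Alignment, AlignmentSet, MatureAnnotation

__all__ = [
    "CANONICAL", "CANONICAL_NT_CHANGE", "NTA", "LV5P", "LV3P", "MV",
    "ExpressionRecord", "IsomiRCall", "SNVRecord", "RNATypeComposition",
    "OutsideTolerance", "UnknownMode",
    "assign_multimappers", "quantify", "classify_isomir", "peel_nta",
    "detect_snvs", "rna_type_composition",
]

CANONICAL = "CANONICAL"
CANONICAL_NT_CHANGE = "CANONICAL_NT_CHANGE"
NTA = "NTA"
LV5P = "LV5P"
LV3P = "LV3P"
MV = "MV"

#: Mature-window tolerance: a read counts toward a mature product iff its
#: 5' offset is within +-MAX_OFFSET5 and its post-NTA 3' offset within
#: +-MAX_OFFSET3; otherwise it accrues to the precursor's hairpin record.
MAX_OFFSET5 = 3
MAX_OFFSET3 = 5


class OutsideTolerance(ValueError):
    """Alignment does not overlap the mature window within tolerance."""


class UnknownMode(ValueError):
    """Not one of the three multiple-mapping modes."""


@dataclass
class ExpressionRecord:
    """Counts for one (mature, precursor) pair under all three modes."""

    mature_name: str
    precursor_name: str
    raw_count: float = 0.0            # full assignment
    adjusted_count: float = 0.0
    single_assigned_count: float = 0.0
    rpm: float = 0.0

    def count(self, mode: str) -> float:
        return {"full": self.raw_count, "adjusted": self.adjusted_count,
                "single": self.single_assigned_count}[mode]


@dataclass
class IsomiRCall:
    """Classification of one read against one mature product.

    Offsets are signed: positive 5' offset means the read starts inside the
    mature (5' trimming); negative means 5' extension.  The 3' offset is
    computed after peeling the non-templated tail.
    """

    sequence: str
    mature_name: str
    offset5: int
    offset3: int
    nta: str
    snvs: list[tuple[int, str, str]]
    categories: frozenset[str]
    hierarchical_category: str


@dataclass(frozen=True)
class SNVRecord:
    """One sequence variant on a precursor: the five reported columns."""

    precursor_name: str
    variant_type: str          # "ref>alt"
    position: int              # 0-based on precursor
    covering_reads: int
    variant_reads: int


@dataclass
class RNATypeComposition:
    """Fraction of trimmed reads assigned to each RNA-type library.

    Reads mapping to several libraries count toward the highest-priority
    (lowest rank) one; Highly Redundant and unmapped reads are unassigned.
    Fractions sum to 1.
    """

    fractions: dict[str, float]
    unassigned: float


def assign_multimappers(alignment_set: AlignmentSet, mode: str) -> list[float]:
    """Effective count per alignment (parallel to ``alignment_set.alignments``).

    ``single`` assigns each read's whole count to the placement on the
    reference with the highest provisional expression from uniquely mapping
    reads, ties broken lexicographically by (ref_name, start).
    """
    alns = alignment_set.alignments
    if mode == "full":
        return [float(a.read.count) for a in alns]
    if mode == "adjusted":
        return [a.read.count / a.multiplicity for a in alns]
    if mode != "single":
        raise UnknownMode(f"unknown multiple-mapping mode {mode!r}")

    provisional: dict[str, float] = {}
    for a in alns:
        if a.multiplicity == 1:
            provisional[a.ref_name] = provisional.get(a.ref_name, 0.0) + a.read.count
    by_read: dict[str, list[int]] = {}
    for i, a in enumerate(alns):
        by_read.setdefault(a.read.sequence, []).append(i)
    out = [0.0] * len(alns)
    for idxs in by_read.values():
        winner = min(
            idxs,
            key=lambda i: (-provisional.get(alns[i].ref_name, 0.0),
                           alns[i].ref_name, alns[i].start),
        )
        out[winner] = float(alns[winner].read.count)
    return out


def peel_nta(read_seq: str, precursor_seq: str, start: int) -> str:
    """Maximal 3'-terminal run of read bases mismatching the precursor at
    their aligned positions (or lying past the precursor end)."""
    i = len(read_seq) - 1
    while i >= 0:
        pos = start + i
        if pos < len(precursor_seq) and read_seq[i] == precursor_seq[pos]:
            break
        i -= 1
    return read_seq[i + 1 :]


def classify_isomir(
    alignment: Alignment,
    mature: MatureAnnotation,
    precursor_seq: str,
    mode: str = "hierarchical",
) -> IsomiRCall:
    """Classify one aligned read against a mature window.

    Raises :class:`OutsideTolerance` when the read's offsets exceed the
    mature-window tolerance. In ``hierarchical`` mode ``categories`` holds
    only the single winning label; in ``fuzzy`` mode it holds every
    applicable one (always including the hierarchical winner).
    """
    seq = alignment.read.sequence
    nta = peel_nta(seq, precursor_seq, alignment.start)
    templated_len = len(seq) - len(nta)
    offset5 = alignment.start - mature.start
    offset3 = (alignment.start + templated_len) - mature.end
    if abs(offset5) > MAX_OFFSET5 or abs(offset3) > MAX_OFFSET3:
        raise OutsideTolerance(
            f"offsets ({offset5}, {offset3}) exceed tolerance "
            f"({MAX_OFFSET5}, {MAX_OFFSET3})"
        )
    snvs = [m for m in alignment.mismatches if m[0] < templated_len]

    if offset5 == 0 and offset3 == 0 and not nta and not snvs:
        fuzzy = {CANONICAL}
        hier = CANONICAL
    else:
        fuzzy = set()
        if snvs and offset5 == 0 and offset3 == 0 and not nta:
            fuzzy.add(CANONICAL_NT_CHANGE)
        if nta:
            fuzzy.add(NTA)
        if offset5 != 0:
            fuzzy.add(LV5P)
        if offset3 != 0:
            fuzzy.add(LV3P)
        if offset5 != 0 and offset3 != 0:
            fuzzy.add(MV)
        if CANONICAL_NT_CHANGE in fuzzy:
            hier = CANONICAL_NT_CHANGE
        elif nta:
            hier = NTA
        elif offset5 != 0 and offset3 == 0:
            hier = LV5P
        elif offset3 != 0 and offset5 == 0:
            hier = LV3P
        else:
            hier = MV
    cats = frozenset({hier}) if mode == "hierarchical" else frozenset(fuzzy)
    return IsomiRCall(
        sequence=seq, mature_name=mature.mature_name, offset5=offset5,
        offset3=offset3, nta=nta, snvs=snvs, categories=cats,
        hierarchical_category=hier,
    )


def _mature_for(
    alignment: Alignment,
    annotations: Sequence[MatureAnnotation],
    precursor_seq: str,
) -> MatureAnnotation | None:
    """Mature window this placement counts toward (closest by total offset),
    or None for a hairpin read."""
    best: tuple[int, str] | None = None
    chosen = None
    nta = peel_nta(alignment.read.sequence, precursor_seq, alignment.start)
    tlen = len(alignment.read.sequence) - len(nta)
    for ann in annotations:
        if ann.precursor_name != alignment.ref_name:
            continue
        o5 = alignment.start - ann.start
        o3 = (alignment.start + tlen) - ann.end
        if abs(o5) > MAX_OFFSET5 or abs(o3) > MAX_OFFSET3:
            continue
        key = (abs(o5) + abs(o3), ann.mature_name)
        if best is None or key < best:
            best, chosen = key, ann
    return chosen


def quantify(
    alignment_set: AlignmentSet,
    annotations: Sequence[MatureAnnotation],
    precursors: Mapping[str, str],
    mode: str = "adjusted",
) -> list[ExpressionRecord]:
    """Aggregate per-(mature, precursor) expression under all three modes.

    A placement contributes to the mature window it overlaps within the
    isomiR tolerance; placements outside every window accrue to a
    ``<precursor>:hairpin`` record.  ``rpm`` normalizes the requested mode's
    column to reads per million.
    """
    eff = {m: assign_multimappers(alignment_set, m)
           for m in ("full", "adjusted", "single")}
    records: dict[tuple[str, str], ExpressionRecord] = {}
    for i, a in enumerate(alignment_set.alignments):
        ann = _mature_for(a, annotations, precursors[a.ref_name])
        key = ((ann.mature_name, ann.precursor_name) if ann
               else (f"{a.ref_name}:hairpin", a.ref_name))
        rec = records.setdefault(key, ExpressionRecord(*key))
        rec.raw_count += eff["full"][i]
        rec.adjusted_count += eff["adjusted"][i]
        rec.single_assigned_count += eff["single"][i]
    total = sum(r.count(mode) for r in records.values())
    if total > 0:
        for r in records.values():
            r.rpm = r.count(mode) / total * 1e6
    return sorted(records.values(),
                  key=lambda r: (-r.count(mode), r.mature_name, r.precursor_name))


def detect_snvs(
    alignment_set: AlignmentSet,
    precursors: Mapping[str, str],
    min_cov: int = 10,
    min_var_reads: int = 2,
    min_var_fraction: float = 0.05,
) -> list[SNVRecord]:
    """Call sequence variants on precursors from alignment mismatches.

    Uses full-assignment counts (integer evidence).  Non-templated 3' tails
    are excluded both from variant evidence and from coverage.  A variant is
    reported when variant_reads >= min_var_reads, covering_reads >= min_cov
    and the variant fraction >= min_var_fraction.  Phred scores are not used.
    """
    coverage: dict[tuple[str, int], int] = {}
    variants: dict[tuple[str, int, str], int] = {}
    for a in alignment_set.alignments:
        seq = a.read.sequence
        prec = precursors[a.ref_name]
        nta = peel_nta(seq, prec, a.start)
        tlen = len(seq) - len(nta)
        for i in range(tlen):
            pos = (a.ref_name, a.start + i)
            coverage[pos] = coverage.get(pos, 0) + a.read.count
        for rpos, ref_b, read_b in a.mismatches:
            if rpos < tlen:
                key = (a.ref_name, a.start + rpos, f"{ref_b}>{read_b}")
                variants[key] = variants.get(key, 0) + a.read.count
    out = []
    for (ref, pos, vtype), var_reads in sorted(variants.items()):
        cov = coverage[(ref, pos)]
        if (var_reads >= min_var_reads and cov >= min_cov
                and var_reads / cov >= min_var_fraction):
            out.append(SNVRecord(ref, vtype, pos, cov, var_reads))
    return out


def rna_type_composition(
    alignment_set: AlignmentSet,
    priority: Mapping[str, int],
    total_reads: int | None = None,
) -> RNATypeComposition:
    """Assign each read to the highest-priority RNA-type library it maps to.

    ``priority`` maps library name -> rank (1 = highest).  Fractions are over
    ``total_reads`` (default: all reads in the alignment set, mapped or not);
    HR and unmapped reads are unassigned.
    """
    lib_of: dict[str, str] = {}
    for a in alignment_set.alignments:
        cur = lib_of.get(a.read.sequence)
        if cur is None or priority[a.library] < priority[cur]:
            lib_of[a.read.sequence] = a.library
    count_of = {a.read.sequence: a.read.count for a in alignment_set.alignments}
    assigned: dict[str, int] = {}
    for seq, lib in lib_of.items():
        assigned[lib] = assigned.get(lib, 0) + count_of[seq]
    mapped_total = sum(assigned.values())
    other = (sum(r.count for r in alignment_set.unmapped)
             + sum(r.count for r in alignment_set.highly_redundant))
    if total_reads is None:
        total_reads = mapped_total + other
    if total_reads == 0:
        return RNATypeComposition(fractions={}, unassigned=1.0)
    fractions = {lib: n / total_reads for lib, n in sorted(assigned.items())}
    return RNATypeComposition(
        fractions=fractions, unassigned=1.0 - mapped_total / total_reads
    )
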