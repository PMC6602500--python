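"""Protocol-aware read preprocessing.

Small RNA library preparation protocols differ in adapter sequences, in
randomized bases flanking the insert (ligation-bias reduction, e.g. NEXTflex
4N), and in unique molecular identifiers (UMIs) used to collapse PCR
duplicates (e.g. QIAseq's 12-base UMI after the 3' adapter).  This module
ships those geometries as declared :class:`ProtocolPreset` data, trims and
quality-filters reads accordingly, and tallies per-sample QC statistics
(read-length histogram, adapter-dimer fraction, per-stage survivor counts).

An *adapter dimer* is a library molecule with no insert: after trimming the
read has length 0.  A high dimer fraction flags library-preparation problems
such as low RNA input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .io_formats import CollapsedRead, SequenceRecord

__all__ = [
    "UmiSide",
    "ProtocolPreset",
    "PRESETS",
    "TrimResult",
    "QCStats",
    "UmiTooShort",
    "NoQualities",
    "trim_adapter",
    "extract_umi",
    "dedup_umi",
    "quality_filter",
    "preprocess_sample",
]


class UmiTooShort(ValueError):
    """Fewer bases available than the preset's UMI length demands."""


class NoQualities(ValueError):
    """Quality filtering requested on input without Phred scores."""


class UmiSide(Enum):
    NONE = "none"
    READ_START = "read_start"
    AFTER_ADAPTER3 = "after_adapter3"


@dataclass(frozen=True)
class ProtocolPreset:
    """Adapter/UMI geometry of one library preparation protocol.

    ``random5``/``random3`` are randomized bases stripped from the 5'/3' ends
    of the insert after adapter trimming; ``umi_len`` > 0 iff ``umi_side``
    is not NONE.
    """

    name: str
    adapter3: str | None = None
    adapter5: str | None = None
    random5: int = 0
    random3: int = 0
    umi_len: int = 0
    umi_side: UmiSide = UmiSide.NONE

    def __post_init__(self) -> None:
        if (self.umi_len > 0) != (self.umi_side is not UmiSide.NONE):
            raise ValueError("umi_len > 0 iff umi_side != NONE")


#: Shipped presets. Adapter sequences and UMI geometries are declared data
#: and can be overridden with a custom preset.
PRESETS: dict[str, ProtocolPreset] = {
    "illumina": ProtocolPreset("illumina", adapter3="TGGAATTCTCGGGTGCCAAGG"),
    "nebnext": ProtocolPreset("nebnext", adapter3="AGATCGGAAGAGCACACGTCT"),
    "nextflex": ProtocolPreset(
        "nextflex", adapter3="TGGAATTCTCGGGTGCCAAGG", random5=4, random3=4
    ),
    "qiaseq": ProtocolPreset(
        "qiaseq",
        adapter3="AACTGTAGGCACCATCAAT",
        umi_len=12,
        umi_side=UmiSide.AFTER_ADAPTER3,
    ),
    "cats": ProtocolPreset("cats", adapter3="AAAAAAAAAA"),
}


@dataclass
class TrimResult:
    insert: str
    adapter_found: bool
    umi: str | None = None
    original_length: int = 0
    insert_qualities: list[int] | None = None

    @property
    def is_dimer(self) -> bool:
        return self.adapter_found and len(self.insert) == 0


@dataclass
class QCStats:
    """Per-sample preprocessing tallies.

    ``length_histogram`` counts reads surviving all filters by insert length.
    Every input read lands in exactly one of: no-adapter discard, dimer,
    quality-filtered, length-filtered, survivor.
    """

    reads_input: int = 0
    reads_adapter_trimmed: int = 0
    reads_no_adapter: int = 0
    reads_dimer: int = 0
    reads_quality_filtered: int = 0
    reads_length_filtered: int = 0
    reads_survived: int = 0
    umi_dedup_removed: int = 0
    length_histogram: dict[int, int] = field(default_factory=dict)

    @property
    def dimer_fraction(self) -> float:
        return self.reads_dimer / self.reads_input if self.reads_input else 0.0

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "reads_input", "reads_adapter_trimmed", "reads_no_adapter",
            "reads_dimer", "reads_quality_filtered", "reads_length_filtered",
            "reads_survived", "umi_dedup_removed")}
        d["dimer_fraction"] = self.dimer_fraction
        d["length_histogram"] = dict(sorted(self.length_histogram.items()))
        return d


def _find_adapter(
    seq: str, adapter: str, min_overlap: int, max_mismatch_rate: float
) -> int | None:
    """Leftmost position where a prefix of *adapter* (>= min_overlap bases)
    matches *seq* with mismatch fraction <= max_mismatch_rate. The adapter
    may run off the 3' end of the read."""
    n, m = len(seq), len(adapter)
    for pos in range(0, n - min_overlap + 1):
        overlap = min(m, n - pos)
        budget = int(max_mismatch_rate * overlap)
        mm = 0
        for i in range(overlap):
            if seq[pos + i] != adapter[i]:
                mm += 1
                if mm > budget:
                    break
        else:
            return pos
    return None


def trim_adapter(
    record: SequenceRecord,
    preset: ProtocolPreset,
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.1,
) -> TrimResult:
    """Trim the 3' adapter and strip randomized bases from the insert.

    The insert is the read prefix before the leftmost adapter occurrence
    (exact-prefix match of >= *min_overlap* adapter bases tolerating a
    mismatch fraction of *max_mismatch_rate*). ``random5``/``random3`` bases
    are then removed from the insert ends. An insert of length 0 flags an
    adapter dimer. When no adapter is found the full read is returned with
    ``adapter_found=False``; the caller decides the keep/discard policy.
    """
    seq = record.sequence
    quals = record.qualities
    if not preset.adapter3:
        ins_q = list(quals) if quals is not None else None
        return TrimResult(seq, False, original_length=len(seq),
                          insert_qualities=ins_q)
    pos = _find_adapter(seq, preset.adapter3, min_overlap, max_mismatch_rate)
    found = pos is not None
    insert = seq[:pos] if found else seq
    ins_q = list(quals[: len(insert)]) if quals is not None else None
    if found:
        lo, hi = preset.random5, len(insert) - preset.random3
        hi = max(lo, hi)
        insert = insert[lo:hi]
        if ins_q is not None:
            ins_q = ins_q[lo:hi]
    return TrimResult(insert, found, original_length=len(seq),
                      insert_qualities=ins_q)


def extract_umi(record: SequenceRecord, preset: ProtocolPreset,
                min_overlap: int = 10, max_mismatch_rate: float = 0.1
                ) -> TrimResult:
    """Trim adapters and pull the UMI from its configured position.

    ``read_start`` UMIs are the first ``umi_len`` bases of the raw read;
    ``after_adapter3`` UMIs are the ``umi_len`` bases immediately following
    the 3' adapter. The UMI is removed from the retained sequence.
    """
    if preset.umi_side is UmiSide.NONE:
        raise ValueError("preset has no UMI")

    if preset.umi_side is UmiSide.READ_START:
        if len(record.sequence) < preset.umi_len:
            raise UmiTooShort(
                f"read length {len(record.sequence)} < umi_len {preset.umi_len}")
        umi = record.sequence[: preset.umi_len]
        rest = SequenceRecord(
            id=record.id,
            sequence=record.sequence[preset.umi_len:],
            qualities=record.qualities[preset.umi_len:]
            if record.qualities is not None else None,
        )
        result = trim_adapter(rest, preset, min_overlap, max_mismatch_rate)
        result.umi = umi
        result.original_length = len(record.sequence)
        return result

    # after_adapter3: insert + adapter + UMI
    result = trim_adapter(record, preset, min_overlap, max_mismatch_rate)
    if not result.adapter_found:
        return result
    adapter_start = len(result.insert) + preset.random5 + preset.random3
    umi_start = adapter_start + len(preset.adapter3 or "")
    tail = record.sequence[umi_start:]
    if len(tail) < preset.umi_len:
        raise UmiTooShort(
            f"{len(tail)} bases after adapter < umi_len {preset.umi_len}")
    result.umi = tail[: preset.umi_len]
    return result


def dedup_umi(trimmed: Sequence[tuple[str, str]]) -> list[CollapsedRead]:
    """Collapse (insert, UMI) pairs: a sequence's count is the number of
    distinct UMIs seen with it, removing PCR duplicates."""
    umis: dict[str, set[str]] = {}
    for seq, umi in trimmed:
        umis.setdefault(seq, set()).add(umi)
    ordered = sorted(umis.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [
        CollapsedRead(sequence=seq, count=len(u), rank_id=f"read_{i}")
        for i, (seq, u) in enumerate(ordered, start=1)
    ]


def quality_filter(qualities: Sequence[int] | None, method: str,
                   threshold: int) -> bool:
    """Keep decision for one read's (adapter-trimmed) Phred scores.

    ``mean`` keeps reads whose average Phred score reaches the threshold;
    ``min`` is stricter, discarding any read with at least one position
    below it.
    """
    if qualities is None:
        raise NoQualities("quality filtering requires FASTQ input")
    if len(qualities) == 0:
        return True
    if method == "mean":
        return sum(qualities) / len(qualities) >= threshold
    if method == "min":
        return min(qualities) >= threshold
    raise ValueError(f"unknown quality filter method {method!r}")


def preprocess_sample(
    records: Iterable[SequenceRecord],
    preset: ProtocolPreset,
    qc_method: str | None = "mean",
    qc_threshold: int = 20,
    min_len: int = 15,
    max_len: int | None = None,
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.1,
    keep_no_adapter: bool = False,
) -> tuple[list[CollapsedRead], QCStats]:
    """Run the full preprocessing chain on one sample.

    Stage order: adapter trim -> UMI extraction -> quality filter -> length
    filter [min_len, max_len] -> UMI dedup (or plain collapse).  Set
    ``qc_method=None`` to skip quality filtering (FASTA input).
    """
    stats = QCStats()
    survivors: list[tuple[str, list[int] | None, str | None]] = []
    has_umi = preset.umi_side is not UmiSide.NONE

    for rec in records:
        stats.reads_input += 1
        try:
            tr = (extract_umi(rec, preset, min_overlap, max_mismatch_rate)
                  if has_umi
                  else trim_adapter(rec, preset, min_overlap, max_mismatch_rate))
        except UmiTooShort:
            stats.reads_length_filtered += 1
            continue
        if preset.adapter3 and not tr.adapter_found:
            if not keep_no_adapter:
                stats.reads_no_adapter += 1
                continue
        else:
            stats.reads_adapter_trimmed += 1
        if tr.is_dimer:
            stats.reads_dimer += 1
            continue
        if qc_method is not None and rec.qualities is not None:
            if not quality_filter(tr.insert_qualities, qc_method, qc_threshold):
                stats.reads_quality_filtered += 1
                continue
        n = len(tr.insert)
        if n < min_len or (max_len is not None and n > max_len):
            stats.reads_length_filtered += 1
            continue
        stats.reads_survived += 1
        stats.length_histogram[n] = stats.length_histogram.get(n, 0) + 1
        survivors.append((tr.insert, tr.insert_qualities, tr.umi))

    if has_umi:
        pairs = [(seq, umi) for seq, _, umi in survivors if umi is not None]
        collapsed = dedup_umi(pairs)
        stats.umi_dedup_removed = len(pairs) - sum(c.count for c in collapsed)
    else:
        from .io_formats import collapse
        collapsed = collapse(seq for seq, _, _ in survivors)
    return collapsed, stats
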