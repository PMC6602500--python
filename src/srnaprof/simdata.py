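"""Deterministic synthetic small RNA data with ground truth.

Every pipeline stage is exercised against data whose truth is known by
construction: precursors with embedded mature windows, reads drawn from
mature products with a configurable isomiR profile (canonical reads, 3'
non-templated additions, 5'/3' length variants), planted sequence variants
at set frequencies, per-base sequencing errors, and library-preparation
geometry (3' adapter, randomized flanks, UMIs).  Count matrices for the DE
stage are negative-binomial with planted fold changes.

All randomness flows through one seeded :class:`numpy.random.Generator`;
identical seeds give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import SequenceRecord
from .librarymap import MatureAnnotation, ReferenceLibrary
from .preprocess import ProtocolPreset, UmiSide

__all__ = [
    "SimSpec", "GroundTruth", "make_reference",
    "simulate_reads", "simulate_counts",
]

_BASES = np.array(list("ACGT"))

#: Category mix emulating a typical mammalian miRNA-seq library: mostly
#: canonical reads, a sizeable non-templated-addition fraction, and smaller
#: 5'/3' length-variant fractions.
DEFAULT_PROFILE: dict[str, float] = {
    "canonical": 0.55, "nta": 0.20, "lv5p": 0.05, "lv3p": 0.15, "mv": 0.05,
}


class InvalidSpec(ValueError):
    pass


@dataclass
class SimSpec:
    """Everything the read simulator needs; see module docstring."""

    library: ReferenceLibrary
    annotations: list[MatureAnnotation]
    abundances: dict[str, float]                  # mature_name -> weight
    profile: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PROFILE))
    snv_plants: list[tuple[str, int, str, float]] = field(default_factory=list)
    error_rate: float = 0.001
    preset: ProtocolPreset | None = None
    depth: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.profile.values()) - 1.0) > 1e-9:
            raise InvalidSpec("profile probabilities must sum to 1")
        if self.depth < 0:
            raise InvalidSpec("depth must be >= 0")
        for prec, pos, alt, freq in self.snv_plants:
            if not 0.0 <= freq <= 1.0:
                raise InvalidSpec("SNV frequency must be in [0, 1]")
            if prec not in self.library.sequences:
                raise InvalidSpec(f"unknown precursor {prec!r}")
            if not 0 <= pos < len(self.library.sequences[prec]):
                raise InvalidSpec("SNV position outside precursor")


@dataclass
class GroundTruth:
    """What the simulator actually planted, recorded per read."""

    mature_counts: dict[str, int] = field(default_factory=dict)
    read_categories: list[str] = field(default_factory=list)
    read_inserts: list[str] = field(default_factory=list)
    snv_plants: list[tuple[str, int, str, float]] = field(default_factory=list)
    planted_log2fc: dict[str, float] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def make_reference(
    rng: np.random.Generator,
    n_precursors: int = 5,
    precursor_len: int = 70,
    mature_len: int = 22,
    mature_start: int = 15,
) -> tuple[ReferenceLibrary, list[MatureAnnotation]]:
    """Random precursor set with one mature window each.

    Lengths follow typical animal miRNA hairpins (~70 nt precursor, 22 nt
    mature product).  Precursors are rejection-sampled so no mature sequence
    recurs elsewhere in the set (keeps simulated reads uniquely mappable).
    """
    seqs: dict[str, str] = {}
    annots: list[MatureAnnotation] = []
    while len(seqs) < n_precursors:
        name = f"prec-{len(seqs) + 1}"
        seq = _random_seq(rng, precursor_len)
        mature = seq[mature_start : mature_start + mature_len]
        joined = "".join(seqs.values())
        if joined.count(mature) or seq.count(mature) != 1:
            continue
        if any(s.count(seq[mature_start : mature_start + 20]) for s in seqs.values()):
            continue
        seqs[name] = seq
        annots.append(MatureAnnotation(
            mature_name=f"mir-{len(seqs)}", precursor_name=name,
            start=mature_start, end=mature_start + mature_len))
    return ReferenceLibrary(name="mirna", sequences=seqs), annots


def _apply_category(
    rng: np.random.Generator, category: str, mature: MatureAnnotation,
    precursor: str,
) -> str:
    """Build one read of the given isomiR category from the precursor."""
    start, end = mature.start, mature.end
    if category in ("lv5p", "mv"):
        # 5' shift of +-1..2, kept templated (cut within the precursor)
        while True:
            d5 = int(rng.integers(1, 3)) * (1 if rng.random() < 0.5 else -1)
            if 0 <= start + d5 < end:
                start += d5
                break
    if category in ("lv3p", "mv"):
        while True:
            d3 = int(rng.integers(1, 3)) * (1 if rng.random() < 0.5 else -1)
            if start < end + d3 <= len(precursor):
                end += d3
                break
    read = precursor[start:end]
    if category == "nta":
        # non-templated tail; every base differs from the template at its
        # aligned position so the planted category is unambiguous
        n = int(rng.integers(1, 3))
        tail = []
        for i in range(n):
            pos = end + i
            templated = precursor[pos] if pos < len(precursor) else None
            choices = [b for b in "ACGT" if b != templated]
            tail.append(str(rng.choice(choices)))
        read += "".join(tail)
    return read


def simulate_reads(
    spec: SimSpec, fastq_path: str | Path | None = None
) -> tuple[list[SequenceRecord], GroundTruth]:
    """Draw reads per the simulation settings; optionally write them as FASTQ.

    Reads are sampled from mature products by abundance weight, edited per
    the isomiR profile, given planted variants and per-base sequencing
    errors, then wrapped in the preset's library geometry (randomized
    flanks, 3' adapter, UMI).  Qualities are constant Q30; error positions
    keep that score (the error model is substitution-only).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    annots = {a.mature_name: a for a in spec.annotations}
    names = sorted(spec.abundances)
    weights = np.array([spec.abundances[n] for n in names], dtype=float)
    weights /= weights.sum()
    categories = sorted(spec.profile)
    cat_p = np.array([spec.profile[c] for c in categories])
    truth = GroundTruth(snv_plants=list(spec.snv_plants))
    records: list[SequenceRecord] = []

    snv_by_prec: dict[str, list[tuple[int, str, float]]] = {}
    for prec, pos, alt, freq in spec.snv_plants:
        snv_by_prec.setdefault(prec, []).append((pos, alt, freq))

    for i in range(spec.depth):
        mature_name = names[int(rng.choice(len(names), p=weights))]
        ann = annots[mature_name]
        precursor = spec.library.sequences[ann.precursor_name]
        # planted variants act at the precursor level (allele of the locus)
        prec_variant = list(precursor)
        for pos, alt, freq in snv_by_prec.get(ann.precursor_name, []):
            if rng.random() < freq:
                prec_variant[pos] = alt
        category = categories[int(rng.choice(len(categories), p=cat_p))]
        insert = _apply_category(rng, category, ann, "".join(prec_variant))
        # sequencing errors: substitution-only, uniform over positions
        bases = list(insert)
        for j in range(len(bases)):
            if rng.random() < spec.error_rate:
                bases[j] = str(rng.choice([b for b in "ACGT" if b != bases[j]]))
        insert = "".join(bases)
        truth.mature_counts[mature_name] = truth.mature_counts.get(mature_name, 0) + 1
        truth.read_categories.append(category)
        truth.read_inserts.append(insert)

        raw = insert
        if spec.preset is not None:
            p = spec.preset
            raw = (_random_seq(rng, p.random5) + insert
                   + _random_seq(rng, p.random3) + (p.adapter3 or ""))
            if p.umi_side is UmiSide.AFTER_ADAPTER3:
                raw += _random_seq(rng, p.umi_len)
            elif p.umi_side is UmiSide.READ_START:
                raw = _random_seq(rng, p.umi_len) + raw
        records.append(SequenceRecord(
            id=f"sim_{i + 1}", sequence=raw, qualities=[30] * len(raw)))

    if fastq_path is not None:
        with open(fastq_path, "w") as fh:
            for rec in records:
                qual = "".join(chr(q + 33) for q in rec.qualities or [])
                fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")
    return records, truth


def simulate_counts(
    n_features: int,
    n_per_group: int,
    planted: Mapping[str, float] | None = None,
    dispersion: float = 0.1,
    base_mean: float = 200.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str], GroundTruth]:
    """Negative-binomial count matrix with planted log2 fold changes.

    Returns (counts features x samples, sample->group labels, truth).
    Group A samples are ``A1..An``, group B ``B1..Bn``; planted features'
    group-A means are scaled by 2**log2fc (so "up" means higher in A).
    ``dispersion`` is the NB dispersion alpha (variance = mu + alpha*mu^2).
    """
    if n_per_group < 2:
        raise ValueError("need n_per_group >= 2")
    planted = dict(planted or {})
    rng = np.random.default_rng(seed)
    features = [f"feat-{i + 1}" for i in range(n_features)]
    base = rng.lognormal(mean=np.log(base_mean), sigma=1.0, size=n_features)
    samples = [f"A{i + 1}" for i in range(n_per_group)] + \
              [f"B{i + 1}" for i in range(n_per_group)]
    groups = {s: ("A" if s.startswith("A") else "B") for s in samples}
    truth = GroundTruth(planted_log2fc={f: planted.get(f, 0.0) for f in features})

    def nb_draw(mu: np.ndarray) -> np.ndarray:
        n = 1.0 / dispersion
        p = n / (n + mu)
        return rng.negative_binomial(n, p)

    mat = np.zeros((n_features, 2 * n_per_group), dtype=float)
    mu_a = base * np.array([2.0 ** planted.get(f, 0.0) for f in features])
    for j in range(n_per_group):
        mat[:, j] = nb_draw(mu_a)
    for j in range(n_per_group):
        mat[:, n_per_group + j] = nb_draw(base)
    counts = pd.DataFrame(mat, index=features, columns=samples)
    return counts, groups, truth
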