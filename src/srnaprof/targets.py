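"""Seed-match target-site detection for animal miRNAs.

Animal miRNA targeting is dominated by Watson-Crick pairing between the
miRNA *seed* (positions 2-7/2-8 from the 5' end) and the 3' UTR.  The four
canonical site types, most to least specific:

* ``8mer``     — match to the reverse complement of positions 2-8, followed
                 by an A opposite position 1;
* ``7mer-m8``  — match to the reverse complement of positions 2-8;
* ``7mer-A1``  — match to positions 2-7 plus the A anchor;
* ``6mer``     — match to positions 2-7 only.

Sites are exact substring matches on the UTR sense strand (patterns written
5'->3' on the target); when one locus qualifies for several types only the
most specific is reported.  This is several-fold faster than
thermodynamic/alignment-based target predictors and is meant as a quick
first-pass scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Seq import reverse_complement

__all__ = ["SITE_TYPES", "SeedSite", "SequenceTooShort",
           "seed_patterns", "find_seed_sites"]

#: Most specific first; used for suppression at identical loci.
SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")


class SequenceTooShort(ValueError):
    """miRNA shorter than the 8 bases the seed definitions require."""


@dataclass(frozen=True)
class SeedSite:
    """One seed match on a UTR, 0-based half-open, sense strand."""

    utr_id: str
    start: int
    end: int
    site_type: str
    mirna_id: str

    def __post_init__(self) -> None:
        expected = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}
        if self.end - self.start != expected[self.site_type]:
            raise ValueError("span does not match site type")


def seed_patterns(mirna: str) -> dict[str, str]:
    """DNA patterns (5'->3' on the target strand) for each site type.

    The miRNA may be given as RNA or DNA, 5'->3'.  By construction the 8mer
    pattern is the 7mer-m8 pattern + "A" and the 7mer-A1 pattern is the
    6mer pattern + "A".
    """
    m = mirna.upper().replace("U", "T")
    if len(m) < 8:
        raise SequenceTooShort(f"need >= 8 bases, got {len(m)}")
    seed6 = reverse_complement(m[1:7])   # positions 2-7
    seed7 = reverse_complement(m[1:8])   # positions 2-8
    return {
        "6mer": seed6,
        "7mer-A1": seed6 + "A",
        "7mer-m8": seed7,
        "8mer": seed7 + "A",
    }


def find_seed_sites(
    mirna_id: str,
    mirna: str,
    utrs: Mapping[str, str],
) -> list[SeedSite]:
    """All seed sites of one miRNA across a set of UTR sequences.

    Every pattern occurrence is reported, overlaps included; when a span is
    explained by several site types only the most specific wins
    (8mer > 7mer-m8 > 7mer-A1 > 6mer).  A more specific site suppresses the
    less specific matches it contains at the same seed locus (the 6mer
    inside an 8mer is not a separate site).
    """
    patterns = seed_patterns(mirna)
    sites: list[SeedSite] = []
    for utr_id, utr in utrs.items():
        seq = utr.upper().replace("U", "T")
        # seed-region start -> best site found there; the seed hexamer match
        # position identifies the locus across types. For 7mer-m8/8mer the
        # hexamer sits one base right of the pattern start.
        best: dict[int, SeedSite] = {}
        for site_type in reversed(SITE_TYPES):  # least specific first
            pat = patterns[site_type]
            offset = 1 if site_type in ("7mer-m8", "8mer") else 0
            start = 0
            while (pos := seq.find(pat, start)) != -1:
                locus = pos + offset
                best[locus] = SeedSite(
                    utr_id=utr_id, start=pos, end=pos + len(pat),
                    site_type=site_type, mirna_id=mirna_id)
                start = pos + 1
        sites.extend(best.values())
    sites.sort(key=lambda s: (s.utr_id, s.start, s.site_type))
    return sites
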