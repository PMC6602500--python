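"""Detect input formats from content and collapse reads to unique sequences.

Small RNA files arrive as FASTQ, FASTA, or read-count FASTA (headers like
``>read_1#5231`` carrying a multiplicity). Detection is content-based, so a
mislabelled extension cannot break a run.
"""

import tempfile
from pathlib import Path

from srnaprof import collapse, detect_format, read_records, write_readcount
from srnaprof.io_formats import detect_format_file

print("--- content-based detection ---")
for sample in ("@r1\nACGT\n+\nIIII\n",
               ">seq1#12\nACGT\n>seq2#3\nTTTT\n",
               ">chr_region_1\nACGTACGT\n"):
    kind = detect_format(sample)
    print(f"{sample.splitlines()[0]:>16}  ->  {kind.kind.value}"
          + (f" (separator {kind.separator!r})" if kind.separator else ""))

print("\n--- collapsing conserves counts ---")
reads = ["TACCTCGTA"] * 5 + ["GGGTACCTC"] * 2 + ["ACGTACGTA"]
collapsed = collapse(reads)
for c in collapsed:
    print(f"{c.rank_id}: {c.sequence} x{c.count}")
print(f"total {sum(c.count for c in collapsed)} == input {len(reads)}")

with tempfile.TemporaryDirectory() as tmp:
    rc = Path(tmp) / "reads.rc"
    write_readcount(collapsed, rc, separator="#")
    print("\n--- read-count FASTA round trip ---")
    print(rc.read_text().rstrip())
    back = list(read_records(rc, detect_format_file(rc)))
    print("round trip identical:", back == collapsed)
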