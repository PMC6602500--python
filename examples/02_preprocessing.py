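"""Protocol-aware preprocessing: adapters, randomized flanks, UMIs, QC.

Builds a small synthetic QIAseq-style library (3' adapter followed by a
12-base UMI, with PCR duplicates) and runs the full preprocessing chain.
The UMI dedup count equals the number of distinct molecules, not reads.
"""

import numpy as np

from srnaprof import PRESETS, preprocess_sample
from srnaprof.io_formats import SequenceRecord

rng = np.random.default_rng(11)
preset = PRESETS["qiaseq"]
insert = "TGAGGTAGTAGGTTGTATAGTT"  # a let-7 style 22-mer

# 40 molecules (distinct UMIs), PCR-amplified to 200 reads, plus 50 dimers
umis = ["".join(rng.choice(list("ACGT"), size=12)) for _ in range(40)]
reads = []
for i in range(200):
    umi = umis[rng.integers(len(umis))]
    seq = insert + preset.adapter3 + umi
    reads.append(SequenceRecord(f"r{i}", seq, [35] * len(seq)))
for i in range(50):
    seq = preset.adapter3 + umis[0]
    reads.append(SequenceRecord(f"d{i}", seq, [35] * len(seq)))

collapsed, stats = preprocess_sample(reads, preset)
print(f"input reads:        {stats.reads_input}")
print(f"adapter trimmed:    {stats.reads_adapter_trimmed}")
print(f"adapter dimers:     {stats.reads_dimer} "
      f"({100 * stats.dimer_fraction:.0f}% — high values flag low RNA input)")
print(f"UMI dedup removed:  {stats.umi_dedup_removed} PCR duplicates")
(mol,) = collapsed
print(f"molecules recovered: {mol.sequence} x{mol.count} "
      f"(== {len(umis)} planted UMIs)")
print(f"length histogram:   {stats.length_histogram}")
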