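"""Seed-match target sites of let-7a in synthetic 3' UTRs.

The scanner reports 6mer/7mer-A1/7mer-m8/8mer matches of the miRNA seed's
reverse complement, keeping only the most specific type at each locus.
"""

import numpy as np

from srnaprof.targets import find_seed_sites, seed_patterns

LET7A = "UGAGGUAGUAGGUUGUAUAGUU"

pats = seed_patterns(LET7A)
print("let-7a seed patterns (5'->3' on the target):")
for t in ("6mer", "7mer-A1", "7mer-m8", "8mer"):
    print(f"  {t:>8}: {pats[t]}")

rng = np.random.default_rng(9)
utrs = {f"utr{i}": "".join(rng.choice(list("ACGT"), size=800))
        for i in range(20)}
utrs["utr_planted"] = "A" * 30 + pats["8mer"] + "G" * 30

sites = find_seed_sites("let-7a", LET7A, utrs)
print(f"\n{len(sites)} sites across {len(utrs)} UTRs:")
from collections import Counter
for t, n in Counter(s.site_type for s in sites).most_common():
    print(f"  {t:>8}: {n}")
print("\nplanted 8mer found:",
      [(s.utr_id, s.start, s.site_type) for s in sites
       if s.utr_id == "utr_planted"])
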