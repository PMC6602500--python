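"""Coverage tracks: bedGraph intervals and merged BED6 regions.

Coverage sums read counts per base (full assignment); contiguously covered
regions merge into BED records scored by their peak coverage.
"""

from srnaprof.tracks import GenomicPlacement, make_bedgraph, merge_to_bed

placements = [
    GenomicPlacement("chr1", 100, 122, "+", 5, "r1"),
    GenomicPlacement("chr1", 110, 132, "+", 3, "r2"),
    GenomicPlacement("chr1", 200, 221, "-", 7, "r3"),
]

track = make_bedgraph(placements)
print("--- bedGraph (chrom, start, end, coverage) ---")
for iv in track.intervals:
    print("\t".join(map(str, iv)))

mass = sum((e - s) * v for _, s, e, v in track.intervals)
reads = sum(p.read_length * p.count for p in placements)
print(f"coverage mass {mass} == sum(read_length x count) {reads}")

print("\n--- merged BED6 (score = regional peak coverage) ---")
for b in merge_to_bed(track):
    print(f"{b.chrom}\t{b.start}\t{b.end}\t{b.name}\t{b.score}\t{b.strand}")

print("\n--- minus strand only ---")
for iv in make_bedgraph(placements, scope="minus").intervals:
    print("\t".join(map(str, iv)))
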