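# Methods

This note documents the models, conventions and numerical choices behind
`srnaprof`, and what the synthetic-data tests do and do not demonstrate.

## Input formats and detection

Three encodings are accepted: FASTQ (4-line, Phred+33), FASTA (wrapped or
unwrapped), and read-count FASTA, where each header is
`>name<separator><count>` and the sequence is unique. Detection is purely
content-based on the first 40 non-empty lines (bounded memory on large
files); the file extension is never consulted. Read-count separators are
tried in the order `#`, `-`, `_x`, `:` and every sampled header must parse
under the same separator. Bare `_` is deliberately not a candidate:
ordinary FASTA identifiers such as `chr_region_1` end in `_<integer>`
without being counts, and treating them as read counts would silently
corrupt plain FASTA input; the common `_x<count>` spelling is still
recognized. Headers that parse under conflicting separators raise an
explicit ambiguity error rather than guessing.

Phred encoding is fixed at offset 33; modern instruments emit nothing
else. `U` is normalized to `T` on read. N-containing reads pass through
I/O untouched — filtering is a preprocessing concern.

## Preprocessing

Each library-preparation protocol is a declared `ProtocolPreset`: 3'
adapter, randomized flanking bases stripped after trimming (NEXTflex-style
4N), and UMI length/position (QIAseq places a 12-base UMI after the 3'
adapter). The shipped presets are data, not code, and a fully custom
preset can be supplied. Adapter search takes the leftmost position where a
prefix of the adapter (≥ `min_overlap`, default 10) matches with a
mismatch fraction ≤ `max_mismatch_rate` (default 0.1); the adapter may run
off the 3' end of the read. Reads without an adapter are discarded by
default (configurable), since an untrimmed 3' end cannot be interpreted
under a 3'-adapter protocol.

An adapter dimer is a read whose insert has length 0 after trimming —
two adapters ligated with nothing in between; the dimer fraction is a key
library-quality signal. Reads with inserts of 1–14 nt count as
length-filtered, not dimers (default length window 15–∞; the shortest
annotated matures are ~16 nt).

Stage order is fixed: trim → UMI extraction → quality filter (on the
trimmed insert's scores) → length filter → UMI deduplication or plain
collapsing. The `mean` filter keeps reads whose average Phred score
reaches the threshold; `min` discards a read if any single position falls
below it, hence min-survivors are always a subset of mean-survivors at
equal threshold. UMI deduplication counts distinct UMIs per insert
sequence, collapsing PCR duplicates to molecules. QC accounting places
every input read in exactly one bucket (no-adapter, dimer,
quality-filtered, length-filtered, survivor).

## Library-mode alignment

Reads map directly against reference RNA sequences. A placement requires
an exact match of the read's first 20 bases (the whole read when shorter);
the remaining 3' bases extend gaplessly with at most 2 mismatches
(defaults; both configurable). The 5'-anchored exact seed reflects small
RNA biology: 5' ends are constrained (seed-shifted isomiRs are rare and
change targeting), while 3' ends carry trimming, extension and
non-templated tails — exactly the variation the free 3' extension
tolerates. Indels are not modeled. Only placements achieving the minimum
mismatch count are retained. Reads with more than 10 retained placements
(configurable) are flagged Highly Redundant (HR) and excluded from
expression profiling; they are reported separately and excluded from
coverage tracks. Multiplicity is counted jointly across all loaded
libraries. An optional both-strands mode reverse-complements the read for
non-miRNA libraries.

On references of this size the seeded index is provably equivalent to an
exhaustive all-offsets scan (tested against one); the seed is an indexing
device, not an approximation. One divergence worth noting: tools built on
genome mappers may allow mismatches inside the seed region; we require the
seed to be exact, which is stricter and deterministic.

## Expression and multiple mapping

A read placement contributes to the mature product whose annotated window
it overlaps within tolerance |5' offset| ≤ 3 and |3' offset| ≤ 5 (after
peeling non-templated bases); placements outside every window accrue to a
`<precursor>:hairpin` record. The tolerance spans reported isomiR offset
ranges without absorbing unrelated precursor fragments. Expression rows
are keyed by (mature, precursor) because a mature name may recur on
several precursors.

Three multiple-mapping policies: *full* gives every placement the whole
read count (totals can exceed the library size); *adjusted* divides the
count by the number of placements (the default for expression matrices);
*single* assigns the whole count to the reference with the highest
provisional expression computed from uniquely mapping reads, ties broken
lexicographically by (reference, start) for determinism. Under adjusted
and single the grand total equals the mapped read count exactly. RPM
normalizes the chosen column to reads per million.

## isomiR classification

For each aligned read against its mature window: the non-templated
addition (NTA) is the maximal 3'-terminal run of read bases that mismatch
the precursor at their aligned positions — a 3' base matching the template
is templated by definition. The 5' offset is read_start − mature_start
(positive = starts inside the mature); the 3' offset is computed after NTA
peeling. Internal mismatches outside the NTA are nucleotide variants.

Categories: canonical (offsets 0, no NTA, no variants); canonical with
nucleotide changes; NTA; 5' length variant; 3' length variant; multiple
length variant (both offsets non-zero). Hierarchical mode assigns exactly
one label in that precedence order (NTA outranks length variants); fuzzy
mode returns every applicable label — a read trimmed at both ends carries
{LV5P, LV3P, MV} — and always contains the hierarchical winner.

## Sequence variants

Variants are tallied at precursor level from alignment mismatches using
full-assignment counts (integer evidence; fractional reads would make the
variant-read column meaningless). NTA bases are excluded from both
variant evidence and coverage. Phred scores are not used. A record
(precursor, ref>alt, position, covering reads, variant reads) is emitted
when variant reads ≥ 2, coverage ≥ 10 and variant fraction ≥ 5% (defaults,
all exposed). Raising any threshold can only remove records. With the
default thresholds a planted 30% variant is recovered while a 0.1%
per-base sequencing-error floor produces no calls; the fraction gate is
what rejects errors, since absolute error counts grow with depth.

Known limitation: a variant at a read's final templated base is
indistinguishable from a one-base NTA and is peeled, and variant reads
carrying additional 3' modifications can exceed the mismatch budget; both
effects bias recovered variant frequencies slightly downward in samples
with rich isomiR profiles (visible in the worked example: 24% recovered
for a 30% plant under the default isomiR mix, vs ~30% on canonical-only
samples).

## Coverage tracks

Per-base coverage sums counts of covering placements (full assignment; the
adjusted option divides each read's count by its number of placements,
written with 4 decimals). Tracks exist per strand scope (pooled, +, −)
and per read-length class (all; 19–23 nt; additionally 24 nt for plants,
where 24-mers are a distinct biological class). Intervals are maximal
constant-value runs, 0-based half-open. Contiguously covered runs merge
into six-column BED records whose score is the regional coverage maximum;
scores above 1000 are written as-is (a deviation from the strict BED spec,
noted so downstream consumers can clamp if needed). Coverage mass — Σ
interval length × value — equals Σ read length × count exactly.

## Differential expression

The matrix is features × samples with counts from the chosen
multiple-mapping mode (adjusted by default). Internal methods normalize
columns to counts per million; external backends receive raw counts and
normalize themselves. The internal test is Welch's unequal-variance
t-test on log2(CPM+1), with Benjamini–Hochberg adjustment at α = 0.05.
Zero-variance features get p = 1 when group means agree (no evidence) and
p = 0 when they differ (the degenerate limit), avoiding NaN propagation.
Fold change is log2(mean_A+1) − log2(mean_B+1) on normalized means — the
+1 pseudocount prevents division by zero and damps chance fold changes at
very low expression, and the difference-of-logs form makes group-swap
antisymmetry exact in floating point. "Up" means higher in the first
listed group.

External backends plug in behind one contract: edgeR runs through an
Rscript subprocess (exactTest on a TMM-normalized DGEList), DESeq2 through
pydeseq2; a missing runtime raises `BackendUnavailable` and the consensus
proceeds over the remaining methods, recording the omission. A
NOISeq-style probability backend would map significance as posterior
probability ≥ 1 − α; no runtime for it is registered here.

Consensus intersects per-method significant sets (overall and split by
direction); UpSet membership tables list, for every non-empty method
subset, the features significant in exactly that subset. A parallel
membership marks |log2FC| ≥ 1 (configurable), which depends only on the
normalized matrix and is therefore identical across methods.

## Target sites

The seed scanner reports exact occurrences of the reverse complement of
miRNA positions 2–7 (6mer) or 2–8 (7mer-m8), each optionally followed by
an A opposite position 1 (7mer-A1, 8mer) — the canonical animal seed-site
nomenclature, chosen because exact-match scanning is what makes the method
several-fold faster than thermodynamic predictors. No wobble pairing. At
one seed locus only the most specific qualifying type is reported
(8mer > 7mer-m8 > 7mer-A1 > 6mer); distinct loci, overlapping or not, are
all reported.

## Synthetic data

The generator is the testing backbone: every pipeline stage is validated
against data with known truth. `simulate_reads` draws reads from mature
windows of (generated or supplied) precursors by abundance weight, applies
an isomiR profile (default 55% canonical / 20% NTA / 5% 5'LV / 15% 3'LV /
5% MV, shifts of ±1–2 nt — a typical mammalian miRNA-seq mix), plants
variants at set allele frequencies, flips bases at a per-base error rate
(default 0.1%), and wraps inserts in a protocol's geometry. Qualities are
constant Q30; the error model is substitution-only and does not lower the
score at error positions. Planted NTA tails mismatch the template at
every added base so planted categories are unambiguous under the NTA
definition. `simulate_counts` draws negative-binomial counts (dispersion
α = 0.1, variance μ + αμ², i.e. a biological CV of ~0.32 — moderate for
human data) around lognormal base means (median 200), scaling group-A
means by 2^log2FC for planted features.

All randomness flows through one seeded generator; identical seeds give
byte-identical FASTQ output.

What passing these tests shows — and does not. The generator emulates
read structure, isomiR geometry, planted variants, uniform sequencing
errors and NB count dispersion. It does not model ligation or GC bias,
position-dependent error rates, quality-score degradation, adapter
sequencing errors, or cross-mapping between genuine paralogous miRNA
families (generated precursors are rejection-sampled to keep matures
uniquely mappable). Recovery on synthetic data therefore demonstrates
correctness of the algorithms under their stated assumptions, not
end-to-end accuracy on arbitrary real libraries.

## Problem sizes and benchmark conventions

Test and acceptance runs use 5 precursors (~70 nt), read depths of
10⁴, DE matrices of 500–1000 features at 5 samples per group, and external
backends on 80–300 features at 4–5 per group — sizes at which every oracle
comparison is exhaustive and the whole suite completes in minutes on one
core. The type-I error of the internal t-test is measured on null NB
matrices as the fraction of features with p < 0.05 (expected 0.05 ± 3
binomial SE); power is measured the same way — the fraction of planted
|log2FC| = 2 features with p < α — i.e. the power of the per-feature test,
not the recall of the BH selection, which depends additionally on the
true-effect fraction and fluctuates with the seed.
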