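"""Multi-mapping assignment, isomiR classification, SNV calling, composition."""

from collections import Counter

import numpy as np
import pytest

from srnaprof.io_formats import CollapsedRead, collapse
from srnaprof.librarymap import (
    Alignment,
    AlignmentSet,
    MatureAnnotation,
    ReferenceLibrary,
    align_sample,
)
from srnaprof.profiler import (
    CANONICAL,
    CANONICAL_NT_CHANGE,
    LV3P,
    LV5P,
    MV,
    NTA,
    OutsideTolerance,
    UnknownMode,
    assign_multimappers,
    classify_isomir,
    detect_snvs,
    peel_nta,
    quantify,
    rna_type_composition,
)
from srnaprof import simdata


def _two_placement_set():
    """One read (count 10) on P1 and P2; P1 carries 100 unique-read counts,
    P2 carries 10."""
    multi = CollapsedRead("A" * 22, 10, "m")
    u1 = CollapsedRead("C" * 22, 100, "u1")
    u2 = CollapsedRead("G" * 22, 10, "u2")
    return AlignmentSet(alignments=[
        Alignment(read=multi, ref_name="P1", start=0, multiplicity=2),
        Alignment(read=multi, ref_name="P2", start=0, multiplicity=2),
        Alignment(read=u1, ref_name="P1", start=10, multiplicity=1),
        Alignment(read=u2, ref_name="P2", start=10, multiplicity=1),
    ])


class TestAssignMultimappers:
    def test_adjusted_divides_by_multiplicity(self):
        eff = assign_multimappers(_two_placement_set(), "adjusted")
        assert eff[:2] == [5.0, 5.0]

    def test_full_duplicates_count(self):
        eff = assign_multimappers(_two_placement_set(), "full")
        assert eff[:2] == [10.0, 10.0]

    def test_single_goes_to_highest_expressed(self):
        eff = assign_multimappers(_two_placement_set(), "single")
        assert eff[:2] == [10.0, 0.0]  # P1 has the higher unique expression

    def test_single_tie_breaks_lexicographically(self):
        aset = _two_placement_set()
        aset.alignments[3] = Alignment(
            read=CollapsedRead("G" * 22, 100, "u2"), ref_name="P2",
            start=10, multiplicity=1)
        eff = assign_multimappers(aset, "single")
        assert eff[:2] == [10.0, 0.0]  # tie 100 vs 100 -> P1 < P2

    def test_unknown_mode(self):
        with pytest.raises(UnknownMode):
            assign_multimappers(_two_placement_set(), "bogus")

    def test_count_conservation(self):
        aset = _two_placement_set()
        total = 10 + 100 + 10
        for mode in ("adjusted", "single"):
            assert sum(assign_multimappers(aset, mode)) == total
        assert sum(assign_multimappers(aset, "full")) >= total


class TestClassifyIsomir:
    def _align(self, lib, mature, seq, start=None):
        (aset) = align_sample([CollapsedRead(seq, 1, "r")], [lib])
        assert aset.alignments, "construction must map"
        return aset.alignments[0]

    def test_canonical(self, tiny_library):
        lib, mature = tiny_library
        prec = lib.sequences["prec-X"]
        a = self._align(lib, mature, prec[mature.start : mature.end])
        call = classify_isomir(a, mature, prec, mode="fuzzy")
        assert call.categories == {CANONICAL}
        assert call.hierarchical_category == CANONICAL
        assert (call.offset5, call.offset3, call.nta, call.snvs) == (0, 0, "", [])

    def test_nta_peeling(self, tiny_library):
        """Mature + one base that mismatches the next templated base."""
        lib, mature = tiny_library
        prec = lib.sequences["prec-X"]
        templated = prec[mature.end]
        added = {"A": "C", "C": "G", "G": "T", "T": "A"}[templated]
        a = self._align(lib, mature, prec[mature.start : mature.end] + added)
        call = classify_isomir(a, mature, prec, mode="fuzzy")
        assert call.nta == added
        assert call.categories == {NTA}
        assert call.hierarchical_category == NTA
        assert call.offset3 == 0  # computed after peeling

    def test_templated_extension_is_lv3p_not_nta(self, tiny_library):
        lib, mature = tiny_library
        prec = lib.sequences["prec-X"]
        a = self._align(lib, mature, prec[mature.start : mature.end + 1])
        call = classify_isomir(a, mature, prec, mode="fuzzy")
        assert call.nta == "" and call.categories == {LV3P}

    def test_multiple_length_variant_fuzzy_vs_hierarchical(self, tiny_library):
        lib, mature = tiny_library
        prec = lib.sequences["prec-X"]
        seq = prec[mature.start + 1 : mature.end - 2]  # 5' trim 1, 3' trim 2
        a = self._align(lib, mature, seq)
        fuzzy = classify_isomir(a, mature, prec, mode="fuzzy")
        assert fuzzy.categories == {LV5P, LV3P, MV}
        hier = classify_isomir(a, mature, prec, mode="hierarchical")
        assert hier.hierarchical_category == MV
        assert hier.categories == {MV}
        assert hier.hierarchical_category in fuzzy.categories

    def test_internal_substitution(self, tiny_library):
        lib, mature = tiny_library
        prec = lib.sequences["prec-X"]
        seq = list(prec[mature.start : mature.end])
        pos = 20  # outside the exact seed, not terminal
        ref_base = seq[pos]
        seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref_base]
        a = self._align(lib, mature, "".join(seq))
        call = classify_isomir(a, mature, prec)
        assert call.hierarchical_category == CANONICAL_NT_CHANGE
        assert call.snvs == [(pos, ref_base, seq[pos])]

    def test_outside_tolerance(self, tiny_library):
        lib, mature = tiny_library
        prec = lib.sequences["prec-X"]
        a = self._align(lib, mature, prec[0:22])  # offset5 = -10
        with pytest.raises(OutsideTolerance):
            classify_isomir(a, mature, prec)

    def test_hierarchical_partition_on_simulated_sample(self, toy_library):
        """Every classified read gets exactly one hierarchical category and
        fuzzy categories always contain it."""
        lib, annots = toy_library
        spec = simdata.SimSpec(
            library=lib, annotations=annots,
            abundances={a.mature_name: 1.0 for a in annots},
            error_rate=0.0, depth=3000, seed=17)
        recs, truth = simdata.simulate_reads(spec)
        aset = align_sample(collapse(recs), [lib])
        amap = {a.precursor_name: a for a in annots}
        recovered = Counter()
        for a in aset.alignments:
            h = classify_isomir(a, amap[a.ref_name],
                                lib.sequences[a.ref_name], "hierarchical")
            f = classify_isomir(a, amap[a.ref_name],
                                lib.sequences[a.ref_name], "fuzzy")
            assert len(h.categories) == 1
            assert h.hierarchical_category in f.categories
            recovered[h.hierarchical_category] += a.read.count
        planted = Counter(truth.read_categories)
        key = {"canonical": CANONICAL, "nta": NTA, "lv5p": LV5P,
               "lv3p": LV3P, "mv": MV}
        assert recovered == Counter({key[k]: v for k, v in planted.items()})


class TestQuantify:
    def test_exact_mature_read(self, tiny_library):
        lib, mature = tiny_library
        prec = lib.sequences
        seq = prec["prec-X"][mature.start : mature.end]
        aset = align_sample([CollapsedRead(seq, 7, "r")], [lib])
        (rec,) = quantify(aset, [mature], prec)
        assert rec.mature_name == "mir-X"
        assert rec.raw_count == rec.adjusted_count == 7

    def test_hairpin_fallback(self, tiny_library):
        lib, mature = tiny_library
        prec = lib.sequences
        seq = prec["prec-X"][0:22]  # far outside the mature window
        aset = align_sample([CollapsedRead(seq, 3, "r")], [lib])
        (rec,) = quantify(aset, [mature], prec)
        assert rec.mature_name == "prec-X:hairpin"

    def test_no_reads(self, tiny_library):
        lib, mature = tiny_library
        aset = align_sample([], [lib])
        assert quantify(aset, [mature], lib.sequences) == []

    def test_simulated_counts_recovered_adjusted(self, toy_library):
        lib, annots = toy_library
        spec = simdata.SimSpec(
            library=lib, annotations=annots,
            abundances={a.mature_name: w for a, w in
                        zip(annots, [5, 3, 1, 1, 1])},
            profile={"canonical": 1.0, "nta": 0, "lv5p": 0, "lv3p": 0, "mv": 0},
            error_rate=0.0, depth=4000, seed=23)
        recs, truth = simdata.simulate_reads(spec)
        aset = align_sample(collapse(recs), [lib])
        got = {r.mature_name: r.adjusted_count
               for r in quantify(aset, annots, lib.sequences)}
        assert got == pytest.approx(truth.mature_counts)


class TestDetectSnvs:
    def test_thresholds_by_construction(self, tiny_library):
        lib, mature = tiny_library
        prec = dict(lib.sequences)
        ref = prec["prec-X"]
        pos = mature.start + 20
        ref_base = ref[pos]
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref_base]
        wt = ref[mature.start : mature.end]
        var = wt[:20] + alt + wt[21:]
        aset = align_sample([CollapsedRead(wt, 60, "a"),
                             CollapsedRead(var, 40, "b")], [lib])
        (snv,) = detect_snvs(aset, prec, min_cov=10, min_var_reads=2,
                             min_var_fraction=0.05)
        assert (snv.precursor_name, snv.variant_type, snv.position) == (
            "prec-X", f"{ref_base}>{alt}", pos)
        assert (snv.covering_reads, snv.variant_reads) == (100, 40)

    def test_nta_excluded_from_evidence(self, tiny_library):
        lib, mature = tiny_library
        prec = dict(lib.sequences)
        ref = prec["prec-X"]
        templated = ref[mature.end]
        added = {"A": "C", "C": "G", "G": "T", "T": "A"}[templated]
        seq = ref[mature.start : mature.end] + added
        aset = align_sample([CollapsedRead(seq, 50, "a")], [lib])
        assert detect_snvs(aset, prec, min_cov=1, min_var_reads=1,
                           min_var_fraction=0.0) == []

    def test_threshold_monotonicity(self, toy_library, rng):
        lib, annots = toy_library
        spec = simdata.SimSpec(
            library=lib, annotations=annots,
            abundances={a.mature_name: 1.0 for a in annots},
            snv_plants=[("prec-1", 35, "A", 0.3), ("prec-2", 36, "C", 0.2)],
            error_rate=0.005, depth=4000, seed=31)
        recs, _ = simdata.simulate_reads(spec)
        aset = align_sample(collapse(recs), [lib])
        base = detect_snvs(aset, lib.sequences, 10, 2, 0.05)
        for args in [(20, 2, 0.05), (10, 5, 0.05), (10, 2, 0.25)]:
            stricter = detect_snvs(aset, lib.sequences, *args)
            assert {(s.precursor_name, s.position, s.variant_type)
                    for s in stricter} <= {
                (s.precursor_name, s.position, s.variant_type) for s in base}


class TestComposition:
    def test_priority_assignment(self):
        motif = "ACGTTGCAGGTCATCGATCGTA"  # non-repetitive 22-mer
        mir = ReferenceLibrary("mirna", {"m1": "GG" + motif + "TT"},
                               priority_rank=1)
        rrna = ReferenceLibrary("rrna", {"r1": "TT" + motif + "GG"},
                                priority_rank=5)
        reads = [CollapsedRead(motif, 10, "r")]
        aset = align_sample(reads, [mir, rrna])
        comp = rna_type_composition(aset, {"mirna": 1, "rrna": 5})
        assert comp.fractions == {"mirna": 1.0}
        assert comp.unassigned == 0.0

    def test_nothing_maps(self, tiny_library):
        lib, _ = tiny_library
        aset = align_sample([CollapsedRead("A" * 22, 5, "r")], [lib])
        comp = rna_type_composition(aset, {"mirna": 1})
        assert comp.unassigned == 1.0

    def test_planted_mix_recovered(self, rng):
        mir_lib, annots = simdata.make_reference(
            np.random.default_rng(7), n_precursors=3)
        raw, rannots = simdata.make_reference(
            np.random.default_rng(8), n_precursors=2,
            precursor_len=120, mature_len=30)
        rrna_lib = ReferenceLibrary(
            "rrna", {f"rrna-{k}": v for k, v in raw.sequences.items()},
            priority_rank=5)
        reads = []
        for i in range(700):
            a = annots[i % len(annots)]
            reads.append(mir_lib.sequences[a.precursor_name][a.start : a.end])
        for i in range(300):
            a = rannots[i % len(rannots)]
            reads.append(
                rrna_lib.sequences[f"rrna-{a.precursor_name}"][a.start : a.end])
        aset = align_sample(collapse(reads), [mir_lib, rrna_lib])
        comp = rna_type_composition(aset, {"mirna": 1, "rrna": 5})
        assert comp.fractions["mirna"] == pytest.approx(0.7)
        assert comp.fractions["rrna"] == pytest.approx(0.3)
        total = sum(comp.fractions.values()) + comp.unassigned
        assert total == pytest.approx(1.0, abs=1e-9)

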