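"""Sequence statistics, stuffer design, assembly and validation."""

import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as mt
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_longest_repeat, brute_longest_self_complement

from gisaq.errors import AssemblyError, DesignError, InvalidSequenceError
from gisaq.standards import (TM_SODIUM_MM, TM_STRAND_NM, DesignConstraints,
                             PrimerCriteria, ScaffoldLayout, Segment,
                             assemble_internal_standard,
                             cross_amplification_matrix, default_layout,
                             design_specific_primers, detect_layout,
                             gc_fraction, generate_stuffer, longest_repeat,
                             longest_self_complement, max_homopolymer_run,
                             melting_temperature, reverse_complement,
                             validate_internal_standard)

IUPAC = "ACGTRYSWKMBDHVN"
PRINTED_GC = {"IS1": 46.40, "IS2": 46.20, "IS3": 45.60, "IS4": 45.40,
              "IS5": 46.90}


class TestCompositionStats:
    @pytest.mark.parametrize("seq,expected", [("GCGC", 1.0), ("ATAT", 0.0),
                                              ("ACGT", 0.5)])
    def test_gc_fraction(self, seq, expected):
        assert gc_fraction(seq) == expected

    def test_gc_fraction_rejects_bad_input(self):
        with pytest.raises(InvalidSequenceError):
            gc_fraction("")
        with pytest.raises(InvalidSequenceError):
            gc_fraction("ACGX")

    @pytest.mark.parametrize("seq,expected", [
        ("A" * 11, 11),
        ("ACGT", 1),
        ("CGTCGT" + "A" * 10 + "CGTCG", 10),  # boundary: 10 passes the default
    ])
    def test_max_homopolymer_run(self, seq, expected):
        assert max_homopolymer_run(seq) == expected

    def test_longest_repeat_small_cases(self):
        assert longest_repeat("ACGTACGT") == 4
        rng = np.random.default_rng(0)
        background = "".join(rng.choice(list("ACGT"), size=200))
        block = "ACGTTGCACGATGCACG"  # 17-mer pasted twice
        seq = background[:50] + block + background[50:120] + block + background[120:]
        assert longest_repeat(seq) >= 17
        assert longest_repeat(seq) > DesignConstraints(
            target_length=10, target_gc=0.5).max_repeat

    def test_longest_self_complement_cases(self):
        assert longest_self_complement("AAAACGCGTTTT") >= 8
        assert longest_self_complement("AAAA") == 0
        stem = "ACGTTACGCAT"  # 11-base hairpin stem
        hairpin = stem + "TTTT" + reverse_complement(stem)
        assert longest_self_complement(hairpin) >= 11

    @pytest.mark.parametrize("func,oracle", [
        (longest_repeat, brute_longest_repeat),
        (longest_self_complement, brute_longest_self_complement),
    ])
    def test_scanners_match_bruteforce(self, func, oracle):
        rng = np.random.default_rng(42)
        for _ in range(150):
            n = int(rng.integers(2, 61))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            assert func(seq) == oracle(seq), seq

    def test_scanner_preconditions(self):
        with pytest.raises(InvalidSequenceError):
            longest_repeat("A")
        with pytest.raises(InvalidSequenceError):
            longest_self_complement("C")


class TestReverseComplement:
    def test_degenerate_primer(self):
        assert reverse_complement("GTGGACTACHVGGGTWTCTAAT") == "ATTAGAWACCCBDGTAGTCCAC"

    def test_edge_cases(self):
        assert reverse_complement("") == ""
        assert reverse_complement("ACGT") == "ACGT"

    def test_unknown_symbol(self):
        with pytest.raises(InvalidSequenceError):
            reverse_complement("ACGZ")

    @settings(deadline=None, max_examples=200)
    @given(st.text(alphabet=IUPAC, max_size=80))
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq


class TestMeltingTemperature:
    def test_matches_independent_nearest_neighbor(self):
        """Equal within 0.01 C to biopython's unified-parameter route."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(8, 31))
            primer = "".join(rng.choice(list("ACGT"), size=n))
            if primer == reverse_complement(primer):
                continue  # fully palindromic duplexes use a symmetry term
            ref = mt.Tm_NN(primer, nn_table=mt.DNA_NN4, Na=TM_SODIUM_MM,
                           dnac1=TM_STRAND_NM, dnac2=TM_STRAND_NM, saltcorr=5)
            assert melting_temperature(primer) == pytest.approx(ref, abs=0.01)

    def test_deterministic_and_monotone_in_gc(self):
        primer = "GTACTCCTACGGGAGGCAGCA"
        assert melting_temperature(primer) == melting_temperature(primer)
        assert melting_temperature("GCGGCCGCGGCCGCGGAT") > melting_temperature(
            "ATATTAATATTAATATTA")

    def test_rejects_degenerate_and_short(self):
        with pytest.raises(InvalidSequenceError):
            melting_temperature("ACGTACGN")
        with pytest.raises(InvalidSequenceError):
            melting_temperature("ACGT")


class TestStufferGeneration:
    def test_satisfies_constraints_over_many_seeds(self):
        cons = DesignConstraints(target_length=120, target_gc=0.46)
        for seed in range(100):
            seq = generate_stuffer(cons, rng_seed=seed)
            assert len(seq) == 120
            assert abs(gc_fraction(seq) - 0.46) <= 0.01 + 1e-12
            assert max_homopolymer_run(seq) <= cons.max_homopolymer
            assert longest_repeat(seq) <= cons.max_repeat
            assert longest_self_complement(seq) <= cons.max_self_complement

    def test_reproducible(self):
        cons = DesignConstraints(target_length=300, target_gc=0.46)
        assert generate_stuffer(cons, rng_seed=1) == generate_stuffer(cons, rng_seed=1)

    def test_infeasible_constraints(self):
        with pytest.raises(ValueError):
            DesignConstraints(target_length=100, target_gc=0.5, max_homopolymer=0)
        # GC window admitting no integer count
        cons = DesignConstraints(target_length=20, target_gc=0.46,
                                 gc_tolerance=0.001)
        with pytest.raises(DesignError):
            generate_stuffer(cons, rng_seed=0)


class TestAssemblyAndAnchors:
    def test_printed_standards_have_all_anchors(self, reference_standards):
        assert len(reference_standards) == 5
        for iss in reference_standards:
            assert iss.sequence.startswith("GTACTCCTACGGGAGGCAGCA")  # 336F
            assert "GCATCGATGAAGAACGCAGC" in iss.sequence              # ITS3
            assert "GCATATCAATAAGCGGAGGA" in iss.sequence              # rc(ITS4)
            # degenerate-matched rc(806R) suffix checked by layout detection
            detect_layout(iss.sequence, id=iss.id)

    def test_printed_length_and_gc(self, reference_standards):
        for iss in reference_standards:
            assert iss.length == 472
            assert iss.gc_percent == pytest.approx(PRINTED_GC[iss.id], abs=0.1)
        is1 = next(s for s in reference_standards if s.id == "IS1")
        assert abs(is1.gc_percent - 46.40) < 0.005

    def test_assembly_roundtrips_coordinates(self, designed_standards):
        for iss in designed_standards:
            redetected = detect_layout(iss.sequence, id=iss.id)
            assert redetected.coordinates == iss.coordinates
            assert redetected.sequence == iss.sequence

    def test_fungal_sites_must_nest_in_order(self):
        with pytest.raises(AssemblyError):
            ScaffoldLayout((
                Segment("fwd_universal_bact"),
                Segment("rc_rev_universal_fungal_site"),
                Segment("stuffer", length=100),
                Segment("fwd_universal_fungal_site"),
                Segment("rc_rev_universal_bact"),
            ))

    def test_missing_segment_is_assembly_error(self):
        layout = default_layout()
        with pytest.raises(AssemblyError):
            assemble_internal_standard(layout, ["ACGT" * 10], id="bad")

    def test_scrambled_tail_fails_anchor_check(self, reference_standards):
        iss = reference_standards[0]
        scrambled = iss.sequence[:-22] + "ACGT" * 5 + "AC"
        with pytest.raises(AssemblyError):
            detect_layout(scrambled, id="scrambled")


class TestSpecificPrimers:
    def test_cross_amplification_matrix_is_diagonal(self, designed_standards):
        matrix = cross_amplification_matrix(designed_standards)
        assert np.array_equal(matrix, np.eye(len(designed_standards), dtype=bool))

    def test_primers_respect_composition_criteria(self, designed_standards):
        crit = PrimerCriteria()
        for iss in designed_standards:
            pair = iss.specific_primers
            for primer in (pair.forward, pair.reverse):
                assert max_homopolymer_run(primer) <= 3
                assert longest_self_complement(primer) <= 5
                assert "AAAA" not in primer  # homopolymer > 3 rejected
                assert crit.tm_window[0] <= melting_temperature(primer) <= crit.tm_window[1]

    def test_same_seed_same_pair(self, designed_standards):
        iss = designed_standards[0]
        a = design_specific_primers(iss, other_standards=designed_standards,
                                    rng_seed=99)
        b = design_specific_primers(iss, other_standards=designed_standards,
                                    rng_seed=99)
        assert (a.forward, a.reverse) == (b.forward, b.reverse)


class TestValidation:
    def test_printed_standards_pass_structure_checks(self, reference_standards):
        for iss in reference_standards:
            report = validate_internal_standard(iss)
            by_rule = {(r.rule, r.target): r for r in report.results}
            assert by_rule[("anchor_sites", "full")].passed
            assert by_rule[("homopolymer", "full")].observed <= 10

    def test_designed_standards_pass_everything(self, designed_standards):
        cons = DesignConstraints(target_length=472, target_gc=0.46)
        for iss in designed_standards:
            assert validate_internal_standard(iss, cons).passed

    def test_failure_is_reported_not_raised(self, reference_standards):
        iss = reference_standards[0]
        bad = detect_layout(iss.sequence, id="IS1-bad")
        bad.sequence = iss.sequence[:100] + "A" * 12 + iss.sequence[112:]
        report = validate_internal_standard(bad)
        assert not report.passed
        assert any(r.rule == "homopolymer" and not r.passed for r in report.results)
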