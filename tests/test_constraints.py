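import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligorepair.constraints import (
    ConstraintSet,
    error_profile,
    find_violations,
    gc_fraction,
    max_homopolymer_run,
    violation_penalty,
)

from conftest import FIG2_SEQ, random_seq
from oracles import naive_violations

dna = st.text(alphabet="ACGT", min_size=0, max_size=80)


def as_tuples(violations):
    return {(v.rule, v.start, v.end, round(v.magnitude, 9)) for v in violations}


class TestGcFraction:
    @pytest.mark.parametrize("seq,frac", [("ACGT", 0.5), ("AATT", 0.0), ("GGCC", 1.0)])
    def test_examples(self, seq, frac):
        assert gc_fraction(seq) == frac

    def test_n_counts_as_neither(self):
        assert gc_fraction("GCNN") == 0.5

    def test_empty_span_is_error(self):
        with pytest.raises(ValueError):
            gc_fraction("ACGT", 2, 2)


class TestFindViolations:
    def test_worked_example_run_of_five_and_length(self, cs30):
        violations = find_violations(FIG2_SEQ, cs30)
        assert {v.rule for v in violations} == {"homopolymer", "length"}
        (homo,) = [v for v in violations if v.rule == "homopolymer"]
        assert homo.span == (5, 10) and homo.magnitude == 2
        (length,) = [v for v in violations if v.rule == "length"]
        assert length.magnitude == 2

    def test_valid_sequence_yields_empty_list(self, cs30):
        assert find_violations("CGTACATGCATGCATGCTACGTACGTACAT", cs30) == []

    def test_overlapping_blacklist_occurrences(self):
        cs = ConstraintSet(gc_min=0, gc_max=1, blacklist=["CGTA"])
        violations = find_violations("ACGTACGTACGT", cs)
        hits = {(v.start, v.end) for v in violations if v.rule == "blacklist"}
        assert hits == {(1, 5), (5, 9)}

    def test_kmer_excess_occurrences(self):
        cs = ConstraintSet(gc_min=0, gc_max=1, max_homopolymer=10,
                           kmer_k=3, kmer_max_occurrences=1)
        # "ACGACG": ACG occurs twice -> one kmer violation, excess 1
        violations = [v for v in find_violations("ACGACG", cs) if v.rule == "kmer"]
        assert len(violations) == 1
        assert violations[0].magnitude == 1
        assert violations[0].span == (0, 6)

    def test_n_always_violates(self):
        cs = ConstraintSet(gc_min=0, gc_max=1)
        violations = find_violations("ACNT", cs)
        assert [(v.rule, v.span) for v in violations] == [("ambiguous", (2, 3))]

    def test_trailing_window_evaluated_alone(self):
        cs = ConstraintSet(window_size=4)
        # 6 nt: windows [0,4) and [4,6); trailing "AA" has GC 0 -> violation
        violations = find_violations("ACGTAA", cs)
        assert ("gc_window", (4, 6)) in [(v.rule, v.span) for v in violations]

    @settings(max_examples=200, derandomize=True)
    @given(dna)
    def test_spans_within_bounds(self, seq):
        cs = ConstraintSet(max_homopolymer=2, blacklist=["ACCA"], kmer_k=4,
                           target_length=20)
        for v in find_violations(seq, cs):
            assert 0 <= v.start < v.end <= len(seq) or (v.rule == "length" and not seq)
            assert v.magnitude > 0

    def test_agrees_with_naive_scanner_on_random_sequences(self, rng):
        cs = ConstraintSet(max_homopolymer=3, window_size=10,
                           blacklist=["GGTACC", "TTAA"], kmer_k=5,
                           kmer_max_occurrences=1, target_length=60)
        for _ in range(300):
            seq = random_seq(rng, rng.randint(0, 200), "ACGTN" if rng.random() < 0.2 else "ACGT")
            expected = naive_violations(
                seq, 0.4, 0.6, 10, 3, blacklist=["GGTACC", "TTAA"],
                kmer_k=5, kmer_m=1, target_len=60,
            )
            assert as_tuples(find_violations(seq, cs)) == expected, seq

    def test_homopolymer_monotone_in_run_growth(self, rng):
        cs = ConstraintSet(gc_min=0, gc_max=1, max_homopolymer=3)
        for _ in range(50):
            base = rng.choice("ACGT")
            prefix = random_seq(rng, rng.randint(0, 10)).rstrip(base)
            seq = prefix + base * 3
            before = [v for v in find_violations(seq, cs) if v.rule == "homopolymer"]
            after = [v for v in find_violations(seq + base, cs) if v.rule == "homopolymer"]
            grown = [v for v in after if v.end == len(seq) + 1]
            assert len(grown) == 1 and len(after) == len(before) + 1


class TestErrorProfile:
    def test_valid_sequence_all_zero(self, cs30):
        profile = error_profile("CGTACATGCATGCATGCTACGTACGTACAT", cs30)
        assert profile.total == 0 and profile.length_delta == 0
        assert all(s == 0 for s in profile.scores)

    def test_homopolymer_contribution(self):
        cs = ConstraintSet(gc_min=0, gc_max=1, max_homopolymer=3)
        seq = "TGCATAAAAAGCATGC"  # run of 5 A at [5,10)
        profile = error_profile(seq, cs)
        for i in range(5, 10):
            assert profile.scores[i] == pytest.approx((5 - 3) / 5)
        assert profile.total == pytest.approx(2.0)
        assert all(profile.scores[i] == 0 for i in range(len(seq)) if not 5 <= i < 10)

    def test_gc_window_contribution_targets_aggravating_bases(self):
        cs = ConstraintSet(window_size=10, max_homopolymer=10)
        seq = "GGCCGGCCAT"  # one window, GC 0.8 vs max 0.6
        profile = error_profile(seq, cs)
        # gc_global violates too (same span); window + global deviation = 0.4
        for i, b in enumerate(seq):
            if b in "GC":
                assert profile.scores[i] == pytest.approx(0.2 + 0.2)
            else:
                assert profile.scores[i] == 0

    def test_length_only_affects_delta(self):
        cs = ConstraintSet(target_length=5)
        profile = error_profile("ACGTACG", cs)
        assert profile.length_delta == 2
        assert profile.total == 0

    @settings(max_examples=200, derandomize=True)
    @given(dna)
    def test_zero_total_iff_no_violations(self, seq):
        cs = ConstraintSet(max_homopolymer=2, target_length=15, blacklist=["TATA"])
        violations = find_violations(seq, cs)
        profile = error_profile(seq, cs)
        clean = profile.total == 0 and profile.length_delta == 0
        assert clean == (not violations)

    def test_weights_scale_contributions(self):
        seq = "TGCATAAAAAGCATGC"
        heavy = ConstraintSet(gc_min=0, gc_max=1, max_homopolymer=3,
                              rule_weights={"homopolymer": 2.5})
        assert error_profile(seq, heavy).total == pytest.approx(5.0)


class TestViolationPenalty:
    def test_valid_sequence_zero(self, cs30):
        assert violation_penalty("CGTACATGCATGCATGCTACGTACGTACAT", cs30) == 0

    def test_weighted_counts(self):
        cs = ConstraintSet(gc_min=0, gc_max=1, max_homopolymer=3)
        assert violation_penalty("TTTTT", cs) == 1.0
        cs_w = ConstraintSet(gc_min=0, gc_max=1, blacklist=["CGTA"],
                             rule_weights={"blacklist": 0.5})
        assert violation_penalty("ACGTACGTACGT", cs_w) == pytest.approx(1.0)


def test_max_homopolymer_run():
    assert max_homopolymer_run("") == 0
    assert max_homopolymer_run("ACGT") == 1
    assert max_homopolymer_run("AACCCGT") == 3
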