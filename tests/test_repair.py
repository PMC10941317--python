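import random

import pytest

from oligorepair.constraints import ConstraintSet, find_violations, max_homopolymer_run
from oligorepair.io import SequenceRecord
from oligorepair.repair import (
    Cluster,
    Edit,
    edit_distance,
    keep_original_option,
    repair_cluster,
    repair_sequence,
    report_entry,
    sort_members,
)

from conftest import FIG2_SEQ, FIG3_SEQ, random_seq
from oracles import dp_edit_distance, valid_within_k_edits


def replay(seq, edits):
    for e in edits:
        seq = e.apply(seq)
    return seq


class TestEditDistance:
    @pytest.mark.parametrize(
        "a,b,d", [("ACGT", "ACGT", 0), ("ACGT", "AGT", 1), ("AAAA", "TTTT", 4),
                  ("", "ACG", 3)]
    )
    def test_examples(self, a, b, d):
        assert edit_distance(a, b) == d

    def test_agrees_with_dp_oracle(self, rng):
        for _ in range(100):
            a = random_seq(rng, rng.randint(0, 30))
            b = random_seq(rng, rng.randint(0, 30))
            assert edit_distance(a, b) == dp_edit_distance(a, b)


class TestRepairSequence:
    def test_long_homopolymer_and_length_are_fixed(self, cs30):
        """32 nt with a run of 5 against a length-30 code: the repaired
        output has the target length and no run above the bound."""
        result = repair_sequence(FIG2_SEQ, cs30)
        assert result.success
        assert len(result.repaired) == 30
        assert max_homopolymer_run(result.repaired) <= 3
        assert find_violations(result.repaired, cs30) == []
        assert replay(FIG2_SEQ, result.edits) == result.repaired

    def test_run_between_gc_windows_repaired_with_g(self, cs30):
        """A C-run straddling two GC windows at the lower GC bound can only
        be broken by a G substitution; A/T would empty the window."""
        result = repair_sequence(FIG3_SEQ, cs30)
        assert result.success
        (edit,) = result.edits
        assert edit.op == "substitution" and edit.to_base == "G"
        # brute force over the three candidate bases at the edited position
        valid_bases = [
            b for b in "AGT"
            if not find_violations(
                FIG3_SEQ[: edit.position] + b + FIG3_SEQ[edit.position + 1 :], cs30
            )
        ]
        assert valid_bases == ["G"]

    def test_valid_input_is_identity(self, cs30):
        seq = "CGTACATGCATGCATGCTACGTACGTACAT"
        result = repair_sequence(seq, cs30)
        assert result.success and result.edits == [] and result.repaired == seq

    def test_too_short_input_grows_to_target(self):
        cs = ConstraintSet(gc_min=0, gc_max=1, target_length=6)
        result = repair_sequence("ACGT", cs)
        assert result.success and len(result.repaired) == 6
        assert result.repaired.startswith("ACGT")

    def test_n_bases_are_replaced(self):
        cs = ConstraintSet(gc_min=0, gc_max=1)
        result = repair_sequence("ACNTG", cs)
        assert result.success
        assert "N" not in result.repaired and len(result.repaired) == 5

    def test_budget_exhaustion_is_nonerror_failure(self, cs30):
        result = repair_sequence(FIG2_SEQ, cs30, max_changes=1)
        assert not result.success
        assert result.n_changes <= 1

    def test_zero_budget_on_violating_input_fails(self, cs30):
        result = repair_sequence(FIG2_SEQ, cs30, max_changes=0)
        assert not result.success and result.repaired == FIG2_SEQ

    def test_deterministic(self, cs30, rng):
        for _ in range(20):
            seq = random_seq(rng, 32)
            r1 = repair_sequence(seq, cs30)
            r2 = repair_sequence(seq, cs30)
            assert r1.edits == r2.edits and r1.repaired == r2.repaired

    def test_idempotent_on_success(self, cs30, rng):
        for _ in range(30):
            seq = random_seq(rng, rng.randint(28, 33))
            result = repair_sequence(seq, cs30)
            if result.success:
                again = repair_sequence(result.repaired, cs30)
                assert again.edits == [] and again.repaired == result.repaired

    def test_soundness_and_replay_on_random_inputs(self, rng):
        cs = ConstraintSet(max_homopolymer=3, target_length=30, blacklist=["GGTACC"])
        n_success = 0
        for _ in range(200):
            seq = random_seq(rng, rng.randint(25, 35))
            result = repair_sequence(seq, cs, max_changes=8)
            assert result.n_changes <= 8
            if result.success:
                n_success += 1
                assert find_violations(result.repaired, cs) == []
                assert replay(seq, result.edits) == result.repaired
        assert n_success > 0  # the suite exercises the success path

    def test_greedy_success_confirmed_by_enumeration(self, rng):
        """One-sided check: when the greedy loop fixes a short sequence in k
        edits, exhaustive enumeration finds a valid sequence within k edits."""
        cs = ConstraintSet(max_homopolymer=2, target_length=10)
        is_valid = lambda s: not find_violations(s, cs)
        for _ in range(60):
            seq = random_seq(rng, rng.randint(9, 11))
            result = repair_sequence(seq, cs, max_changes=2)
            if result.success and result.n_changes:
                assert valid_within_k_edits(seq, is_valid, result.n_changes) is not None


def _rec(id, bases, abundance=1):
    return SequenceRecord(id, bases, abundance=abundance)


class TestRepairCluster:
    VALID = "CGTACATGCATGCATGCTACGTACGTACAT"

    def test_valid_centroid_is_correct(self, cs30):
        cluster = Cluster(centroid=_rec("c", self.VALID))
        done = repair_cluster(cluster, cs30)
        assert done.status == "correct"
        assert done.chosen.bases == self.VALID and "correct" in done.chosen.tags

    def test_valid_member_substitutes_violating_centroid(self, cs30):
        centroid = _rec("c", FIG2_SEQ, abundance=5)
        member = _rec("m", self.VALID)
        done = repair_cluster(Cluster(centroid=centroid, members=[centroid, member]), cs30)
        assert done.status == "substituted"
        assert done.chosen.bases == self.VALID and "substituted" in done.chosen.tags

    def test_exhaustive_mode_picks_minimum_changes(self, cs30):
        # FIG3 needs 1 edit, FIG2 needs 3; FIG2 is closer to itself as centroid
        centroid = _rec("c", FIG2_SEQ, abundance=9)
        other = _rec("m", FIG3_SEQ)
        done = repair_cluster(Cluster(centroid=centroid, members=[centroid, other]),
                              cs30, exhaustive=True)
        assert done.status == "repaired"
        assert done.chosen.tags & {"repaired:1"}
        assert len(done.edits) == 1

    def test_first_success_mode_stops_at_sort_order(self, cs30):
        centroid = _rec("c", FIG2_SEQ, abundance=9)
        other = _rec("m", FIG3_SEQ)
        done = repair_cluster(Cluster(centroid=centroid, members=[centroid, other]),
                              cs30, exhaustive=False)
        assert done.status == "repaired"
        # centroid itself repairs first (distance 0 in the sort order)
        assert done.chosen.tags & {"repaired:3"}

    def test_unrecoverable_cluster(self):
        cs = ConstraintSet(max_homopolymer=1, target_length=4)
        cluster = Cluster(centroid=_rec("c", "AAAA"))
        done = repair_cluster(cluster, cs, max_changes=0)
        assert done.status == "unrecoverable" and done.chosen is None

    def test_empty_cluster_is_error(self, cs30):
        with pytest.raises(ValueError):
            repair_cluster(Cluster(centroid=None, members=[]), cs30)

    def test_member_sort_keys(self):
        centroid = _rec("c", "ACGTACGT")
        near = _rec("x", "ACGTACGA")          # distance 1
        far = _rec("a", "ACGTTTTT")           # distance 3+
        heavy = _rec("b", "ACGTACGA", abundance=4)  # distance 1, higher abundance
        ordered = sort_members([far, near, heavy, centroid], centroid)
        assert [m.id for m in ordered] == ["c", "b", "x", "a"]


class TestKeepOriginal:
    def _repaired_cluster(self, cs30):
        cluster = Cluster(centroid=_rec("c", FIG2_SEQ))
        return repair_cluster(cluster, cs30)

    def test_flag_emits_original_and_repaired(self, cs30):
        done = self._repaired_cluster(cs30)
        records = list(keep_original_option(done, True))
        assert len(records) == 2
        assert "original" in records[0].tags
        assert any(t.startswith("repaired:") for t in records[1].tags)

    def test_no_flag_emits_representative_only(self, cs30):
        done = self._repaired_cluster(cs30)
        records = list(keep_original_option(done, False))
        assert len(records) == 1

    def test_correct_cluster_never_duplicated(self, cs30):
        cluster = Cluster(centroid=_rec("c", TestRepairCluster.VALID))
        done = repair_cluster(cluster, cs30)
        assert len(list(keep_original_option(done, True))) == 1


def test_report_entry_matches_schema_invariants(cs30):
    done = repair_cluster(Cluster(centroid=_rec("c", FIG2_SEQ)), cs30)
    entry = report_entry(done)
    assert entry["category"] == "repaired"
    assert entry["n_changes"] == len(entry["edits"]) == 3
    assert entry["original_centroid"] == FIG2_SEQ


def test_edit_apply_and_validation():
    assert Edit("substitution", 1, "C", "G").apply("ACG") == "AGG"
    assert Edit("deletion", 0, "A").apply("ACG") == "CG"
    assert Edit("insertion", 3, to_base="T").apply("ACG") == "ACGT"
    with pytest.raises(ValueError):
        Edit("swap", 0)
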