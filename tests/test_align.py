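"""Alignment engine and read-classification rules."""

import random

import pytest

from pearkit import (
    EditSpec,
    align_semi_global,
    anchor_identity,
    apply_edit,
    classify_read,
    classify_reads,
    detect_cutsite_indel,
)
from pearkit.simulate import ReadSimParams, simulate_reads

from oracle_align import (
    enumerate_alignments_signatures,
    gotoh_signatures,
    signature_of_ops,
)


class TestAligner:
    def test_substring_read_aligns_gapless(self):
        ref = "TTTTGGGGAACCTTGGACGTACGTAA"
        read = ref[8:16]
        aln = align_semi_global(read, ref)
        assert aln.score == len(read)
        assert [op.op for op in aln.ops] == ["match"]
        assert (aln.ref_start, aln.ref_end) == (8, 16)

    def test_single_insertion_called_once_leftmost(self):
        ref = "GATCCATGCATTGCCATACGTGCA"
        read = ref[:10] + "T" + ref[10:20]
        aln = align_semi_global(read, ref)
        ins = [op for op in aln.ops if op.op == "ins"]
        assert len(ins) == 1 and ins[0].length == 1
        assert not any(op.op == "del" for op in aln.ops)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            align_semi_global("", "ACGT")

    def test_gotoh_oracle_agrees_with_brute_force_enumeration(self):
        """The DP oracle itself is validated against true exhaustive
        enumeration of every alignment path on tiny instances."""
        rnd = random.Random(7)
        for _ in range(40):
            read = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(1, 5)))
            ref = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(1, 7)))
            assert enumerate_alignments_signatures(read, ref) == \
                gotoh_signatures(read, ref)

    def test_score_and_op_multiset_match_oracle(self):
        rnd = random.Random(42)
        for _ in range(60):
            L = rnd.randint(5, 25)
            read = "".join(rnd.choice("ACGT") for _ in range(L))
            ref = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(L, 25)))
            best, sigs = gotoh_signatures(read, ref)
            aln = align_semi_global(read, ref)
            assert aln.score == best
            assert signature_of_ops(aln.ops) in sigs

    def test_ops_reconstruct_read(self):
        ref = "GATCCATGCATTGCCATACGTGCA"
        read = ref[:8] + ref[11:20] + "G"
        aln = align_semi_global(read, ref)
        consumed = sum(op.length for op in aln.ops if op.op != "del")
        assert consumed == len(read)


class TestCutsiteIndel:
    REF = ("GATCATGGTCTCGGAAAGGTGATTGGAACCATCGACAGTAGACAGCCCCC"
           "GTCAAAAAAGTTGGCTGGGTGTGGCTGCCC")
    CUT = 40

    def test_insertion_at_cut_called_distance_zero(self):
        # insert a base differing from both neighbours so the call cannot
        # left-shift away from the nick
        base = next(
            b for b in "ACGT"
            if b not in (self.REF[self.CUT - 1], self.REF[self.CUT])
        )
        read = self.REF[: self.CUT] + base + self.REF[self.CUT :]
        call = detect_cutsite_indel(align_semi_global(read, self.REF), self.CUT)
        assert call is not None and call.kind == "ins"
        assert call.distance_to_cut == 0

    def test_deletion_outside_window_not_called(self):
        start = self.CUT + 5
        read = self.REF[:start] + self.REF[start + 3 :]
        aln = align_semi_global(read, self.REF)
        assert detect_cutsite_indel(aln, self.CUT) is None

    def test_long_deletion_boundary_inclusive_at_two(self):
        # 10-nt deletion whose 5' boundary sits exactly 2 nt 3' of the nick
        start = self.CUT + 2
        read = self.REF[:start] + self.REF[start + 10 :]
        aln = align_semi_global(read, self.REF)
        call = detect_cutsite_indel(aln, self.CUT)
        assert call is not None and call.kind == "del" and call.length == 10
        assert call.distance_to_cut == 2

    def test_any_length_accepted_inside_window(self):
        read = self.REF[: self.CUT - 1] + self.REF[self.CUT + 14 :]
        aln = align_semi_global(read, self.REF)
        call = detect_cutsite_indel(aln, self.CUT)
        assert call is not None and call.length == 15


class TestClassifyRead:
    def test_reference_read_is_unedited(self, sub_amplicon):
        cls = classify_read(sub_amplicon.ref_seq, sub_amplicon)
        assert cls.label == "unedited"

    def test_edited_read_is_intended(self, sub_amplicon):
        cls = classify_read(sub_amplicon.edited_seq, sub_amplicon)
        assert cls.label == "intended"

    @pytest.mark.parametrize("n_bad,expected", [(5, "unedited"), (6, "filtered")])
    def test_anchor_threshold_15_of_20(self, sub_amplicon, n_bad, expected):
        """15/20 anchor matches pass the 75% rule; 14/20 fail."""
        seq = list(sub_amplicon.ref_seq)
        swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
        for k in range(n_bad):
            pos = 2 * k  # positions 0,2,...
            seq[pos] = swap[seq[pos]]
        cls = classify_read("".join(seq), sub_amplicon)
        assert cls.label == expected

    def test_intended_substitution_with_cut_indel_is_byproduct(self, sub_amplicon):
        # alt allele present but a 1-nt deletion at the nick: not "intended"
        cut = sub_amplicon.cut_site
        seq = sub_amplicon.edited_seq
        read = seq[: cut - 1] + seq[cut:]
        cls = classify_read(read, sub_amplicon)
        assert cls.label == "indel_byproduct"

    def test_intended_indel_edit_detected(self, ins_amplicon, del_amplicon):
        for amp in (ins_amplicon, del_amplicon):
            assert classify_read(amp.edited_seq, amp).label == "intended"
            assert classify_read(amp.ref_seq, amp).label == "unedited"

    def test_byproduct_indel_different_from_intended(self, ins_amplicon):
        # deletion at the nick while the programmed edit is an insertion
        cut = ins_amplicon.cut_site
        read = ins_amplicon.ref_seq[: cut - 2] + ins_amplicon.ref_seq[cut:]
        cls = classify_read(read, ins_amplicon)
        assert cls.label == "indel_byproduct"
        assert cls.indel.kind == "del"

    def test_invariant_to_trailing_reference_extension(self, sub_amplicon):
        read = sub_amplicon.edited_seq[:150]
        cls1 = classify_read(read, sub_amplicon)
        import dataclasses
        longer = dataclasses.replace(
            sub_amplicon,
            ref_seq=sub_amplicon.ref_seq + "ACGTACGTAAAA",
            edited_seq="",
        )
        cls2 = classify_read(read, longer)
        assert cls1.label == cls2.label == "intended"

    def test_short_read_filtered_separately(self, sub_amplicon):
        cls = classify_read(sub_amplicon.ref_seq[:12], sub_amplicon)
        assert cls.label == "filtered" and cls.filter_reason == "short"

    def test_labels_partition_read_set(self, sub_amplicon):
        params = ReadSimParams(
            amplicon=sub_amplicon, n_reads=300, frac_intended=0.4,
            per_base_error=0.02, read_len=120, seed=5,
        )
        records, _ = simulate_reads(params)
        classes = classify_reads([seq for _, seq, _ in records], sub_amplicon)
        labels = {"filtered", "intended", "indel_byproduct", "unedited"}
        assert all(c.label in labels for c in classes)
        assert len(classes) == 300

    def test_error_free_reads_recover_truth_exactly(self, sub_amplicon):
        cut = sub_amplicon.cut_site
        byproduct = EditSpec(
            "deletion", cut - 1, sub_amplicon.ref_seq[cut - 1], ""
        )
        params = ReadSimParams(
            amplicon=sub_amplicon, n_reads=400, frac_intended=0.3,
            byproduct_indels=[(byproduct, 0.1)], per_base_error=0.0,
            read_len=180, seed=6,
        )
        records, truth = simulate_reads(params)
        classes = classify_reads([seq for _, seq, _ in records], sub_amplicon)
        expected = {
            "intended": "intended",
            "byproduct_0": "indel_byproduct",
            "unedited": "unedited",
        }
        for cls, cat in zip(classes, truth["category"]):
            assert cls.label == expected[cat]


def test_anchor_identity_counts_gaps_as_mismatches(sub_amplicon):
    ref = sub_amplicon.ref_seq
    read = ref[:10] + ref[12:100]  # 2-nt deletion inside the anchor
    aln = align_semi_global(read, ref)
    assert anchor_identity(aln) == pytest.approx(18 / 20)
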