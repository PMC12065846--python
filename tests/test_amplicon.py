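import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtdsbr.amplicon import (
    AlignmentScoring,
    AmpliconError,
    AmpliconSpec,
    Assigned,
    ReadLabel,
    assign_read,
    classify_editing_read,
    classify_intron_loss_read,
    global_align,
    quantify_intron_loss,
    quantify_signature_fraction,
)
from tests.conftest import brute_force_align_score

SCORING = AlignmentScoring()
dna = st.text(alphabet="ACGT", min_size=1, max_size=6)


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = global_align("ACGTACGT", "ACGTACGT")
        assert aln.score == 16.0
        assert aln.gap_ops() == []

    def test_single_deletion_at_coordinate_two(self):
        aln = global_align("ACT", "ACGT")
        (gap,) = aln.gap_ops()
        assert gap.kind == "delete" and gap.target_pos == 2 and gap.length == 1

    def test_insertion_anchor_coordinate(self):
        aln = global_align("ACGAT", "ACAT")  # extra G between AC and AT
        (gap,) = aln.gap_ops()
        assert gap.kind == "insert" and gap.target_pos == 2 and gap.seq == "G"

    def test_gapless_reconstruction_invariant(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            q = "".join(np.array(list("ACGT"))[rng.integers(0, 4, rng.integers(1, 30))])
            t = "".join(np.array(list("ACGT"))[rng.integers(0, 4, rng.integers(1, 30))])
            aln = global_align(q, t)
            assert aln.aligned_query.replace("-", "") == q
            assert aln.aligned_target.replace("-", "") == t
            # operations tile the target exactly
            consumed = sum(op.length for op in aln.ops if op.kind != "insert")
            assert consumed == len(t)

    def test_empty_sequence_rejected(self):
        with pytest.raises(AmpliconError):
            global_align("", "ACGT")

    @given(dna, dna)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_enumeration(self, q, t):
        assert global_align(q, t, SCORING).score == pytest.approx(
            brute_force_align_score(q, t, SCORING)
        )

    def test_matches_brute_force_on_8mers(self):
        rng = np.random.default_rng(19)
        for _ in range(8):
            q = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 8)])
            t = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 8)])
            assert global_align(q, t, SCORING).score == pytest.approx(
                brute_force_align_score(q, t, SCORING)
            )


class TestAssignment:
    def test_exact_reads_assign_to_their_amplicon(self, intron_loss_spec):
        spec = intron_loss_spec
        assert assign_read(spec.alt_seq, spec)[0] is Assigned.ALT
        assert assign_read(spec.reference_seq, spec)[0] is Assigned.REFERENCE

    def test_substituted_alt_read_still_alt(self, intron_loss_spec):
        spec = intron_loss_spec
        read = list(spec.alt_seq)
        read[10] = next(b for b in "ACGT" if b != read[10])
        assert assign_read("".join(read), spec)[0] is Assigned.ALT


class TestIntronLossClassification:
    def test_perfect_loss(self, intron_loss_spec):
        c = classify_intron_loss_read("r", intron_loss_spec.alt_seq, intron_loss_spec)
        assert c.label is ReadLabel.PERFECT_LOSS and c.window_indels == 0

    def test_deletion_near_junction_demotes(self, intron_loss_spec):
        spec = intron_loss_spec
        p = spec.junction_pos - 2
        read = spec.alt_seq[:p] + spec.alt_seq[p + 1 :]
        c = classify_intron_loss_read("r", read, spec)
        assert c.label is ReadLabel.IMPERFECT_LOSS

    def test_indel_far_from_junction_is_still_perfect(self, intron_loss_spec):
        spec = intron_loss_spec
        p = spec.junction_pos + 10
        read = spec.alt_seq[:p] + "A" + spec.alt_seq[p:]  # 1-bp insertion outside window
        c = classify_intron_loss_read("r", read, spec)
        assert c.label is ReadLabel.PERFECT_LOSS

    def test_substitution_inside_window_does_not_demote(self, intron_loss_spec):
        spec = intron_loss_spec
        j = spec.junction_pos
        read = list(spec.alt_seq)
        read[j] = next(b for b in "ACGT" if b != read[j])
        c = classify_intron_loss_read("r", "".join(read), spec)
        assert c.label is ReadLabel.PERFECT_LOSS

    def test_junction_window_boundary_sweep(self, intron_loss_spec):
        """A 1-bp deletion demotes exactly within 3 bp of the junction."""
        spec = intron_loss_spec
        j = spec.junction_pos
        demoted = []
        for off in range(-8, 8):
            p = j + off
            read = spec.alt_seq[:p] + spec.alt_seq[p + 1 :]
            c = classify_intron_loss_read("r", read, spec)
            if c.label is ReadLabel.IMPERFECT_LOSS:
                demoted.append(off)
        assert demoted == list(range(-3, 3))  # half-open window [j-3, j+3)
        assert max(abs(o) for o in demoted) == 3

    def test_shrinking_window_only_promotes(self, intron_loss_spec):
        spec = intron_loss_spec
        j = spec.junction_pos
        reads = []
        for off in range(-6, 6):
            p = j + off
            reads.append(spec.alt_seq[:p] + spec.alt_seq[p + 1 :])
        labels = {}
        for hw in (0, 1, 2, 3, 4):
            s = AmpliconSpec(
                reference_seq=spec.reference_seq, alt_seq=spec.alt_seq,
                junction_pos=j, junction_halfwidth=hw,
            )
            labels[hw] = [classify_intron_loss_read("r", r, s).label for r in reads]
        for hw in (0, 1, 2, 3):
            for small, large in zip(labels[hw], labels[hw + 1]):
                # demotion at the smaller window implies demotion at the larger
                assert small is not ReadLabel.IMPERFECT_LOSS or large is ReadLabel.IMPERFECT_LOSS


class TestEditingClassification:
    def test_unmodified(self, editing_spec):
        c = classify_editing_read("r", editing_spec.reference_seq, editing_spec)
        assert c.label is ReadLabel.UNMODIFIED

    def test_signature_insertion_at_cut(self, editing_spec):
        spec = editing_spec
        read = spec.reference_seq[: spec.cut_pos] + spec.signature_seq + spec.reference_seq[spec.cut_pos :]
        assert classify_editing_read("r", read, spec).label is ReadLabel.SIGNATURE

    def test_non_signature_insertion_is_indel(self, editing_spec):
        spec = editing_spec
        other = "ATG" if spec.signature_seq != "ATG" else "GAT"
        read = spec.reference_seq[: spec.cut_pos] + other + spec.reference_seq[spec.cut_pos :]
        assert classify_editing_read("r", read, spec).label is ReadLabel.INDEL

    def test_deletion_outside_window_unmodified(self, editing_spec):
        spec = editing_spec
        p = spec.cut_pos + 30
        read = spec.reference_seq[:p] + spec.reference_seq[p + 2 :]
        assert classify_editing_read("r", read, spec).label is ReadLabel.UNMODIFIED

    def test_cut_window_spans_25_positions(self, editing_spec):
        """Sliding a 1-bp deletion across the amplicon marks exactly the
        25 bp centered on the cut site as modified."""
        spec = editing_spec
        modified = []
        for p in range(len(spec.reference_seq)):
            read = spec.reference_seq[:p] + spec.reference_seq[p + 1 :]
            c = classify_editing_read("r", read, spec)
            if c.label is not ReadLabel.UNMODIFIED:
                modified.append(p)
        assert modified == list(range(spec.cut_pos - 12, spec.cut_pos + 13))
        assert len(modified) == 25


class TestQuantification:
    def test_all_reference_reads_zero_percent(self, intron_loss_spec):
        reads = [(f"r{i}", intron_loss_spec.reference_seq) for i in range(5)]
        report, _ = quantify_intron_loss(reads, intron_loss_spec)
        assert report.percent_intron_loss == 0.0

    def test_formula_10_5_5_gives_25_percent(self, intron_loss_spec):
        spec = intron_loss_spec
        j = spec.junction_pos
        imperfect = spec.alt_seq[: j - 1] + spec.alt_seq[j:]
        reads = (
            [(f"a{i}", spec.reference_seq) for i in range(10)]
            + [(f"b{i}", spec.alt_seq) for i in range(5)]
            + [(f"c{i}", imperfect) for i in range(5)]
        )
        report, cls = quantify_intron_loss(reads, spec)
        assert report.percent_intron_loss == pytest.approx(25.0)
        assert sum(report.counts.values()) == report.total == 20  # partition

    def test_single_perfect_read_100_percent(self, intron_loss_spec):
        report, _ = quantify_intron_loss([("r", intron_loss_spec.alt_seq)], intron_loss_spec)
        assert report.percent_intron_loss == pytest.approx(100.0)

    def test_signature_fractions_60_30_10(self, editing_spec):
        spec = editing_spec
        cut = spec.cut_pos
        sig = spec.reference_seq[:cut] + spec.signature_seq + spec.reference_seq[cut:]
        indel = spec.reference_seq[:cut] + spec.reference_seq[cut + 2 :]
        reads = (
            [(f"u{i}", spec.reference_seq) for i in range(60)]
            + [(f"i{i}", indel) for i in range(30)]
            + [(f"s{i}", sig) for i in range(10)]
        )
        report, _ = quantify_signature_fraction(reads, spec)
        assert report.signature_fraction_of_indels == pytest.approx(0.25)
        assert report.signature_fraction_of_total == pytest.approx(0.10)

    def test_no_indel_reads_fraction_undefined(self, editing_spec):
        reads = [(f"r{i}", editing_spec.reference_seq) for i in range(4)]
        report, _ = quantify_signature_fraction(reads, editing_spec)
        assert report.signature_fraction_of_indels is None
        assert report.signature_fraction_of_total == 0.0

    def test_all_signature_reads_both_fractions_one(self, editing_spec):
        spec = editing_spec
        cut = spec.cut_pos
        sig = spec.reference_seq[:cut] + spec.signature_seq + spec.reference_seq[cut:]
        report, _ = quantify_signature_fraction([("r", sig), ("q", sig)], spec)
        assert report.signature_fraction_of_indels == 1.0
        assert report.signature_fraction_of_total == 1.0

    def test_zero_reads_rejected(self, intron_loss_spec):
        with pytest.raises(AmpliconError):
            quantify_intron_loss([], intron_loss_spec)
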