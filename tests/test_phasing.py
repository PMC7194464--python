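import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from phasilens.mirna import SrnaAlignment, map_reads
from phasilens.phasing import (
    PhaseStats,
    assign_registers,
    call_phas,
    phase_score,
    render_alignment,
)
from phasilens.preprocess import CollapsedRead


def _aln(start1, length=21, strand="+", count=1, seqid="tx", seq=None):
    seq = seq or "".join(random.Random(start1 * 7 + length).choice("ACGT")
                         for _ in range(length))
    return SrnaAlignment(CollapsedRead(seq, count), seqid, start1 - 1, strand, 0)


class TestAssignRegisters:
    def test_plus_read_at_anchor_is_d1(self):
        (call,) = assign_registers([_aln(562)], s=562)
        assert call.in_phase
        assert call.register == 0
        assert call.d_label == "D1(+)"

    def test_minus_read_ending_at_anchor_plus_18_is_in_phase(self):
        # duplex 2-nt overhang rule: end = s + 18 => 18 == 21 - 3 (mod 21)
        a = _aln(562 - 2, strand="-")  # spans 560..580, end = 580 = 562+18
        (call,) = assign_registers([a], s=562)
        assert a.end == 562 + 18
        assert call.in_phase
        assert call.register == 0
        assert call.d_label == "D1(-)"

    def test_plus_read_off_register_out_of_phase(self):
        (call,) = assign_registers([_aln(563)], s=562)
        assert not call.in_phase

    def test_cycle_k_registers(self):
        for k in range(5):
            (call,) = assign_registers([_aln(100 + 21 * k)], s=100)
            assert call.in_phase and call.register == k
            (mcall,) = assign_registers(
                [_aln(100 + 21 * k - 2, strand="-")], s=100
            )
            assert mcall.in_phase and mcall.register == k

    @given(shift=st.integers(-1000, 1000), start=st.integers(1200, 1400),
           strand=st.sampled_from("+-"))
    @settings(max_examples=80, deadline=None)
    def test_translation_equivariance(self, shift, start, strand):
        s = 1250
        a = _aln(start, strand=strand)
        b = _aln(start + shift, strand=strand) if start + shift >= 1 else None
        (ca,) = assign_registers([a], s=s)
        if b is not None:
            (cb,) = assign_registers([b], s=s + shift)
            assert ca.in_phase == cb.in_phase


class TestPhaseScore:
    def test_formula_value(self):
        # k=3 occupied cycles, P=10, U=0 => ln(101)
        alns = [
            _aln(100, count=4),
            _aln(121, count=3),
            _aln(142, count=3),
        ]
        stats = phase_score(alns, s=100)
        assert stats.k == 3 and stats.P == 10 and stats.U == 0
        assert stats.score == pytest.approx(math.log(101), rel=1e-12)

    def test_k_below_minimum_scores_zero(self):
        alns = [_aln(100, count=50), _aln(121, count=50)]
        stats = phase_score(alns, s=100)
        assert stats.k == 2
        assert stats.score == 0.0

    def test_size_filter_excludes_other_lengths(self):
        alns = [_aln(100, length=24, count=50)]
        stats = phase_score(alns, s=100)
        assert stats.P == 0 and stats.U == 0

    def test_matches_formula_oracle_on_random_windows(self):
        rng = random.Random(23)
        for _ in range(100):
            s = 50
            alns = []
            for _ in range(rng.randrange(1, 25)):
                start = rng.randrange(s, s + 210 - 21)
                strand = rng.choice("+-")
                length = rng.randrange(20, 23)
                count = rng.randrange(1, 10)
                if strand == "-":
                    start1 = start - length + 1
                    if start1 < 1:
                        continue
                    alns.append(_aln(start1, length=length, strand="-", count=count))
                else:
                    alns.append(_aln(start, length=length, count=count))
            stats = phase_score(alns, s=s)
            # independent tally from the register definitions
            P = U = 0.0
            cycles = set()
            for a in alns:
                five = a.start + 1 if a.strand == "+" else a.end
                if not (s <= five < s + 210):
                    continue
                if a.strand == "+":
                    in_phase = (a.start + 1 - s) % 21 == 0
                    reg = (a.start + 1 - s) // 21
                else:
                    in_phase = (a.end - s) % 21 == 18
                    reg = (a.end - s - 18) // 21
                if in_phase and 0 <= reg < 10:
                    P += a.read.count
                    cycles.add(reg)
                else:
                    U += a.read.count
            assert stats.P == P and stats.U == U and stats.k == len(cycles)
            assert stats.score == pytest.approx(
                oracles.phase_score_formula(P, U, len(cycles)), rel=1e-9
            )

    def test_monotone_in_P_and_U(self):
        base = [_aln(100, count=5), _aln(121, count=5), _aln(142, count=5)]
        s0 = phase_score(base, s=100).score
        more_p = base + [_aln(163, count=5)]
        assert phase_score(more_p, s=100).score >= s0
        more_u = base + [_aln(105, count=5)]
        assert phase_score(more_u, s=100).score <= s0

    def test_anchor_shift_by_period_equal_scores(self):
        # reads confined to cycles 1..8 relative to the earlier anchor
        alns = [_aln(100 + 21 * k, count=3) for k in range(1, 9)]
        a = phase_score(alns, s=100, window_cycles=20)
        b = phase_score(alns, s=121, window_cycles=20)
        assert a.P == b.P and a.U == b.U
        assert a.k == b.k + 1 or a.k == b.k  # registers shift down by one


class TestCallPhas:
    def test_clean_fixture_truth_anchor_is_best(self, clean_truth, clean_records):
        tx = {"TARGET_T1": clean_truth.transcript}
        alns = map_reads(clean_records, tx, max_mismatch=1)
        anchors = [clean_truth.slice_position + d for d in range(-10, 11)]
        anchors = [a for a in anchors if a >= 1]
        reports = call_phas("TARGET_T1", alns, anchors)
        assert reports[0].anchor == clean_truth.slice_position
        assert reports[0].best and reports[0].passed
        truth_score = reports[0].score
        for rep in reports[1:]:
            assert rep.score < truth_score

    def test_all_generated_phased_reads_in_phase(self, clean_truth, clean_reads):
        from phasilens.preprocess import collapse_reads

        phased = [r for r in clean_reads if r.label.startswith("phased")]
        tx = {"TARGET_T1": clean_truth.transcript}
        alns = map_reads(
            collapse_reads([r.sequence for r in phased]), tx, max_mismatch=0
        )
        calls = assign_registers(alns, s=clean_truth.slice_position)
        by_seq = {}
        for c in calls:
            by_seq.setdefault(c.alignment.read.sequence, []).append(c)
        for r in phased:
            assert any(c.in_phase for c in by_seq[r.sequence])

    def test_uniform_random_reads_score_below_threshold(self):
        rng = random.Random(31)
        for seed in range(3):
            alns = []
            for _ in range(60):
                start1 = rng.randrange(1, 400)
                alns.append(_aln(start1, count=1, length=21))
            reports = call_phas("tx", alns, anchors=list(range(50, 80)),
                                score_min=4.0)
            assert not any(r.passed for r in reports)

    def test_no_anchors_empty(self):
        assert call_phas("tx", [], []) == []

    def test_render_alignment_smoke(self, clean_truth, clean_records):
        tx = {"TARGET_T1": clean_truth.transcript}
        alns = map_reads(clean_records, tx, max_mismatch=1)
        reports = call_phas("TARGET_T1", alns, [clean_truth.slice_position])
        text = render_alignment(clean_truth.transcript, reports[0])
        assert "D1(+)" in text
        assert f"anchor={clean_truth.slice_position}" in text
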