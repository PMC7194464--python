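import random

import numpy as np
import pytest
from scipy import stats as sps

from phasilens import synth
from phasilens.errors import UnanchoredReadError
from phasilens.preprocess import CollapsedRead, collapse_reads
from phasilens.tails import (
    Anchor,
    classify_tail,
    find_anchor,
    run_tails,
    tail_fraction_report,
)


def _genome(seed=13, n=600):
    rng = random.Random(seed)
    return {"c": "".join(rng.choice("ACGT") for _ in range(n))}


class TestClassifyTail:
    def test_fully_templated(self):
        g = _genome()
        seq = g["c"][100:122]
        if seq.endswith("T"):  # avoid the ambiguous case here
            seq = seq[:-1] + {"T": "A"}[seq[-1]]
            g = {"c": g["c"][:121] + seq[-1] + g["c"][122:]}
        call = classify_tail(CollapsedRead(seq), g, Anchor("c", 100, "+"))
        assert call.klass == "templated"
        assert call.tail == ""
        assert call.templated_prefix_len == 22

    def test_mono_u_over_non_t_genomic_base(self):
        g = {"c": "A" * 50 + "CGCGCGCGCGCGCGCGCGCGC" + "A" * 50}
        read = CollapsedRead(g["c"][50:71] + "T")  # genome has A next
        call = classify_tail(read, g, Anchor("c", 50, "+"))
        assert call.klass == "mono_U"
        assert call.tail == "T"
        assert call.templated_prefix_len == 21

    def test_terminal_t_matching_genome_is_ambiguous(self):
        g = {"c": "A" * 50 + "CGCGCGCGCGCGCGCGCGCGT" + "A" * 50}
        read = CollapsedRead(g["c"][50:71])  # ends in templated T
        call = classify_tail(read, g, Anchor("c", 50, "+"))
        assert call.klass == "ambiguous"
        assert call.tail == "T"
        assert call.templated_prefix_len == 20

    def test_longer_tail_is_other_tail(self):
        g = {"c": "A" * 50 + "CGCGCGCGCGCGCGCGCGCGC" + "A" * 50}
        read = CollapsedRead(g["c"][50:71] + "TT")
        call = classify_tail(read, g, Anchor("c", 50, "+"))
        assert call.klass == "other_tail"
        assert call.tail == "TT"

    def test_invariant_prefix_plus_tail(self):
        g = _genome(21)
        rng = random.Random(99)
        for _ in range(50):
            start = rng.randrange(0, 550)
            core = g["c"][start : start + 21]
            tail = "".join(rng.choice("ACGT") for _ in range(rng.randrange(0, 3)))
            read = CollapsedRead(core + tail)
            try:
                call = classify_tail(read, g, Anchor("c", start, "+"))
            except UnanchoredReadError:
                continue
            assert call.templated_prefix_len + len(call.tail) == len(read.sequence)
            assert call.klass in ("templated", "mono_U", "other_tail", "ambiguous")

    def test_short_prefix_raises(self):
        g = {"c": "A" * 100}
        read = CollapsedRead("A" * 10 + "C" * 11)
        with pytest.raises(UnanchoredReadError):
            classify_tail(read, g, Anchor("c", 0, "+"))

    def test_minus_strand_anchor(self):
        from phasilens.ioutils import revcomp

        g = _genome(33)
        seg = g["c"][200:221]
        read = CollapsedRead(revcomp(seg) + "T")
        anchor = find_anchor(read.sequence, g)
        assert anchor is not None and anchor.strand == "-"
        call = classify_tail(read, g, anchor)
        assert call.klass in ("mono_U", "ambiguous")
        assert call.genome_span[0] <= 200 < call.genome_span[1]


class TestFindAnchor:
    def test_prefers_longest_prefix(self):
        g = {"c": "A" * 30 + "CATGCATGCATGCATGCATGC" + "A" * 30}
        read = CollapsedRead(g["c"][30:51] + "T")
        anchor = find_anchor(read.sequence, g)
        assert anchor == Anchor("c", 30, "+")

    def test_returns_none_for_foreign_read(self):
        g = {"c": "A" * 200}
        assert find_anchor("CGCGCGCGCGCGCGCGCGCG", g) is None


class TestFractionReport:
    def test_arithmetic(self):
        g = {"c": "A" * 50 + "CGCGCGCGCGCGCGCGCGCGC" + "A" * 50}
        core = g["c"][50:71]
        calls = [
            classify_tail(CollapsedRead(core + "T", count=93), g, Anchor("c", 50, "+")),
            classify_tail(CollapsedRead(core + "A", count=7), g, Anchor("c", 50, "+")),
        ]
        report = tail_fraction_report(calls)
        row = report[report["length"] == 22].iloc[0]
        assert row["frac_mono_U"] == pytest.approx(0.93)
        assert row["frac_templated"] == pytest.approx(0.07)

    def test_empty_class_is_nan_not_zero(self):
        report = tail_fraction_report([])
        assert len(report) == 0
        g = {"c": "A" * 50 + "CGCGCGCGCGCGCGCGCGCGC" + "A" * 50}
        core = g["c"][50:71]
        calls = [classify_tail(CollapsedRead(core), g, Anchor("c", 50, "+"))]
        report = tail_fraction_report(calls)
        assert 22 not in set(report["length"])

    def test_fractions_sum_to_one_excluding_ambiguous(self):
        rng = random.Random(3)
        g = _genome(55)
        calls = []
        for _ in range(60):
            start = rng.randrange(0, 550)
            core = g["c"][start : start + rng.randrange(19, 23)]
            tail = rng.choice(["", "T", "TT", "A"])
            try:
                calls.append(
                    classify_tail(
                        CollapsedRead(core + tail, count=rng.randrange(1, 9)),
                        g,
                        Anchor("c", start, "+"),
                    )
                )
            except UnanchoredReadError:
                pass
        report = tail_fraction_report(calls)
        for _, row in report.iterrows():
            fr = row[["frac_templated", "frac_mono_U", "frac_other_tail"]]
            if not fr.isna().any():
                assert float(fr.sum()) == pytest.approx(1.0)

    def test_matches_weighted_tally_oracle(self):
        rng = random.Random(4)
        g = _genome(56)
        calls = []
        tally = {}
        for _ in range(80):
            start = rng.randrange(0, 550)
            core = g["c"][start : start + 21]
            tail = rng.choice(["", "T", "AC"])
            count = rng.randrange(1, 10)
            try:
                call = classify_tail(CollapsedRead(core + tail, count=count), g,
                                     Anchor("c", start, "+"))
            except UnanchoredReadError:
                continue
            calls.append(call)
            key = (len(call.read.sequence), call.klass)
            tally[key] = tally.get(key, 0) + count
        report = tail_fraction_report(calls)
        for _, row in report.iterrows():
            ln = row["length"]
            classifiable = sum(
                v for (l, k), v in tally.items()
                if l == ln and k != "ambiguous"
            )
            if classifiable:
                assert row["frac_mono_U"] == pytest.approx(
                    tally.get((ln, "mono_U"), 0) / classifiable
                )


class TestGeneratorRecovery:
    def test_binomial_interval_on_generated_22mers(self):
        """Estimated mono-U fraction of 1000 22-nt reads stays inside the
        exact binomial 99% interval around theta across seeds."""
        theta = 0.93
        cfg = synth.clean_config(depth=20000)
        for seed in (1, 2, 3):
            truth = synth.build_truth_set(cfg, seed=seed)
            reads = synth.simulate_srna_library(truth)
            records = collapse_reads([r.sequence for r in reads])
            calls, unanchored, report = run_tails(
                records, truth.genome, locus=(
                    truth.config.chrom, truth.hairpin[0], truth.hairpin[1]
                )
            )
            assert not unanchored
            row = report[report["length"] == 22].iloc[0]
            n22 = int(row["abundance"])
            assert n22 == 1000
            lo = sps.binom.ppf(0.005, n22, theta) / n22
            hi = sps.binom.ppf(0.995, n22, theta) / n22
            assert lo <= row["frac_mono_U"] <= hi

    def test_p_zero_yields_no_mono_u(self):
        cfg = synth.clean_config(p_mono_U=0.0)
        truth = synth.build_truth_set(cfg, seed=5)
        reads = synth.simulate_srna_library(truth)
        assert not any(r.label == "mirna_tailed" for r in reads)
        records = collapse_reads([r.sequence for r in reads])
        _, _, report = run_tails(records, truth.genome)
        if (report["length"] == 22).any():
            row = report[report["length"] == 22].iloc[0]
            assert row["frac_mono_U"] == 0.0
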