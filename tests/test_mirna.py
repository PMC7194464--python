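import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from phasilens.errors import ConfigError
from phasilens.ioutils import revcomp
from phasilens.mirna import (
    HairpinThresholds,
    annotate_mirna,
    cluster_by_coverage,
    evaluate_hairpin,
    fold_window,
    map_reads,
    pairing_to_dotbracket,
)
from phasilens.preprocess import CollapsedRead


def _random_genome(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestMapReads:
    def test_identity_alignment(self):
        rng = random.Random(1)
        genome = {"c": _random_genome(rng, 400)}
        read = CollapsedRead(genome["c"][100:121])
        hits = [a for a in map_reads([read], genome) if a.strand == "+"]
        assert any(a.start == 100 and a.mismatches == 0 for a in hits)

    def test_reverse_complement_alignment(self):
        rng = random.Random(2)
        genome = {"c": _random_genome(rng, 400)}
        read = CollapsedRead(revcomp(genome["c"][100:121]))
        hits = map_reads([read], genome)
        assert any(
            a.start == 100 and a.strand == "-" and a.mismatches == 0 for a in hits
        )

    def test_matches_brute_force_scan(self):
        rng = random.Random(3)
        genome = {"g1": _random_genome(rng, 1500), "g2": _random_genome(rng, 500)}
        reads = [
            CollapsedRead("".join(rng.choice("ACGT") for _ in range(21)))
            for _ in range(10)
        ]
        # plant exact and 1-mismatch copies
        planted = genome["g1"][700:721]
        reads.append(CollapsedRead(planted))
        mutated = planted[:10] + ("A" if planted[10] != "A" else "C") + planted[11:]
        reads.append(CollapsedRead(mutated))
        for mm in (0, 1):
            got = sorted(
                (a.seqid, a.start, a.strand, a.mismatches, a.read.sequence)
                for a in map_reads(reads, genome, max_mismatch=mm)
            )
            expected = sorted(
                (sid, pos, strand, m, r.sequence)
                for r in reads
                for sid, pos, strand, m in oracles.scan_alignments(
                    r.sequence, genome, mm
                )
            )
            assert got == expected

    def test_reads_with_n_are_skipped(self):
        genome = {"c": "ACGT" * 100}
        read = CollapsedRead("ACGTNACGTACGTACGTACGT")
        assert map_reads([read], genome) == []

    def test_empty_genome_rejected(self):
        with pytest.raises(ConfigError):
            map_reads([], {})


class TestClusterByCoverage:
    def test_twenty_stacked_reads_make_one_cluster(self):
        genome = {"c": "A" * 100}
        read = CollapsedRead("ACGTACGTACGTACGTACGTA", count=20)
        from phasilens.mirna import SrnaAlignment

        alns = [SrnaAlignment(read, "c", 40, "+", 0)]
        clusters = cluster_by_coverage(alns, 15, {"c": 100})
        assert clusters == [("c", 40, 61)]

    def test_below_threshold_no_cluster(self):
        from phasilens.mirna import SrnaAlignment

        read = CollapsedRead("ACGTACGTACGTACGTACGTA", count=10)
        alns = [SrnaAlignment(read, "c", 40, "+", 0)]
        assert cluster_by_coverage(alns, 15, {"c": 100}) == []

    def test_matches_coverage_array_oracle(self):
        from phasilens.mirna import SrnaAlignment

        rng = random.Random(7)
        length = 500
        alns = []
        intervals = []
        for i in range(60):
            start = rng.randrange(0, length - 25)
            rlen = rng.randrange(18, 26)
            count = rng.randrange(1, 30)
            seq = "".join(rng.choice("ACGT") for _ in range(rlen))
            alns.append(SrnaAlignment(CollapsedRead(seq, count), "c", start, "+", 0))
            intervals.append((start, start + rlen, float(count)))
        got = cluster_by_coverage(alns, 15, {"c": length})
        expected = [
            ("c", s, e) for s, e in oracles.coverage_clusters(intervals, length, 15)
        ]
        assert got == expected

    def test_order_invariance(self):
        from phasilens.mirna import SrnaAlignment

        rng = random.Random(8)
        alns = []
        for i in range(30):
            seq = "".join(rng.choice("ACGT") for _ in range(21))
            alns.append(
                SrnaAlignment(CollapsedRead(seq, rng.randrange(1, 20)), "c",
                              rng.randrange(0, 250), "+", 0)
            )
        a = cluster_by_coverage(alns, 10, {"c": 300})
        rng.shuffle(alns)
        b = cluster_by_coverage(alns, 10, {"c": 300})
        assert a == b


class TestFoldWindow:
    def test_simple_hairpin(self):
        pairs = fold_window("GGGAAACCC")
        assert len(pairs) == 3
        assert oracles.structure_is_valid("GGGAAACCC", pairs)

    def test_unpairable_sequence(self):
        assert fold_window("AAAAAA") == []

    def test_window_longer_than_foldsize_rejected(self):
        with pytest.raises(ConfigError):
            fold_window("A" * 50, foldsize=40)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle(self, seed):
        rng = random.Random(seed)
        for _ in range(5):
            n = rng.randrange(1, 13)
            seq = "".join(rng.choice("ACGU") for _ in range(n))
            pairs = fold_window(seq)
            assert oracles.structure_is_valid(seq, pairs)
            assert len(pairs) == oracles.max_pairs_brute(seq)

    def test_deterministic(self):
        seq = "GGCAUGCAUGCAUCGCAUGGCAUGC"
        assert fold_window(seq) == fold_window(seq)

    def test_dotbracket_rendering(self):
        pairs = fold_window("GGGAAACCC")
        db = pairing_to_dotbracket(9, pairs)
        assert db.count("(") == db.count(")") == 3


class TestEvaluateHairpin:
    def test_synthetic_hairpin_accepted(self, clean_truth, clean_records):
        cands, _ = annotate_mirna(clean_records, clean_truth.genome)
        accepted = [c for c in cands if c.accepted]
        assert len(accepted) == 1
        c = accepted[0]
        assert c.mature_seq == clean_truth.mature_seq
        assert c.star_seq == clean_truth.star_seq
        assert c.overhang_3p == 2
        assert c.mature_arm == clean_truth.mature_arm

    def test_star_removed_rejects_with_no_star(self, clean_truth, clean_reads):
        from phasilens.preprocess import collapse_reads

        seqs = [
            r.sequence for r in clean_reads if r.label != "mirna_star"
        ]
        cands, _ = annotate_mirna(collapse_reads(seqs), clean_truth.genome)
        hairpin_cands = [
            c for c in cands
            if c.window[0] < clean_truth.hairpin[1]
            and c.window[1] > clean_truth.hairpin[0]
        ]
        assert hairpin_cands
        assert not any(c.accepted for c in hairpin_cands)
        assert any("no_star" in c.reasons for c in hairpin_cands)

    def test_sirna_like_cluster_rejected(self):
        # uniform reads on both strands of a non-hairpin region
        rng = random.Random(11)
        genome = {"c": _random_genome(rng, 400)}
        seqs = []
        for start in range(100, 200, 10):
            seqs += [genome["c"][start : start + 21]] * 3
            seqs += [revcomp(genome["c"][start + 5 : start + 26])] * 3
        from phasilens.preprocess import collapse_reads

        cands, _ = annotate_mirna(collapse_reads(seqs), genome, mincov=5)
        assert cands
        assert not any(c.accepted for c in cands)

    def test_accepted_mature_is_window_substring(self, clean_truth, clean_records):
        cands, _ = annotate_mirna(clean_records, clean_truth.genome)
        for c in cands:
            if c.accepted:
                ws, we = c.window
                assert c.mature_seq in clean_truth.genome[c.seqid][ws:we]
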