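"""Independent brute-force oracles used to freeze expected values.

These deliberately avoid the package's own algorithms: structure
enumeration instead of DP, per-position scans instead of vectorized
mapping, direct formula transcriptions instead of shared helpers.
"""

from __future__ import annotations

import math
import statistics
from typing import Dict, List, Sequence, Tuple

_RNA_PAIRS = {
    ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "U"), ("U", "G"),
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def pairable(a: str, b: str) -> bool:
    a = a.upper().replace("T", "U")
    b = b.upper().replace("T", "U")
    return (a, b) in _RNA_PAIRS


def enumerate_structures(seq: str, min_loop: int = 3):
    """Yield every valid nested structure (as a frozenset of pairs).

    Exponential; intended for sequences of length <= 12.
    """
    n = len(seq)

    def rec(i: int, j: int):
        if j - i <= min_loop:
            yield frozenset()
            return
        # position i unpaired
        for rest in rec(i + 1, j):
            yield rest
        # position i paired with k
        for k in range(i + min_loop + 1, j + 1):
            if pairable(seq[i], seq[k]):
                for inner in rec(i + 1, k - 1):
                    for outer in rec(k + 1, j):
                        yield inner | outer | {(i, k)}

    yield from rec(0, n - 1)


def max_pairs_brute(seq: str, min_loop: int = 3) -> int:
    return max(len(s) for s in enumerate_structures(seq, min_loop))


def structure_is_valid(seq: str, pairs: Sequence[Tuple[int, int]], min_loop: int = 3) -> bool:
    seen = set()
    for i, j in pairs:
        if not (0 <= i < j < len(seq)):
            return False
        if j - i - 1 < min_loop:
            return False
        if not pairable(seq[i], seq[j]):
            return False
        if i in seen or j in seen:
            return False
        seen.add(i)
        seen.add(j)
    for i, j in pairs:
        for a, b in pairs:
            if a < i < b < j:  # crossing
                return False
    return True


def scan_alignments(
    seq: str, genome: Dict[str, str], max_mismatch: int
) -> List[Tuple[str, int, str, int]]:
    """All-positions alignment scan: (seqid, start, strand, mismatches)."""
    hits = []
    for strand, query in (("+", seq.upper()), ("-", revcomp(seq))):
        for sid, chrom in genome.items():
            chrom = chrom.upper()
            for pos in range(len(chrom) - len(query) + 1):
                mm = sum(
                    1 for a, b in zip(query, chrom[pos : pos + len(query)]) if a != b
                )
                if mm <= max_mismatch:
                    hits.append((sid, pos, strand, mm))
    return sorted(hits)


def coverage_clusters(
    intervals: Sequence[Tuple[int, int, float]], length: int, mincov: float
) -> List[Tuple[int, int]]:
    """Threshold a coverage array built by direct accumulation."""
    cov = [0.0] * length
    for start, end, weight in intervals:
        for p in range(start, end):
            cov[p] += weight
    clusters = []
    p = 0
    while p < length:
        if cov[p] > 1e-9:
            q = p
            while q < length and cov[q] > 1e-9:
                q += 1
            if max(cov[p:q]) >= mincov - 1e-9:
                clusters.append((p, q))
            p = q
        else:
            p += 1
    return clusters


def categorize(counts: Dict[int, float], pos: int) -> int:
    """Direct transcription of the cleavage-category definitions."""
    c = counts[pos]
    assert c > 0
    if c == 1:
        return 4
    values = [v for v in counts.values() if v > 0]
    cmax = max(values)
    if c == cmax:
        return 0 if values.count(cmax) == 1 else 1
    med = statistics.median(values)
    return 2 if c > med else 3


def phase_score_formula(P: float, U: float, k: int, k_min: int = 3) -> float:
    if k < k_min:
        return 0.0
    return math.log((1.0 + 10.0 * P / (1.0 + U)) ** (k - 2))


def duplex_penalty(mirna: str, window: str) -> float:
    """Position-by-position tally of the duplex scoring scheme."""
    m = mirna.upper().replace("T", "U")
    w = window.upper().replace("T", "U")
    assert len(m) == len(w)
    total = 0.0
    for i in range(len(m)):
        t = w[len(w) - 1 - i]
        if pairable(m[i], t) and {m[i], t} in ({"A", "U"}, {"G", "C"}):
            cost = 0.0
        elif {m[i], t} == {"G", "U"}:
            cost = 0.5
        else:
            cost = 1.0
        if 2 <= i + 1 <= 13:
            cost *= 2
        total += cost
    return total


def cigar_junctions(pos1: int, cigar: str) -> List[Tuple[int, int, int]]:
    """(donor, acceptor, skip) per N op, walking the CIGAR string."""
    import re

    ref = pos1 - 1
    out = []
    for length, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        length = int(length)
        if op in "M=XD":
            ref += length
        elif op == "N":
            out.append((ref + 1, ref + length + 1, length))
            ref += length
    return out
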