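"""MIRNA locus annotation from genome-mapped sRNA clusters.

Pipeline: substitution-only read mapping (<=1 mismatch, both strands) ->
fractional coverage clustering -> hairpin folding by base-pair
maximization (Watson-Crick + G:U, Nussinov-style DP) -> duplex-criteria
evaluation (dominant mature read, star read with 2-nt 3' overhangs,
precision threshold).

Base-pair maximization deliberately replaces thermodynamic folding: on
clean data the accept/reject decision depends only on the stem pairing
pattern, not on free energies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigError, PhasilensError
from .ioutils import revcomp
from .preprocess import CollapsedRead

_RNA_PAIRS = {
    ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "U"), ("U", "G"),
}


@dataclass(frozen=True)
class SrnaAlignment:
    """One end-to-end, gapless alignment of a collapsed read."""

    read: CollapsedRead
    seqid: str
    start: int  # 0-based leftmost genomic position
    strand: str  # '+' or '-'
    mismatches: int

    @property
    def end(self) -> int:
        """0-based exclusive end."""
        return self.start + len(self.read.sequence)

    @property
    def five_prime(self) -> int:
        """0-based genomic position of the read's 5' end."""
        return self.start if self.strand == "+" else self.end - 1


def map_reads(
    reads: Sequence[CollapsedRead],
    genome: Dict[str, str],
    max_mismatch: int = 1,
) -> List[SrnaAlignment]:
    """All gapless alignments with <= ``max_mismatch`` substitutions.

    Both strands are searched (reverse complement for '-'); reads
    containing N are skipped (they cannot be placed unambiguously).
    """
    if not genome:
        raise ConfigError("empty genome")
    if max_mismatch not in (0, 1):
        raise ConfigError("max_mismatch must be 0 or 1")

    arrays = {
        sid: np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        for sid, seq in genome.items()
    }
    out: List[SrnaAlignment] = []
    for read in reads:
        seq = read.sequence.upper()
        if "N" in seq:
            continue
        for strand, query in (("+", seq), ("-", revcomp(seq))):
            q = np.frombuffer(query.encode(), dtype=np.uint8)
            for sid, g in arrays.items():
                if len(q) > len(g):
                    continue
                windows = sliding_window_view(g, len(q))
                mm = (windows != q).sum(axis=1)
                for pos in np.nonzero(mm <= max_mismatch)[0]:
                    out.append(
                        SrnaAlignment(read, sid, int(pos), strand, int(mm[pos]))
                    )
    out.sort(key=lambda a: (a.seqid, a.start, a.strand, a.read.sequence))
    return out


def cluster_by_coverage(
    alignments: Sequence[SrnaAlignment],
    mincov: float,
    chrom_sizes: Dict[str, int],
) -> List[Tuple[str, int, int]]:
    """Maximal covered intervals containing a base with coverage >= mincov.

    Coverage sums read abundance per base; multi-mapping reads contribute
    fractionally (count / number of alignments of that sequence) so that
    total coverage mass equals total abundance. Returned intervals are
    0-based half-open, separated by >= 1 uncovered base.
    """
    if mincov < 1:
        raise ConfigError("mincov must be >= 1")
    n_aln = Counter(a.read.sequence for a in alignments)
    cov = {sid: np.zeros(n, dtype=float) for sid, n in chrom_sizes.items()}
    for a in alignments:
        cov[a.seqid][a.start : a.end] += a.read.count / n_aln[a.read.sequence]

    clusters: List[Tuple[str, int, int]] = []
    eps = 1e-9
    for sid in sorted(cov):
        c = cov[sid]
        covered = c > eps
        if not covered.any():
            continue
        edges = np.flatnonzero(np.diff(covered.astype(np.int8)))
        starts = [int(i) + 1 for i in edges[::1] if covered[i + 1]]
        ends = [int(i) + 1 for i in edges if not covered[i + 1]]
        if covered[0]:
            starts = [0] + starts
        if covered[-1]:
            ends = ends + [len(c)]
        for s, e in zip(starts, ends):
            if c[s:e].max() >= mincov - eps:
                clusters.append((sid, s, e))
    return clusters


def _pairable_matrix(seq: str) -> np.ndarray:
    s = seq.upper().replace("T", "U")
    n = len(s)
    mat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if (s[i], s[j]) in _RNA_PAIRS:
                mat[i, j] = True
    return mat


def fold_window(seq: str, min_loop: int = 3, foldsize: int = 340) -> List[Tuple[int, int]]:
    """Maximum-cardinality nested pairing (WC + G:U) with hairpin loops >= min_loop.

    Nussinov-style DP with deterministic traceback: at each subproblem a
    pairing of the left end is preferred over leaving it unpaired, and
    among tying partners the smallest index wins. Returns 0-based index
    pairs sorted by the left index.
    """
    n = len(seq)
    if n > foldsize:
        raise ConfigError(f"window length {n} exceeds foldsize {foldsize}")
    if min_loop < 3:
        raise ConfigError("min_loop must be >= 3")
    if n == 0:
        return []

    P = _pairable_matrix(seq)
    # Padded so that M[k+1, j] is 0 whenever k+1 > j (lower triangle untouched).
    M = np.zeros((n + 1, n + 1), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i + 1, j]
            ks = np.nonzero(P[i, i + min_loop + 1 : j + 1])[0]
            if ks.size:
                ks = ks + i + min_loop + 1
                vals = 1 + M[i + 1, ks - 1] + M[ks + 1, j]
                v = int(vals.max())
                if v > best:
                    best = v
            M[i, j] = best

    pairs: List[Tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        target = int(M[i, j])
        if target == 0:
            continue
        chosen = None
        for k in range(i + min_loop + 1, j + 1):
            if P[i, k] and 1 + M[i + 1, k - 1] + M[k + 1, j] == target:
                chosen = k
                break
        if chosen is not None:
            pairs.append((i, chosen))
            stack.append((chosen + 1, j))
            stack.append((i + 1, chosen - 1))
        else:
            stack.append((i + 1, j))
    pairs.sort()
    return pairs


def pairing_to_dotbracket(n: int, pairing: Sequence[Tuple[int, int]]) -> str:
    chars = ["."] * n
    for i, j in pairing:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def duplex_geometry(
    partner: Dict[int, int],
    mature: Tuple[int, int],
    star: Tuple[int, int],
    mature_plus: bool = True,
    star_plus: bool = True,
) -> Optional[Tuple[int, int, int]]:
    """Duplex geometry of two arm intervals under a pairing map.

    Intervals are half-open window-local coordinates. Returns
    ``(n_unpaired_mature, mature_3p_overhang, star_3p_overhang)`` or
    None when no mature base pairs into the star interval. Overhangs
    are measured from each arm's 3' end (right for plus placements,
    left for minus) to its outermost base paired with the other arm.
    """
    m0, m1 = mature
    s0, s1 = star
    star_range = range(s0, s1)
    paired_m = [p for p in range(m0, m1) if partner.get(p) in star_range]
    if not paired_m:
        return None
    unpaired = (m1 - m0) - len(paired_m)
    ov_m = (m1 - 1) - max(paired_m) if mature_plus else min(paired_m) - m0
    paired_s = [partner[p] for p in paired_m]
    ov_s = (s1 - 1) - max(paired_s) if star_plus else min(paired_s) - s0
    return unpaired, ov_m, ov_s


@dataclass(frozen=True)
class HairpinThresholds:
    """Acceptance thresholds for MIRNA locus evaluation."""

    dominance: float = 0.5
    precision: float = 0.75
    max_unpaired_mature: int = 5
    overhang: int = 2


@dataclass
class HairpinCandidate:
    """Evaluation result for one folded window."""

    seqid: str
    window: Tuple[int, int]  # 0-based half-open genomic interval
    accepted: bool = False
    reasons: Tuple[str, ...] = ()
    mature_seq: Optional[str] = None
    star_seq: Optional[str] = None
    mature_arm: Optional[Tuple[int, int]] = None  # genomic, 0-based half-open
    star_arm: Optional[Tuple[int, int]] = None
    strand: Optional[str] = None
    precision: float = 0.0
    dominance: float = 0.0
    overhang_3p: Optional[int] = None
    n_window_reads: int = 0
    total_abundance: float = 0.0
    pairing: List[Tuple[int, int]] = field(default_factory=list)


def evaluate_hairpin(
    window: Tuple[str, int, int],
    alignments: Sequence[SrnaAlignment],
    pairing: Sequence[Tuple[int, int]],
    thresholds: Optional[HairpinThresholds] = None,
) -> HairpinCandidate:
    """Apply MIRNA duplex criteria to one folded window.

    Accept iff (a) a single dominant read holds >= ``dominance`` of the
    window abundance, (b) some other read placed on the opposite arm
    forms a duplex with <= ``max_unpaired_mature`` unpaired mature bases
    and an exact ``overhang``-nt 3' overhang on both strands under the
    window pairing, and (c) mature + star variants account for
    >= ``precision`` of window abundance.
    """
    thr = thresholds or HairpinThresholds()
    seqid, wstart, wend = window
    cand = HairpinCandidate(seqid=seqid, window=(wstart, wend))

    in_window = [
        a for a in alignments
        if a.seqid == seqid and a.start >= wstart and a.end <= wend
    ]
    by_seq: Dict[str, List[SrnaAlignment]] = {}
    for a in in_window:
        by_seq.setdefault(a.read.sequence, []).append(a)
    if not by_seq:
        cand.reasons = ("no_reads",)
        return cand

    total = sum(alns[0].read.count for alns in by_seq.values())
    cand.n_window_reads = len(by_seq)
    cand.total_abundance = float(total)

    dom_seq, dom_alns = max(
        by_seq.items(), key=lambda kv: (kv[1][0].read.count, kv[0])
    )
    dom_count = dom_alns[0].read.count
    cand.dominance = dom_count / total
    cand.mature_seq = dom_seq

    reasons: List[str] = []
    if cand.dominance < thr.dominance:
        reasons.append("no_dominant")

    partner = {}
    for i, j in pairing:
        partner[i] = j
        partner[j] = i

    star_hit = None
    for maln in sorted(dom_alns, key=lambda a: (a.strand != "+", a.start)):
        m0, m1 = maln.start - wstart, maln.end - wstart
        for seq2, alns2 in sorted(
            by_seq.items(), key=lambda kv: (-kv[1][0].read.count, kv[0])
        ):
            if seq2 == dom_seq:
                continue
            for saln in alns2:
                s0, s1 = saln.start - wstart, saln.end - wstart
                if s0 < m1 and m0 < s1:  # overlapping: same arm
                    continue
                geom = duplex_geometry(
                    partner, (m0, m1), (s0, s1),
                    mature_plus=maln.strand == "+",
                    star_plus=saln.strand == "+",
                )
                if geom is None:
                    continue
                unpaired, ov_m, ov_s = geom
                if unpaired > thr.max_unpaired_mature:
                    continue
                if ov_m == thr.overhang and ov_s == thr.overhang:
                    star_hit = (maln, saln, seq2, ov_m)
                    break
            if star_hit:
                break
        if star_hit:
            break

    if star_hit is None:
        reasons.append("no_star")
        cand.precision = cand.dominance
    else:
        maln, saln, star_seq, ov = star_hit
        cand.star_seq = star_seq
        cand.strand = maln.strand
        cand.mature_arm = (maln.start, maln.end)
        cand.star_arm = (saln.start, saln.end)
        cand.overhang_3p = ov

        def _variant_abundance(ref: SrnaAlignment) -> float:
            tot = 0.0
            for alns in by_seq.values():
                if any(
                    a.strand == ref.strand and a.five_prime == ref.five_prime
                    for a in alns
                ):
                    tot += alns[0].read.count
            return tot

        cand.precision = (
            _variant_abundance(maln) + _variant_abundance(saln)
        ) / total

    if cand.precision < thr.precision:
        reasons.append("low_precision")

    cand.reasons = tuple(reasons)
    cand.accepted = not reasons
    cand.pairing = list(pairing)
    return cand


def _merge_clusters(
    clusters: Sequence[Tuple[str, int, int]], merge_gap: int
) -> List[Tuple[str, int, int]]:
    merged: List[Tuple[str, int, int]] = []
    for sid, s, e in sorted(clusters):
        if merged and merged[-1][0] == sid and s - merged[-1][2] <= merge_gap:
            psid, ps, pe = merged[-1]
            merged[-1] = (psid, ps, max(pe, e))
        else:
            merged.append((sid, s, e))
    return merged


def annotate_mirna(
    records: Sequence[CollapsedRead],
    genome: Dict[str, str],
    *,
    mincov: float = 15,
    foldsize: int = 340,
    max_mismatch: int = 1,
    merge_gap: int = 50,
    pad: int = 75,
    min_loop: int = 3,
    thresholds: Optional[HairpinThresholds] = None,
) -> Tuple[List[HairpinCandidate], List[SrnaAlignment]]:
    """End-to-end MIRNA annotation: map, cluster, fold, evaluate.

    Nearby clusters (gap <= ``merge_gap``) are merged so that both arms
    of a hairpin fall into one folding window; windows are padded by
    ``pad`` on each side, shrinking the padding if ``foldsize`` would be
    exceeded. Windows whose merged cluster alone exceeds ``foldsize``
    are rejected with reason ``too_long``.
    """
    alignments = map_reads(records, genome, max_mismatch=max_mismatch)
    chrom_sizes = {sid: len(seq) for sid, seq in genome.items()}
    clusters = cluster_by_coverage(alignments, mincov, chrom_sizes)
    islands = _merge_clusters(clusters, merge_gap)

    results: List[HairpinCandidate] = []
    for sid, cs, ce in islands:
        if ce - cs > foldsize:
            cand = HairpinCandidate(seqid=sid, window=(cs, ce))
            cand.reasons = ("too_long",)
            results.append(cand)
            continue
        p = min(pad, (foldsize - (ce - cs)) // 2)
        ws = max(0, cs - p)
        we = min(chrom_sizes[sid], ce + p)
        pairing = fold_window(genome[sid][ws:we], min_loop=min_loop, foldsize=foldsize)
        results.append(
            evaluate_hairpin((sid, ws, we), alignments, pairing, thresholds)
        )

    # Keep at most one accepted locus among overlapping windows.
    accepted = sorted(
        (c for c in results if c.accepted),
        key=lambda c: (-c.precision, c.seqid, c.window[0]),
    )
    kept: List[HairpinCandidate] = []
    for c in accepted:
        for k in kept:
            if c.seqid == k.seqid and c.window[0] < k.window[1] and k.window[0] < c.window[1]:
                c.accepted = False
                c.reasons = ("redundant",)
                break
        else:
            kept.append(c)
    return results, alignments
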