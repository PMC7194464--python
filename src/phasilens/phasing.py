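"""21-nt phase-register assignment and phase scoring around a slice anchor.

Registers are anchored at the slice position ``s`` (1-based transcript
coordinate). A plus-strand read is in phase iff ``(start - s) % period
== 0``; a minus-strand read is in phase iff ``(end - s) % period ==
period - 3``, which encodes the 2-nt 3' overhang of diced duplexes: the
antisense partner of the sense cycle spanning ``s+pk .. s+pk+p-1`` spans
``s+pk-2 .. s+pk+p-3``.

The phase score over a window of ``window_cycles`` cycles starting at
``s`` is ``ln[(1 + 10 * P / (1 + U)) ** (k - 2)]`` for ``k >= k_min``
occupied cycles, else 0, with P/U the in-/out-of-phase abundance of
size-selected reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .mirna import SrnaAlignment


@dataclass(frozen=True)
class RegisterCall:
    """Phase register assignment for one alignment."""

    alignment: SrnaAlignment
    register: int
    in_phase: bool
    strand: str

    @property
    def d_label(self) -> Optional[str]:
        """Dn(+)/Dn(-) label, defined only for in-phase reads."""
        if not self.in_phase:
            return None
        return f"D{self.register + 1}({self.strand})"


def assign_registers(
    alignments: Sequence[SrnaAlignment], s: int, period: int = 21
) -> List[RegisterCall]:
    """Assign a phase register and in-phase flag to every alignment.

    Coordinates are 1-based transcript positions; ``start`` is the
    leftmost and ``end`` the rightmost aligned base. The 5'-end rule is
    used regardless of read length.
    """
    calls: List[RegisterCall] = []
    for a in alignments:
        start1 = a.start + 1
        end1 = a.end  # 0-based exclusive end == 1-based inclusive end
        if a.strand == "+":
            offset = start1 - s
            in_phase = offset % period == 0
            register = offset // period
        else:
            offset = end1 - s
            in_phase = offset % period == period - 3
            register = (offset - (period - 3)) // period
        calls.append(RegisterCall(a, register, in_phase, a.strand))
    return calls


@dataclass(frozen=True)
class PhaseStats:
    k: int
    P: float
    U: float
    score: float


def phase_score(
    alignments: Sequence[SrnaAlignment],
    s: int,
    period: int = 21,
    k_min: int = 3,
    window_cycles: int = 10,
    size_range: Tuple[int, int] = (20, 22),
) -> PhaseStats:
    """Phase score over the window ``[s, s + period * window_cycles)``.

    Only reads whose length falls in ``size_range`` (inclusive) count
    toward P, U and k; window membership is by the read's 5'-end
    position.
    """
    calls = assign_registers(alignments, s, period)
    lo, hi = s, s + period * window_cycles
    k_set = set()
    P = 0.0
    U = 0.0
    for c in calls:
        a = c.alignment
        length = len(a.read.sequence)
        five = a.five_prime + 1  # 1-based
        if not (lo <= five < hi):
            continue
        if not (size_range[0] <= length <= size_range[1]):
            continue
        if c.in_phase and 0 <= c.register < window_cycles:
            P += a.read.count
            k_set.add(c.register)
        else:
            U += a.read.count
    k = len(k_set)
    if k < k_min:
        score = 0.0
    else:
        score = (k - 2) * math.log1p(10.0 * P / (1.0 + U))
    return PhaseStats(k=k, P=P, U=U, score=score)


@dataclass
class PhaseReport:
    """Phasing evidence for one candidate anchor on one transcript."""

    transcript_id: str
    anchor: int
    period: int
    stats: PhaseStats
    calls: List[RegisterCall] = field(default_factory=list)
    passed: bool = False
    best: bool = False

    @property
    def score(self) -> float:
        return self.stats.score


def call_phas(
    transcript_id: str,
    alignments: Sequence[SrnaAlignment],
    anchors: Sequence[int],
    score_min: float = 4.0,
    period: int = 21,
    k_min: int = 3,
    window_cycles: int = 10,
    size_range: Tuple[int, int] = (20, 22),
) -> List[PhaseReport]:
    """One report per anchor, sorted by score; the top anchor is flagged best.

    ``passed`` marks reports reaching ``score_min``. An empty anchor
    list yields an empty result.
    """
    tx_alignments = [a for a in alignments if a.seqid == transcript_id]
    reports: List[PhaseReport] = []
    for anchor in sorted(set(anchors)):
        stats = phase_score(
            tx_alignments,
            anchor,
            period=period,
            k_min=k_min,
            window_cycles=window_cycles,
            size_range=size_range,
        )
        reports.append(
            PhaseReport(
                transcript_id=transcript_id,
                anchor=anchor,
                period=period,
                stats=stats,
                calls=assign_registers(tx_alignments, anchor, period),
                passed=stats.score >= score_min,
            )
        )
    reports.sort(key=lambda r: (-r.score, r.anchor))
    if reports:
        reports[0].best = True
    return reports


def render_alignment(
    transcript_seq: str,
    report: PhaseReport,
    flank: int = 5,
    max_reads: int = 80,
) -> str:
    """Text rendering of position-sorted reads under the transcript.

    Shows the window around the anchor with each read on its own line,
    minus-strand reads printed as their reverse complement in lowercase,
    with the D-label when in phase.
    """
    from .ioutils import revcomp

    s = report.anchor
    lo = max(1, s - flank)
    hi = min(len(transcript_seq), s + report.period * 10 + flank)
    width = hi - lo + 1
    lines = [
        f"# {report.transcript_id} anchor={s} period={report.period} "
        f"k={report.stats.k} P={report.stats.P:g} U={report.stats.U:g} "
        f"score={report.stats.score:.3f}",
        f"{transcript_seq[lo - 1:hi]}  <transcript {lo}..{hi}>",
    ]
    shown = 0
    for call in sorted(
        report.calls, key=lambda c: (c.alignment.start, c.alignment.strand)
    ):
        a = call.alignment
        start1 = a.start + 1
        if start1 < lo or a.end > hi or shown >= max_reads:
            continue
        pad = " " * (start1 - lo)
        seq = a.read.sequence
        if a.strand == "-":
            seq = revcomp(seq).lower()
        label = call.d_label or "."
        rest = " " * (width - (start1 - lo) - len(seq))
        lines.append(f"{pad}{seq}{rest}  x{a.read.count} {a.strand} {label}")
        shown += 1
    return "\n".join(lines) + "\n"
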