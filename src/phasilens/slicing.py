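"""Target-site scoring and pseudo-degradome slice-site detection.

A miRNA/target duplex is scored position-by-position against an
antiparallel fixed-length window (no bulges): match 0, G:U wobble 0.5,
mismatch 1.0, with costs doubled over miRNA positions 2-13. T-plots
accumulate sense-strand read 5'-end abundance per transcript position;
the slice site of a candidate duplex is the transcript base paired to
miRNA nucleotide 10 (for a site spanning s..e 1-based, position e - 9).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError, NoCleavageEvidenceError
from .mirna import SrnaAlignment

_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _pair_kind(mirna_base: str, target_base: str) -> str:
    """'match', 'wobble' or 'mismatch' for one antiparallel position."""
    if _WC.get(mirna_base) == target_base:
        return "match"
    if (mirna_base == "G" and target_base == "U") or (
        mirna_base == "U" and target_base == "G"
    ):
        return "wobble"
    return "mismatch"


def score_duplex(mirna: str, target_window: str) -> Tuple[float, str]:
    """Penalty and per-position trace for an antiparallel duplex.

    ``target_window`` is the transcript site in its natural 5'->3'
    orientation; miRNA position i (0-based from the 5' end) is paired
    with window position ``len - 1 - i``. Trace characters, ordered by
    miRNA position: '|' match, 'o' wobble, '.' mismatch.
    """
    m = _to_rna(mirna)
    t = _to_rna(target_window)
    if len(m) != len(t):
        raise ConfigError(
            f"miRNA length {len(m)} != target window length {len(t)}"
        )
    penalty = 0.0
    trace = []
    costs = {"match": 0.0, "wobble": 0.5, "mismatch": 1.0}
    glyph = {"match": "|", "wobble": "o", "mismatch": "."}
    for i in range(len(m)):
        kind = _pair_kind(m[i], t[len(t) - 1 - i])
        cost = costs[kind]
        if 1 <= i <= 12:  # miRNA positions 2-13 (1-based) are doubled
            cost *= 2
        penalty += cost
        trace.append(glyph[kind])
    return penalty, "".join(trace)


@dataclass
class TPlot:
    """Per-position sense-strand 5'-end counts for one transcript."""

    transcript_id: str
    counts: np.ndarray  # length n+1; index 1..n are transcript positions

    @property
    def length(self) -> int:
        return len(self.counts) - 1

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def nonzero_positions(self) -> List[int]:
        return [int(p) for p in np.nonzero(self.counts)[0] if p >= 1]


def build_tplot(
    alignments: Sequence[SrnaAlignment],
    transcript_length: int,
    transcript_id: str,
) -> TPlot:
    """Accumulate sense-strand read 5'-end abundance per position.

    Antisense reads are excluded from the counts (they are retained for
    phasing by the caller).
    """
    counts = np.zeros(transcript_length + 1, dtype=float)
    for a in alignments:
        if a.seqid != transcript_id or a.strand != "+":
            continue
        pos = a.start + 1  # 1-based 5' end
        if 1 <= pos <= transcript_length:
            counts[pos] += a.read.count
    return TPlot(transcript_id=transcript_id, counts=counts)


def categorize_position(tplot: TPlot, pos: int) -> int:
    """Cleavage category 0-4 of a queried position.

    4: count == 1. 0: count > 1 and unique transcript-wide maximum.
    1: count > 1, equals the maximum, maximum attained elsewhere too.
    2: count > 1, below maximum, above the median of positions with
    count > 0. 3: count > 1 and <= that median.
    """
    if not (1 <= pos <= tplot.length):
        raise ConfigError(f"position {pos} outside transcript 1..{tplot.length}")
    c = float(tplot.counts[pos])
    if c == 0:
        raise NoCleavageEvidenceError(
            f"no 5'-end reads at {tplot.transcript_id}:{pos}"
        )
    if c == 1:
        return 4
    nonzero = tplot.counts[1:][tplot.counts[1:] > 0]
    cmax = float(nonzero.max())
    if c == cmax:
        return 0 if int((nonzero == cmax).sum()) == 1 else 1
    median = float(np.median(nonzero))
    return 2 if c > median else 3


@dataclass
class TargetAlignment:
    """A scored miRNA site on a transcript, with slice-site evidence."""

    mirna: str
    transcript_id: str
    start: int  # 1-based inclusive site start on the transcript
    end: int  # 1-based inclusive site end
    penalty: float
    slice_position: int  # transcript base paired to miRNA nt 10
    slice_count: float
    category: Optional[int]
    trace: str


def detect_slice_sites(
    mirna: str,
    transcript_id: str,
    transcript_seq: str,
    alignments: Sequence[SrnaAlignment],
    penalty_max: float = 7.0,
    category_max: int = 4,
) -> List[TargetAlignment]:
    """Scan all fixed-length windows for supported cleavage sites.

    A window is reported when its duplex penalty is <= ``penalty_max``,
    the T-plot count at its slice position is >= 1, and its cleavage
    category is <= ``category_max``. Results are sorted by
    (category, penalty, slice_position).
    """
    m = _to_rna(mirna)
    L = len(m)
    n = len(transcript_seq)
    if n < L:
        return []
    tplot = build_tplot(alignments, n, transcript_id)
    hits: List[TargetAlignment] = []
    for s in range(1, n - L + 2):  # 1-based window start
        e = s + L - 1
        penalty, trace = score_duplex(m, transcript_seq[s - 1 : e])
        if penalty > penalty_max:
            continue
        slice_pos = e - 9
        count = float(tplot.counts[slice_pos]) if 1 <= slice_pos <= n else 0.0
        if count < 1:
            continue
        category = categorize_position(tplot, slice_pos)
        if category > category_max:
            continue
        hits.append(
            TargetAlignment(
                mirna=m,
                transcript_id=transcript_id,
                start=s,
                end=e,
                penalty=penalty,
                slice_position=slice_pos,
                slice_count=count,
                category=category,
                trace=trace,
            )
        )
    hits.sort(key=lambda h: (h.category, h.penalty, h.slice_position))
    return hits


def tplot_table(tplot: TPlot) -> List[Tuple[int, float]]:
    """(position, count) rows for positions with non-zero counts."""
    return [(p, float(tplot.counts[p])) for p in tplot.nonzero_positions()]


def plot_tplot(
    tplot: TPlot, out_png: str, slice_position: Optional[int] = None
) -> None:
    """Optional line plot of the T-plot, slice position marked in red."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    positions = np.arange(1, tplot.length + 1)
    ax.plot(positions, tplot.counts[1:], lw=0.8, color="black")
    if slice_position is not None:
        ax.plot(
            [slice_position],
            [tplot.counts[slice_position]],
            "o",
            color="red",
            ms=5,
        )
    ax.set_xlabel(f"{tplot.transcript_id} position (nt)")
    ax.set_ylabel("5'-end reads")
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
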