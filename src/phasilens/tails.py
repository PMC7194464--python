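"""Classification of reads into genome-templated vs 3'-tailed species.

A read is decomposed into its longest genome-templated prefix at an
anchor plus a (possibly empty) non-templated tail. Classes:

- ``templated``: the full read matches the genome and does not end in T.
- ``ambiguous``: the full read matches the genome and ends in T — a
  non-templated U appended over a genomic T is indistinguishable from
  templated sequence, so such reads are excluded from both numerator and
  denominator of the mono-U fraction.
- ``mono_U``: exactly the final base is a T mismatching the genome.
- ``other_tail``: the trailing mismatching bases are not a single T.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import UnanchoredReadError
from .ioutils import revcomp
from .preprocess import CollapsedRead

MIN_TEMPLATED_PREFIX = 18

TAIL_CLASSES = ("templated", "mono_U", "other_tail", "ambiguous")


@dataclass(frozen=True)
class Anchor:
    """Placement of a read's templated prefix.

    ``start`` is on the oriented strand: for '+', a 0-based position on
    the chromosome; for '-', a 0-based position on the reverse
    complement of the chromosome.
    """

    seqid: str
    start: int
    strand: str


@dataclass(frozen=True)
class TailCall:
    read: CollapsedRead
    anchor: Anchor
    templated_prefix_len: int
    tail: str
    klass: str
    chrom_len: int

    @property
    def genome_span(self) -> Tuple[int, int]:
        """0-based half-open genomic interval covered by the full read."""
        n = len(self.read.sequence)
        if self.anchor.strand == "+":
            return (self.anchor.start, self.anchor.start + n)
        return (self.chrom_len - self.anchor.start - n, self.chrom_len - self.anchor.start)


def find_anchor(
    sequence: str,
    genome: Dict[str, str],
    min_prefix: int = MIN_TEMPLATED_PREFIX,
    _rc_cache: Optional[Dict[str, str]] = None,
) -> Optional[Anchor]:
    """Longest-exact-prefix placement of a read on either strand.

    Prefix lengths are tried from the full read down to ``min_prefix``;
    the first (longest) hit wins, plus strand before minus, chromosomes
    in sorted order. Returns None when no prefix of >= ``min_prefix`` nt
    matches.
    """
    seq = sequence.upper()
    rc_cache = _rc_cache if _rc_cache is not None else {}
    for L in range(len(seq), min_prefix - 1, -1):
        prefix = seq[:L]
        for sid in sorted(genome):
            i = genome[sid].find(prefix)
            if i >= 0:
                return Anchor(sid, i, "+")
            if sid not in rc_cache:
                rc_cache[sid] = revcomp(genome[sid])
            i = rc_cache[sid].find(prefix)
            if i >= 0:
                return Anchor(sid, i, "-")
    return None


def classify_tail(
    read: CollapsedRead, genome: Dict[str, str], anchor: Anchor
) -> TailCall:
    """Classify one read at a given anchor (see module docstring)."""
    chrom = genome[anchor.seqid]
    oriented = chrom if anchor.strand == "+" else revcomp(chrom)
    seq = read.sequence.upper()
    n = len(seq)
    template = oriented[anchor.start : anchor.start + n]

    prefix_len = 0
    for a, b in zip(seq, template):
        if a != b:
            break
        prefix_len += 1

    if prefix_len < MIN_TEMPLATED_PREFIX:
        raise UnanchoredReadError(
            f"templated prefix {prefix_len} nt < {MIN_TEMPLATED_PREFIX} at "
            f"{anchor.seqid}:{anchor.start}{anchor.strand}"
        )

    if prefix_len == n:
        if seq[-1] == "T":
            klass, prefix_len, tail = "ambiguous", n - 1, "T"
        else:
            klass, tail = "templated", ""
    else:
        tail = seq[prefix_len:]
        klass = "mono_U" if tail == "T" else "other_tail"
    return TailCall(
        read=read,
        anchor=anchor,
        templated_prefix_len=prefix_len,
        tail=tail,
        klass=klass,
        chrom_len=len(chrom),
    )


def tail_fraction_report(calls: Sequence[TailCall]) -> pd.DataFrame:
    """Abundance-weighted tail-class fractions per read-length class.

    Ambiguous reads are reported separately and excluded from the
    fraction denominator; an empty (unclassifiable) length class yields
    NaN fractions rather than 0. ``share`` is the length class's share
    of total abundance (ambiguous included).
    """
    rows = {}
    for call in calls:
        length = len(call.read.sequence)
        row = rows.setdefault(
            length,
            {k: 0.0 for k in TAIL_CLASSES} | {"length": length},
        )
        row[call.klass] += call.read.count
    total = sum(
        r["templated"] + r["mono_U"] + r["other_tail"] + r["ambiguous"]
        for r in rows.values()
    )
    records = []
    for length in sorted(rows):
        r = rows[length]
        classifiable = r["templated"] + r["mono_U"] + r["other_tail"]
        class_total = classifiable + r["ambiguous"]
        rec = {
            "length": length,
            "abundance": class_total,
            "share": class_total / total if total else np.nan,
            "ambiguous_abundance": r["ambiguous"],
        }
        for k in ("templated", "mono_U", "other_tail"):
            rec[f"frac_{k}"] = r[k] / classifiable if classifiable else np.nan
        records.append(rec)
    return pd.DataFrame.from_records(records)


def run_tails(
    records: Sequence[CollapsedRead],
    genome: Dict[str, str],
    locus: Optional[Tuple[str, int, int]] = None,
    min_prefix: int = MIN_TEMPLATED_PREFIX,
) -> Tuple[List[TailCall], List[CollapsedRead], pd.DataFrame]:
    """Anchor and classify every read; optionally restrict to one locus.

    ``locus`` is (seqid, start0, end0) half-open; a call is kept when
    its genomic span overlaps the locus. Returns (calls, unanchored
    reads, report).
    """
    rc_cache: Dict[str, str] = {}
    calls: List[TailCall] = []
    unanchored: List[CollapsedRead] = []
    for rec in records:
        anchor = find_anchor(rec.sequence, genome, min_prefix, _rc_cache=rc_cache)
        if anchor is None:
            unanchored.append(rec)
            continue
        try:
            calls.append(classify_tail(rec, genome, anchor))
        except UnanchoredReadError:
            unanchored.append(rec)
    if locus is not None:
        sid, lo, hi = locus
        calls = [
            c
            for c in calls
            if c.anchor.seqid == sid
            and c.genome_span[0] < hi
            and lo < c.genome_span[1]
        ]
    return calls, unanchored, tail_fraction_report(calls)
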