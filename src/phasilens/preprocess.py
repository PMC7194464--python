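"""Adapter trimming, length filtering, read collapsing, RPM normalization.

The trimming rule mirrors the dominant behavior of classic clipper tools:
the leftmost exact occurrence of the full adapter is removed; failing
that, an adapter *prefix* of >= 8 nt anchored at the read 3' end is
removed. No mismatches are tolerated. Reads shorter than ``min_len``
after trimming are discarded.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from .errors import ConfigError, FormatError

VALID_BASES = frozenset("ACGTN")

#: Illumina universal adapter used as the package-wide default.
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
DEFAULT_MIN_LEN = 18


@dataclass(frozen=True)
class CollapsedRead:
    """A unique sRNA sequence with its per-library abundance."""

    sequence: str
    count: int = 1
    rpm: Optional[float] = None

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("CollapsedRead.count must be >= 1")

    @property
    def length(self) -> int:
        return len(self.sequence)


def _validate_sequence(seq: str) -> str:
    seq = seq.upper()
    if not set(seq) <= VALID_BASES:
        bad = sorted(set(seq) - VALID_BASES)
        raise FormatError(f"non-ACGTN characters in read: {bad}")
    return seq


def trim_and_filter(
    read: str,
    adapter: str = DEFAULT_ADAPTER,
    min_len: int = DEFAULT_MIN_LEN,
    min_prefix: int = 8,
) -> Optional[str]:
    """Trim the 3' adapter off ``read``; return the insert or None to discard.

    Matching strategy: leftmost exact full-adapter occurrence first; if
    absent, the longest adapter prefix of >= ``min_prefix`` nt that is a
    suffix of the read. Reads with no adapter occurrence are returned
    unchanged (subject to the length filter).
    """
    if not adapter:
        raise ConfigError("adapter must be non-empty")
    if min_len < 1:
        raise ConfigError("min_len must be >= 1")
    read = _validate_sequence(read)
    adapter = _validate_sequence(adapter)

    idx = read.find(adapter)
    if idx < 0:
        for k in range(min(len(adapter) - 1, len(read)), min_prefix - 1, -1):
            if read.endswith(adapter[:k]):
                idx = len(read) - k
                break
    trimmed = read if idx < 0 else read[:idx]
    if len(trimmed) < min_len:
        return None
    return trimmed


def collapse_reads(reads: Sequence[str]) -> List[CollapsedRead]:
    """Collapse a read list into unique records ordered by (count desc, seq)."""
    counts = Counter(r.upper() for r in reads)
    return [
        CollapsedRead(sequence=seq, count=n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def expand_reads(records: Iterable[CollapsedRead]) -> List[str]:
    """Inverse of :func:`collapse_reads` up to read order."""
    out: List[str] = []
    for rec in records:
        out.extend([rec.sequence] * rec.count)
    return out


def rpm_normalize(records: Sequence[CollapsedRead], library_total: int) -> List[CollapsedRead]:
    """Attach reads-per-million values: ``rpm = count / total * 1e6``."""
    if library_total <= 0:
        raise ConfigError("library_total must be > 0")
    total_counts = sum(r.count for r in records)
    if library_total < total_counts:
        raise ConfigError(
            f"library_total ({library_total}) < sum of counts ({total_counts})"
        )
    return [
        dataclasses.replace(r, rpm=r.count / library_total * 1e6) for r in records
    ]


def write_collapsed_fasta(path: str, records: Sequence[CollapsedRead]) -> None:
    """Write collapsed reads in the ``>tK_xN`` dialect (K = rank, N = count)."""
    with open(path, "w") as fh:
        for rank, rec in enumerate(records, start=1):
            fh.write(f">t{rank}_x{rec.count}\n{rec.sequence}\n")


def read_collapsed_fasta(path: str) -> List[CollapsedRead]:
    records: List[CollapsedRead] = []
    with open(path) as fh:
        name = None
        seq_parts: List[str] = []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append(_collapsed_from_header(name, "".join(seq_parts)))
                name = line[1:]
                seq_parts = []
            else:
                seq_parts.append(line)
        if name is not None:
            records.append(_collapsed_from_header(name, "".join(seq_parts)))
    return records


def _collapsed_from_header(name: str, seq: str) -> CollapsedRead:
    try:
        count = int(name.rsplit("_x", 1)[1])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"collapsed FASTA header '{name}' lacks _xN count") from exc
    return CollapsedRead(sequence=_validate_sequence(seq), count=count)


def abundance_table(records: Sequence[CollapsedRead]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sequence": [r.sequence for r in records],
            "length": [r.length for r in records],
            "count": [r.count for r in records],
            "rpm": [r.rpm for r in records],
        }
    )


def preprocess_library(
    raw_reads: Sequence[str],
    adapter: str = DEFAULT_ADAPTER,
    min_len: int = DEFAULT_MIN_LEN,
) -> Dict[str, object]:
    """Trim, filter, collapse and normalize one library.

    Returns a dict with ``records`` (RPM-annotated CollapsedReads),
    ``n_input``, ``n_kept``.
    """
    kept = []
    for read in raw_reads:
        trimmed = trim_and_filter(read, adapter=adapter, min_len=min_len)
        if trimmed is not None:
            kept.append(trimmed)
    records = collapse_reads(kept)
    if kept:
        records = rpm_normalize(records, library_total=len(kept))
    return {"records": records, "n_input": len(raw_reads), "n_kept": len(kept)}
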