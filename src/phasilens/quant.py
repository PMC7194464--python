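"""Locus-level expression from SAM, splice junctions, summary statistics.

Reads are assigned to a locus iff their leftmost aligned base lies in
the locus interval (stated in the output header); only primary mapped
alignments count. RPKM = count / (locus_kb * total_mapped_millions).
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
from scipy import stats as sps

from .errors import ConfigError, FormatError

EXPR_HEADER_NOTE = "# read-to-locus rule: leftmost aligned base within locus interval"


def _primary_records(sam_path: str):
    try:
        with pysam.AlignmentFile(sam_path, "r", check_sq=True) as fh:
            for rec in fh:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                yield rec
    except (ValueError, OSError) as exc:
        raise FormatError(f"malformed SAM {sam_path}: {exc}") from exc


def count_locus_reads(
    sam_path: str,
    loci: Sequence[Tuple[str, str, int, int]],
) -> pd.DataFrame:
    """Primary-alignment counts and RPKM per locus.

    ``loci`` rows are ``(locus_id, seqid, start1, end1)`` with 1-based
    inclusive coordinates.
    """
    counts: Dict[str, int] = {locus_id: 0 for locus_id, *_ in loci}
    total_mapped = 0
    for rec in _primary_records(sam_path):
        total_mapped += 1
        left = rec.reference_start + 1  # 1-based leftmost aligned base
        for locus_id, seqid, start1, end1 in loci:
            if rec.reference_name == seqid and start1 <= left <= end1:
                counts[locus_id] += 1
    rows = []
    for locus_id, seqid, start1, end1 in loci:
        kb = (end1 - start1 + 1) / 1000.0
        millions = total_mapped / 1e6
        rpkm = counts[locus_id] / (kb * millions) if total_mapped else np.nan
        rows.append(
            {
                "locus": locus_id,
                "seqid": seqid,
                "start": start1,
                "end": end1,
                "count": counts[locus_id],
                "rpkm": rpkm,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["total_mapped"] = total_mapped
    return df


def extract_junctions(sam_path: str) -> pd.DataFrame:
    """Splice junctions from CIGAR skip (N) operations.

    ``donor`` is the first skipped base and ``acceptor`` the first base
    after the skip (both 1-based), so ``skip_length = acceptor - donor``
    (half-open). Identical junctions are merged with summed support.
    """
    support: Dict[Tuple[str, int, int], int] = {}
    for rec in _primary_records(sam_path):
        if rec.cigartuples is None:
            continue
        ref = rec.reference_start  # 0-based
        for op, length in rec.cigartuples:
            if op in (0, 7, 8, 2):  # M, =, X, D consume reference
                ref += length
            elif op == 3:  # N: skipped region
                donor = ref + 1
                acceptor = ref + length + 1
                key = (rec.reference_name, donor, acceptor)
                support[key] = support.get(key, 0) + 1
                ref += length
            # I, S, H, P do not consume reference
    rows = [
        {
            "seqid": sid,
            "donor": donor,
            "acceptor": acceptor,
            "skip_length": acceptor - donor,
            "support": n,
        }
        for (sid, donor, acceptor), n in sorted(support.items())
    ]
    return pd.DataFrame(
        rows, columns=["seqid", "donor", "acceptor", "skip_length", "support"]
    )


def sem_ci(
    values: Sequence[float], confidence: float = 0.95
) -> Tuple[float, float, float, float]:
    """Mean, s.e.m. (n-1 sd) and two-sided t confidence interval."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ConfigError("sem_ci requires n >= 2")
    mean = float(x.mean())
    sem = float(x.std(ddof=1) / math.sqrt(n))
    tq = float(sps.t.ppf(0.5 + confidence / 2.0, n - 1))
    return mean, sem, mean - tq * sem, mean + tq * sem


def paired_t_test(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, int, float]:
    """Two-sided paired Student t-test: ``t = mean(d) / (sd(d)/sqrt(n))``.

    Degenerate zero-variance differences: p = 0 when mean(d) != 0
    (t = +-inf), p = 1 when all differences are zero (t = 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigError("paired_t_test requires equal-length samples")
    n = x.size
    if n < 2:
        raise ConfigError("paired_t_test requires n >= 2")
    d = x - y
    df = n - 1
    sd = float(d.std(ddof=1))
    mean = float(d.mean())
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, mean), df, 0.0
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return t, df, p
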