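"""Codon-level comparison of two same-length coding sequences.

Residue numbering is 1-based from the initiator methionine. The
standard nuclear genetic code is hard-coded; alternative codes are out
of scope.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Tuple

from .errors import ConfigError

CODON_TABLE: Dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")


def translate_codon(codon: str) -> str:
    codon = codon.upper().replace("U", "T")
    try:
        return CODON_TABLE[codon]
    except KeyError as exc:
        raise ConfigError(f"invalid codon '{codon}'") from exc


@dataclass(frozen=True)
class CodonDiff:
    residue: int  # 1-based residue number
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    klass: str  # silent | missense | nonsense


def _validate_cds(cds: str, name: str) -> str:
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ConfigError(f"{name}: length {len(cds)} not a multiple of 3")
    if not cds.startswith("ATG"):
        raise ConfigError(f"{name}: does not start with ATG")
    if cds[-3:] not in STOP_CODONS:
        raise ConfigError(f"{name}: does not end at a stop codon")
    return cds


def compare_orfs(
    cds_a: str, cds_b: str
) -> Tuple[List[CodonDiff], Dict[str, int]]:
    """Per-codon diff of two equal-length ORFs plus class counts.

    Class is silent when the residues are identical, nonsense when the
    alternate residue is a stop, missense otherwise.
    """
    a = _validate_cds(cds_a, "cds_a")
    b = _validate_cds(cds_b, "cds_b")
    if len(a) != len(b):
        raise ConfigError(f"CDS lengths differ: {len(a)} vs {len(b)}")
    diffs: List[CodonDiff] = []
    for idx in range(0, len(a), 3):
        ca, cb = a[idx : idx + 3], b[idx : idx + 3]
        if ca == cb:
            continue
        aa_a, aa_b = translate_codon(ca), translate_codon(cb)
        if aa_a == aa_b:
            klass = "silent"
        elif aa_b == "*":
            klass = "nonsense"
        else:
            klass = "missense"
        diffs.append(
            CodonDiff(
                residue=idx // 3 + 1,
                ref_codon=ca,
                alt_codon=cb,
                ref_aa=aa_a,
                alt_aa=aa_b,
                klass=klass,
            )
        )
    summary = Counter(d.klass for d in diffs)
    return diffs, {
        "n_silent": summary.get("silent", 0),
        "n_missense": summary.get("missense", 0),
        "n_nonsense": summary.get("nonsense", 0),
    }


def count_codon_repeat(cds: str, motif: str, start_residue: int) -> int:
    """Length of the maximal in-frame run of ``motif`` from ``start_residue``."""
    cds = cds.upper().replace("U", "T")
    motif = motif.upper().replace("U", "T")
    if len(motif) != 3:
        raise ConfigError("motif must be a trinucleotide")
    n_residues = len(cds) // 3
    if not (1 <= start_residue <= n_residues):
        raise ConfigError(
            f"start_residue {start_residue} outside 1..{n_residues}"
        )
    i = (start_residue - 1) * 3
    run = 0
    while i + 3 <= len(cds) and cds[i : i + 3] == motif:
        run += 1
        i += 3
    return run
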