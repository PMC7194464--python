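"""Plain-text sequence and annotation I/O shared across stages.

FASTA/FASTQ reading goes through Biopython; GFF3 reading goes through
gffutils (in-memory db). Writers emit the minimal dialects the pipeline
needs and are deterministic byte-for-byte for fixed inputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import gffutils
from Bio import SeqIO

from .errors import FormatError

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str) -> Dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict."""
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path: str, records: Iterable[Tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str) -> List[Tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fastq")]


def write_fastq(path: str, records: Iterable[Tuple[str, str]], qual_char: str = "I") -> None:
    """Write FASTQ with a constant Phred+33 quality character."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual_char * len(seq)}\n")


@dataclass(frozen=True)
class GffFeature:
    """One GFF3 line; coordinates 1-based inclusive as in the format."""

    seqid: str
    source: str
    ftype: str
    start: int
    end: int
    strand: str
    attributes: Tuple[Tuple[str, str], ...] = field(default_factory=tuple)
    score: str = "."
    phase: str = "."

    @property
    def attr_dict(self) -> Dict[str, str]:
        return dict(self.attributes)


def write_gff3(path: str, features: Sequence[GffFeature]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes)
            fh.write(
                f"{f.seqid}\t{f.source}\t{f.ftype}\t{f.start}\t{f.end}\t"
                f"{f.score}\t{f.strand}\t{f.phase}\t{attrs}\n"
            )


def load_gff3(path: str) -> gffutils.FeatureDB:
    """Load a GFF3 file into an in-memory gffutils database."""
    try:
        return gffutils.create_db(
            path, ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:  # pragma: no cover - gffutils raises various types
        raise FormatError(f"cannot parse GFF3 {path}: {exc}") from exc


def gene_intervals(db: gffutils.FeatureDB) -> List[Tuple[str, str, int, int, str]]:
    """``(gene_id, seqid, start1, end1, strand)`` for every gene feature."""
    out = []
    for gene in db.features_of_type("gene"):
        out.append((gene.id, gene.seqid, gene.start, gene.end, gene.strand))
    return out


def extract_transcripts(db: gffutils.FeatureDB, genome: Dict[str, str]) -> Dict[str, str]:
    """Spliced transcript sequences keyed by mRNA id.

    Exon children are concatenated in genomic order; minus-strand
    transcripts are reverse complemented.
    """
    out: Dict[str, str] = {}
    for mrna in db.features_of_type("mRNA"):
        exons = sorted(db.children(mrna, featuretype="exon"), key=lambda e: e.start)
        if not exons:
            continue
        seq = "".join(genome[e.seqid][e.start - 1 : e.end] for e in exons)
        if mrna.strand == "-":
            seq = revcomp(seq)
        out[mrna.id] = seq
    return out


def transcript_exons(db: gffutils.FeatureDB) -> Dict[str, List[Tuple[str, int, int, str]]]:
    """Exon intervals ``(seqid, start1, end1, strand)`` per mRNA id."""
    out: Dict[str, List[Tuple[str, int, int, str]]] = {}
    for mrna in db.features_of_type("mRNA"):
        exons = sorted(db.children(mrna, featuretype="exon"), key=lambda e: e.start)
        out[mrna.id] = [(e.seqid, e.start, e.end, e.strand) for e in exons]
    return out


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
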