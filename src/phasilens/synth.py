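"""Synthetic genome / sRNA / RNA-seq generator with truth tables.

The generated chromosome carries two implanted loci:

- a hairpin locus ``X + loop + revcomp(X)`` with ``X = flank + mature``,
  so that base-pair maximization recovers a full stem in which the
  mature and star species form a duplex with 2-nt 3' overhangs on both
  strands;
- a three-exon target gene whose last exon contains a near-complementary
  site for the mature sequence (mismatches implanted opposite miRNA
  positions 1 and 21), sliced opposite miRNA nucleotide 10, with phased
  21-nt sense/antisense siRNA cycles downstream of the slice site.

All randomness flows through per-operation streams derived from
``(seed, operation-name)`` so each stage is independently reproducible,
and outputs are byte-identical for a fixed (config, seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .errors import ConfigError
from .ioutils import GffFeature, ensure_dir, revcomp, write_fasta, write_fastq, write_gff3
from .preprocess import DEFAULT_ADAPTER
from .slicing import score_duplex

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

MIR_GENE_ID = "MIR_LOCUS"
MIR_TX_ID = "MIR_T1"
TARGET_GENE_ID = "TARGET_GENE"
TARGET_TX_ID = "TARGET_T1"

READ_LABELS = (
    "mirna",
    "mirna_tailed",
    "mirna_star",
    "phased_sense",
    "phased_antisense",
    "noise",
)


def _rng(seed: int, name: str) -> np.random.Generator:
    """Independent per-operation stream: seeded by (seed, crc32(name))."""
    return np.random.default_rng([seed & 0xFFFFFFFF, zlib.crc32(name.encode())])


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults build the standard fixture."""

    chrom: str = "chr1"
    genome_length: int = 6500
    period: int = 21
    n_cycles: int = 8
    mature_length: int = 21
    mir_locus_start: int = 500  # 0-based genomic start of the hairpin
    hairpin_flank: int = 20
    # The loop must not end in A: otherwise the antisense of the 3' arm
    # plus the loop end spells mature+T and a mono-U tail would be
    # genome-templated on the minus strand.
    hairpin_loop: str = "AAAAAAAC"
    pri_pad: int = 20  # pri transcript extends this far past the hairpin
    gene_start: int = 2000
    exon_lengths: Tuple[int, int, int] = (300, 200, 450)
    intron_lengths: Tuple[int, ...] = (1113, 1340)
    site_offset_in_last_exon: int = 50
    p_mono_U: float = 0.93
    sense_fraction: float = 0.5
    depth: int = 400
    noise_fraction: float = 0.15
    mirna_fraction: float = 0.25
    mirna_21_share: float = 0.6
    mirna_22_share: float = 0.2
    noise_length_range: Tuple[int, int] = (18, 26)
    rnaseq_depth: int = 300
    rnaseq_read_length: int = 100
    expression: Tuple[Tuple[str, float], ...] = (
        (TARGET_TX_ID, 1.0),
        (MIR_TX_ID, 0.4),
    )
    adapter: str = DEFAULT_ADAPTER
    site_penalty_max: float = 7.0

    def validate(self) -> None:
        if self.n_cycles < 1:
            raise ConfigError("n_cycles must be >= 1")
        if self.period < 18:
            raise ConfigError("period must be >= 18")
        if not (0.0 <= self.p_mono_U <= 1.0):
            raise ConfigError("p_mono_U must be in [0, 1]")
        if len(self.exon_lengths) != len(self.intron_lengths) + 1:
            raise ConfigError("need len(exon_lengths) == len(intron_lengths) + 1")
        if not (0.0 <= self.noise_fraction <= 1.0):
            raise ConfigError("noise_fraction must be in [0, 1]")


@dataclass
class TruthSet:
    """Synthetic genome plus the generative parameters behind it."""

    config: SynthConfig
    seed: int
    genome: Dict[str, str]
    mature_seq: str
    star_seq: str
    hairpin: Tuple[int, int]  # 0-based half-open genomic interval
    mature_arm: Tuple[int, int]
    star_arm: Tuple[int, int]
    pri_interval: Tuple[int, int]
    gene_interval: Tuple[int, int]
    exons: List[Tuple[int, int]]  # genomic, 0-based half-open
    transcript: str
    site: Tuple[int, int]  # 1-based inclusive transcript interval
    slice_position: int  # 1-based transcript coordinate

    @property
    def phase_positions(self) -> List[int]:
        p, k = self.config.period, self.config.n_cycles
        return [self.slice_position + p * i for i in range(k)]

    def tx_to_genome(self, tx_pos0: int) -> int:
        """Map a 0-based transcript coordinate to a 0-based genome coordinate."""
        off = 0
        for gs, ge in self.exons:
            if tx_pos0 < off + (ge - gs):
                return gs + (tx_pos0 - off)
            off += ge - gs
        raise ConfigError(f"transcript position {tx_pos0} out of range")

    def validate(self) -> None:
        cfg = self.config
        chrom = self.genome[cfg.chrom]
        for name, (lo, hi) in (
            ("hairpin", self.hairpin),
            ("mature_arm", self.mature_arm),
            ("star_arm", self.star_arm),
            ("gene", self.gene_interval),
            ("pri", self.pri_interval),
        ):
            if not (0 <= lo < hi <= len(chrom)):
                raise ConfigError(f"{name} interval {lo}..{hi} outside genome")
        hp = chrom[self.hairpin[0] : self.hairpin[1]]
        if self.mature_seq not in hp or self.star_seq not in hp:
            raise ConfigError("mature/star not substrings of the hairpin")
        s, e = self.site
        if self.slice_position != e - 9:
            raise ConfigError("slice_position must equal site_end - 9")
        window = self.transcript[s - 1 : e]
        penalty, _ = score_duplex(self.mature_seq, window)
        if penalty > cfg.site_penalty_max:
            raise ConfigError(
                f"target-site penalty {penalty} exceeds {cfg.site_penalty_max}"
            )


def _hairpin_geometry_ok(
    genome_arr: Sequence[str],
    hstart: int,
    hend: int,
    mature_local: Tuple[int, int],
    star_local: Tuple[int, int],
    pads: Tuple[int, ...] = (0, 20, 75),
    max_unpaired: int = 5,
    overhang: int = 2,
) -> bool:
    """Check that folding recovers the mature/star duplex geometry.

    Folds the hairpin with several flank paddings (annotation windows
    vary with cluster extents) and requires the duplex criteria to hold
    under each resulting pairing.
    """
    from .mirna import duplex_geometry, fold_window

    for pad in pads:
        ws = max(0, hstart - pad)
        we = min(len(genome_arr), hend + pad)
        seq = "".join(genome_arr[ws:we])
        partner: Dict[int, int] = {}
        for i, j in fold_window(seq):
            partner[i] = j
            partner[j] = i
        shift = hstart - ws
        geom = duplex_geometry(
            partner,
            (mature_local[0] + shift, mature_local[1] + shift),
            (star_local[0] + shift, star_local[1] + shift),
        )
        if geom is None:
            return False
        unpaired, ov_m, ov_s = geom
        if unpaired > max_unpaired or ov_m != overhang or ov_s != overhang:
            return False
    return True


def _mutate_nonpairing(rng_base: str, mirna_base: str) -> str:
    """A base that neither Watson-Crick pairs nor wobbles with ``mirna_base``."""
    wc = {"A": "T", "T": "A", "U": "A", "G": "C", "C": "G"}
    forbidden = {wc[mirna_base]}
    if mirna_base == "G":
        forbidden.add("T")
    elif mirna_base in ("T", "U"):
        forbidden.add("G")
    for b in "ACGT":
        if b not in forbidden and b != rng_base:
            return b
    raise AssertionError("unreachable")


def build_truth_set(
    config: Optional[SynthConfig] = None,
    seed: int = 42,
    outdir: Optional[str] = None,
) -> TruthSet:
    """Construct the synthetic genome and truth tables.

    When ``outdir`` is given, ``genome.fa``, ``loci.gff3`` and
    ``truth.tsv`` are written there.
    """
    cfg = config or SynthConfig()
    cfg.validate()
    rng = _rng(seed, "truth")

    genome_arr = list(_random_dna(rng, cfg.genome_length))

    # --- hairpin locus -------------------------------------------------
    # The mature/flank draw is retried until base-pair maximization of
    # the hairpin in its genomic context recovers the canonical
    # mature/star duplex (2-nt 3' overhangs, few unpaired bases) under
    # annotate-style padded windows; promiscuous folds (e.g. a mature 3'
    # end that re-pairs into the loop) are rejected.
    hstart = cfg.mir_locus_start
    for attempt in range(200):
        flank = _random_dna(rng, cfg.hairpin_flank)
        mature = _random_dna(rng, cfg.mature_length)
        x = flank + mature
        hairpin = x + cfg.hairpin_loop + revcomp(x)
        hend = hstart + len(hairpin)
        trial = list(genome_arr)
        trial[hstart:hend] = list(hairpin)
        m_local = (cfg.hairpin_flank, cfg.hairpin_flank + cfg.mature_length)
        s_local_start = len(hairpin) - (cfg.mature_length - 2) - cfg.hairpin_flank
        s_local = (s_local_start, s_local_start + cfg.mature_length)
        if _hairpin_geometry_ok(trial, hstart, hend, m_local, s_local):
            break
    else:  # pragma: no cover - would indicate a broken generator
        raise ConfigError("could not draw a foldable hairpin in 200 attempts")
    genome_arr[hstart:hend] = list(hairpin)
    mature_arm = (hstart + cfg.hairpin_flank, hstart + cfg.hairpin_flank + cfg.mature_length)
    # star pairs mature[0..L-3] with a 2-nt 3' overhang on both strands
    star_local = len(hairpin) - (cfg.mature_length - 2) - cfg.hairpin_flank
    star_arm = (hstart + star_local, hstart + star_local + cfg.mature_length)
    star_seq = hairpin[star_local : star_local + cfg.mature_length]
    pri_interval = (max(0, hstart - cfg.pri_pad), min(cfg.genome_length, hend + cfg.pri_pad))

    # --- target gene ---------------------------------------------------
    exons: List[Tuple[int, int]] = []
    pos = cfg.gene_start
    for i, elen in enumerate(cfg.exon_lengths):
        exons.append((pos, pos + elen))
        pos += elen
        if i < len(cfg.intron_lengths):
            ilen = cfg.intron_lengths[i]
            # canonical GT..AG donor/acceptor dinucleotides
            genome_arr[pos] = "G"
            genome_arr[pos + 1] = "T"
            genome_arr[pos + ilen - 2] = "A"
            genome_arr[pos + ilen - 1] = "G"
            pos += ilen
    gene_interval = (cfg.gene_start, pos)
    if pos > cfg.genome_length:
        raise ConfigError("gene exceeds genome_length; enlarge the genome")

    # implant the near-complementary site in the last exon
    site_seq = list(revcomp(mature))
    # mismatches opposite miRNA positions 1 (site 3' end) and 21 (site 5' end)
    site_seq[-1] = _mutate_nonpairing(site_seq[-1], mature[0])
    site_seq[0] = _mutate_nonpairing(site_seq[0], mature[-1])
    last_exon = exons[-1]
    g_site_start = last_exon[0] + cfg.site_offset_in_last_exon
    genome_arr[g_site_start : g_site_start + len(site_seq)] = site_seq

    genome = {cfg.chrom: "".join(genome_arr)}
    transcript = "".join(
        genome[cfg.chrom][gs:ge] for gs, ge in exons
    )
    tx_site_start = (
        sum(ge - gs for gs, ge in exons[:-1]) + cfg.site_offset_in_last_exon + 1
    )
    site = (tx_site_start, tx_site_start + cfg.mature_length - 1)
    slice_position = site[1] - 9

    truth = TruthSet(
        config=cfg,
        seed=seed,
        genome=genome,
        mature_seq=mature,
        star_seq=star_seq,
        hairpin=(hstart, hend),
        mature_arm=mature_arm,
        star_arm=star_arm,
        pri_interval=pri_interval,
        gene_interval=gene_interval,
        exons=exons,
        transcript=transcript,
        site=site,
        slice_position=slice_position,
    )
    truth.validate()
    if outdir is not None:
        write_truth_files(truth, outdir)
    return truth


def truth_gff_features(truth: TruthSet) -> List[GffFeature]:
    cfg = truth.config
    src = "phasilens-synth"
    feats = [
        GffFeature(cfg.chrom, src, "gene", truth.pri_interval[0] + 1,
                   truth.pri_interval[1], "+", (("ID", MIR_GENE_ID),)),
        GffFeature(cfg.chrom, src, "mRNA", truth.pri_interval[0] + 1,
                   truth.pri_interval[1], "+",
                   (("ID", MIR_TX_ID), ("Parent", MIR_GENE_ID))),
        GffFeature(cfg.chrom, src, "exon", truth.pri_interval[0] + 1,
                   truth.pri_interval[1], "+",
                   (("ID", f"{MIR_TX_ID}.exon1"), ("Parent", MIR_TX_ID))),
        GffFeature(cfg.chrom, src, "miRNA", truth.mature_arm[0] + 1,
                   truth.mature_arm[1], "+",
                   (("ID", "MIR_MATURE"), ("Parent", MIR_GENE_ID),
                    ("arm", "mature"))),
        GffFeature(cfg.chrom, src, "miRNA", truth.star_arm[0] + 1,
                   truth.star_arm[1], "+",
                   (("ID", "MIR_STAR"), ("Parent", MIR_GENE_ID),
                    ("arm", "star"))),
        GffFeature(cfg.chrom, src, "gene", truth.gene_interval[0] + 1,
                   truth.gene_interval[1], "+", (("ID", TARGET_GENE_ID),)),
        GffFeature(cfg.chrom, src, "mRNA", truth.gene_interval[0] + 1,
                   truth.gene_interval[1], "+",
                   (("ID", TARGET_TX_ID), ("Parent", TARGET_GENE_ID))),
    ]
    for i, (gs, ge) in enumerate(truth.exons, start=1):
        feats.append(
            GffFeature(cfg.chrom, src, "exon", gs + 1, ge, "+",
                       (("ID", f"{TARGET_TX_ID}.exon{i}"),
                        ("Parent", TARGET_TX_ID)))
        )
    return feats


def write_truth_files(truth: TruthSet, outdir: str) -> Dict[str, str]:
    ensure_dir(outdir)
    cfg = truth.config
    paths = {
        "genome": f"{outdir}/genome.fa",
        "gff": f"{outdir}/loci.gff3",
        "truth": f"{outdir}/truth.tsv",
    }
    write_fasta(paths["genome"], sorted(truth.genome.items()))
    write_gff3(paths["gff"], truth_gff_features(truth))
    rows = [
        ("seed", truth.seed),
        ("chrom", cfg.chrom),
        ("genome_length", cfg.genome_length),
        ("period", cfg.period),
        ("n_cycles", cfg.n_cycles),
        ("p_mono_U", cfg.p_mono_U),
        ("mature_seq", truth.mature_seq),
        ("star_seq", truth.star_seq),
        ("hairpin_start", truth.hairpin[0] + 1),
        ("hairpin_end", truth.hairpin[1]),
        ("mature_start", truth.mature_arm[0] + 1),
        ("mature_end", truth.mature_arm[1]),
        ("star_start", truth.star_arm[0] + 1),
        ("star_end", truth.star_arm[1]),
        ("gene_start", truth.gene_interval[0] + 1),
        ("gene_end", truth.gene_interval[1]),
        ("transcript_id", TARGET_TX_ID),
        ("site_start", truth.site[0]),
        ("site_end", truth.site[1]),
        ("slice_position", truth.slice_position),
        ("phase_positions", ",".join(map(str, truth.phase_positions))),
        ("intron_lengths", ",".join(map(str, cfg.intron_lengths))),
    ]
    with open(paths["truth"], "w") as fh:
        fh.write("key\tvalue\n")
        for k, v in rows:
            fh.write(f"{k}\t{v}\n")
    return paths


def read_truth_tsv(path: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            k, v = line.rstrip("\n").split("\t", 1)
            out[k] = v
    return out


@dataclass(frozen=True)
class LabeledRead:
    """One simulated sRNA read with its generative label."""

    read_id: str
    sequence: str
    label: str
    seqid: str
    start: int  # 1-based leftmost genomic base
    end: int  # 1-based rightmost genomic base
    strand: str


def _allocate(total: float, weights: Sequence[float], minimum: int = 0) -> List[int]:
    wsum = sum(weights)
    counts = [max(minimum, int(total * w / wsum)) for w in weights]
    short = int(total) - sum(counts)
    if short > 0:
        counts[0] += short
    return counts


def simulate_srna_library(
    truth: TruthSet,
    depth: Optional[int] = None,
    seed: Optional[int] = None,
    out_fastq: Optional[str] = None,
    out_labels: Optional[str] = None,
    with_adapter: bool = True,
) -> List[LabeledRead]:
    """Simulate an sRNA library over the truth loci.

    Emits (deterministically for fixed inputs): mature 21-nt reads, 22-nt
    variants each mono-uridylated with probability ``p_mono_U``, star
    reads, phased sense/antisense 21-nt cycles downstream of the slice
    site (sense counts decay geometrically so the slice remnant is the
    unique maximum), and uniform background noise. Reads are written as
    FASTQ (constant quality, adapter appended when ``with_adapter``)
    plus a label TSV.
    """
    cfg = truth.config
    depth = cfg.depth if depth is None else depth
    seed = truth.seed if seed is None else seed
    if depth <= 0:
        raise ConfigError("depth must be > 0")
    rng = _rng(seed, "srna")
    chrom = truth.genome[cfg.chrom]
    p = cfg.period

    n_noise = int(round(depth * cfg.noise_fraction))
    n_signal = depth - n_noise
    n_mir = int(round(n_signal * cfg.mirna_fraction))
    n21 = int(round(n_mir * cfg.mirna_21_share))
    n22 = int(round(n_mir * cfg.mirna_22_share))
    n_star = max(0, n_mir - n21 - n22)
    n_phased = max(0, n_signal - n_mir)
    n_sense = int(round(n_phased * cfg.sense_fraction))
    n_anti = n_phased - n_sense
    sense_counts = _allocate(
        n_sense, [0.5 ** k for k in range(cfg.n_cycles)], minimum=1
    )
    anti_counts = _allocate(n_anti, [1.0] * cfg.n_cycles, minimum=1)

    reads: List[LabeledRead] = []
    counter = [0]

    def emit(seq: str, label: str, start0: int, strand: str, n: int = 1) -> None:
        for _ in range(n):
            counter[0] += 1
            reads.append(
                LabeledRead(
                    read_id=f"r{counter[0]:06d}",
                    sequence=seq,
                    label=label,
                    seqid=cfg.chrom,
                    start=start0 + 1,
                    end=start0 + len(seq),
                    strand=strand,
                )
            )

    m0, m1 = truth.mature_arm
    mature = truth.mature_seq
    emit(mature, "mirna", m0, "+", n21)
    tailed_draws = rng.random(n22) < cfg.p_mono_U
    for tailed in tailed_draws:
        if tailed:
            emit(mature + "T", "mirna_tailed", m0, "+")
        else:
            emit(mature + chrom[m1], "mirna", m0, "+")
    emit(truth.star_seq, "mirna_star", truth.star_arm[0], "+", n_star)

    s = truth.slice_position  # 1-based transcript coordinate
    tx = truth.transcript
    for k in range(cfg.n_cycles):
        tx_start0 = s - 1 + p * k
        seq = tx[tx_start0 : tx_start0 + p]
        emit(seq, "phased_sense", truth.tx_to_genome(tx_start0), "+", sense_counts[k])
        a_start0 = s - 3 + p * k  # antisense partner: 2-nt 3' overhang
        aseq = revcomp(tx[a_start0 : a_start0 + p])
        emit(
            aseq, "phased_antisense", truth.tx_to_genome(a_start0), "-",
            anti_counts[k],
        )

    lo, hi = cfg.noise_length_range
    for _ in range(n_noise):
        length = int(rng.integers(lo, hi + 1))
        start0 = int(rng.integers(0, len(chrom) - length))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = chrom[start0 : start0 + length]
        if strand == "-":
            seq = revcomp(seq)
        emit(seq, "noise", start0, strand)

    if out_fastq is not None:
        adapter = cfg.adapter if with_adapter else ""
        write_fastq(
            out_fastq, [(r.read_id, r.sequence + adapter) for r in reads]
        )
    if out_labels is not None:
        with open(out_labels, "w") as fh:
            fh.write("read_id\tlabel\tseqid\tstart\tend\tstrand\tsequence\n")
            for r in reads:
                fh.write(
                    f"{r.read_id}\t{r.label}\t{r.seqid}\t{r.start}\t{r.end}\t"
                    f"{r.strand}\t{r.sequence}\n"
                )
    return reads


def _transcript_cigar(
    exons: Sequence[Tuple[int, int]], tx_start0: int, read_len: int
) -> Tuple[int, List[Tuple[int, int]]]:
    """Project a transcript interval onto the genome as (pos0, cigartuples)."""
    cigar: List[Tuple[int, int]] = []
    remaining = read_len
    offset = 0
    pos0 = None
    for i, (gs, ge) in enumerate(exons):
        elen = ge - gs
        if tx_start0 >= offset + elen:
            offset += elen
            continue
        within = tx_start0 - offset if pos0 is None else 0
        if pos0 is None:
            pos0 = gs + within
        take = min(remaining, elen - within)
        cigar.append((0, take))  # M
        remaining -= take
        if remaining == 0:
            break
        nxt = exons[i + 1]
        cigar.append((3, nxt[0] - ge))  # N
        offset += elen
        tx_start0 = offset  # continue at start of next exon
    if remaining != 0 or pos0 is None:
        raise ConfigError("read extends past transcript end")
    return pos0, cigar


def simulate_rnaseq_alignments(
    truth: TruthSet,
    depth: Optional[int] = None,
    seed: Optional[int] = None,
    out_sam: Optional[str] = None,
) -> str:
    """Write spliced single-end RNA-seq alignments as SAM.

    Per-transcript read totals are proportional to the configured
    expression weights; junction-spanning reads carry N operations whose
    lengths equal the truth intron lengths. Three reads per junction are
    forced so splice evidence is always present.
    """
    cfg = truth.config
    depth = cfg.rnaseq_depth if depth is None else depth
    seed = truth.seed if seed is None else seed
    if depth <= 0:
        raise ConfigError("depth must be > 0")
    if out_sam is None:
        raise ConfigError("out_sam path required")
    rng = _rng(seed, "rnaseq")

    models: Dict[str, Tuple[List[Tuple[int, int]], str]] = {
        TARGET_TX_ID: (list(truth.exons), truth.transcript),
        MIR_TX_ID: (
            [truth.pri_interval],
            truth.genome[cfg.chrom][truth.pri_interval[0] : truth.pri_interval[1]],
        ),
    }
    expr = dict(cfg.expression)
    wsum = sum(expr.values())
    counts = {tx: int(round(depth * w / wsum)) for tx, w in expr.items()}

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": cfg.chrom, "LN": cfg.genome_length}],
    }
    with pysam.AlignmentFile(out_sam, "w", header=header) as out:
        idx = 0
        for tx_id in sorted(counts):
            exons, tx_seq = models[tx_id]
            rl = min(cfg.rnaseq_read_length, len(tx_seq))
            starts: List[int] = []
            # forced junction coverage: reads centered on each exon boundary
            boundary = 0
            for gs, ge in exons[:-1]:
                boundary += ge - gs
                forced = max(0, min(boundary - rl // 2, len(tx_seq) - rl))
                starts.extend([forced] * 3)
            n_random = max(0, counts[tx_id] - len(starts))
            starts.extend(
                int(v) for v in rng.integers(0, len(tx_seq) - rl + 1, size=n_random)
            )
            for t0 in starts:
                pos0, cigar = _transcript_cigar(exons, t0, rl)
                idx += 1
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = f"rna{idx:06d}"
                rec.flag = 0
                rec.reference_id = 0
                rec.reference_start = pos0
                rec.mapping_quality = 60
                rec.cigartuples = cigar
                rec.query_sequence = tx_seq[t0 : t0 + rl]
                rec.query_qualities = pysam.qualitystring_to_array("I" * rl)
                out.write(rec)
    return out_sam


def clean_config(**overrides) -> SynthConfig:
    """A noise-free configuration, handy for exact-recovery tests."""
    return replace(SynthConfig(), noise_fraction=0.0, **overrides)
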