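"""End-to-end orchestration: synth -> preprocess -> mirna -> slice ->
phase -> tails -> quant, with a machine-readable summary and manifest.

Each stage writes into its own subdirectory of the run directory and
consumes only files produced by earlier stages; the run is
deterministic (byte-identical summary) for a fixed config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import os
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import mirna as mirna_mod
from . import phasing as phasing_mod
from . import preprocess as pre_mod
from . import quant as quant_mod
from . import slicing as slicing_mod
from . import synth as synth_mod
from . import tails as tails_mod
from .config import PipelineConfig
from .errors import PhasilensError
from .ioutils import (
    ensure_dir,
    extract_transcripts,
    gene_intervals,
    load_gff3,
    read_fasta,
    read_fastq,
    write_gff3,
    GffFeature,
)

log = logging.getLogger("phasilens")


def _stage_log(cfg: PipelineConfig, stage: str, msg: str) -> None:
    log.info("[%s] seed=%d params=%s %s", stage, cfg.seed, cfg.param_hash(), msg)


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def _synth_config(cfg: PipelineConfig) -> synth_mod.SynthConfig:
    return dataclasses.replace(
        synth_mod.SynthConfig(),
        period=cfg.period,
        n_cycles=cfg.n_cycles,
        p_mono_U=cfg.p_mono_U,
        depth=cfg.depth,
        noise_fraction=cfg.noise_fraction,
        intron_lengths=tuple(cfg.intron_lengths),
        rnaseq_depth=cfg.rnaseq_depth,
        adapter=cfg.adapter,
    )


def run_all(cfg: PipelineConfig, outdir: str) -> Dict[str, object]:
    """Execute every stage on the bundled synthetic fixture.

    Returns the summary dict; also writes ``summary.tsv`` and
    ``manifest.tsv`` under ``outdir``.
    """
    cfg.validate()
    ensure_dir(outdir)
    summary: Dict[str, object] = {}
    artifacts: List[str] = []

    # ---- synth -------------------------------------------------------
    synth_dir = ensure_dir(os.path.join(outdir, "synth"))
    truth = synth_mod.build_truth_set(_synth_config(cfg), seed=cfg.seed, outdir=synth_dir)
    fastq = os.path.join(synth_dir, "reads.fastq")
    labels = os.path.join(synth_dir, "read_labels.tsv")
    reads = synth_mod.simulate_srna_library(
        truth, seed=cfg.seed, out_fastq=fastq, out_labels=labels
    )
    sam_path = os.path.join(synth_dir, "rnaseq.sam")
    synth_mod.simulate_rnaseq_alignments(truth, seed=cfg.seed, out_sam=sam_path)
    artifacts += [
        os.path.join(synth_dir, f)
        for f in ("genome.fa", "loci.gff3", "truth.tsv", "reads.fastq",
                  "read_labels.tsv", "rnaseq.sam")
    ]
    _stage_log(cfg, "synth", f"reads={len(reads)}")
    summary["n_reads_simulated"] = len(reads)

    # ---- preprocess --------------------------------------------------
    pre_dir = ensure_dir(os.path.join(outdir, "preprocess"))
    raw = [seq for _, seq in read_fastq(fastq)]
    result = pre_mod.preprocess_library(raw, adapter=cfg.adapter, min_len=cfg.min_len)
    records = result["records"]
    collapsed_fa = os.path.join(pre_dir, "collapsed.fa")
    pre_mod.write_collapsed_fasta(collapsed_fa, records)
    pre_mod.abundance_table(records).to_csv(
        os.path.join(pre_dir, "abundance.tsv"), sep="\t", index=False
    )
    artifacts += [collapsed_fa, os.path.join(pre_dir, "abundance.tsv")]
    summary["n_reads_kept"] = result["n_kept"]
    summary["n_unique_reads"] = len(records)
    _stage_log(cfg, "preprocess", f"kept={result['n_kept']} unique={len(records)}")
    if not records:
        log.warning("[preprocess] no reads survived trimming/filtering; "
                    "downstream sRNA tables will be empty")

    genome = read_fasta(os.path.join(synth_dir, "genome.fa"))
    db = load_gff3(os.path.join(synth_dir, "loci.gff3"))
    transcripts = extract_transcripts(db, genome)

    # ---- mirna -------------------------------------------------------
    mirna_dir = ensure_dir(os.path.join(outdir, "mirna"))
    candidates, _ = mirna_mod.annotate_mirna(
        records, genome,
        mincov=cfg.mincov, foldsize=cfg.foldsize, max_mismatch=cfg.max_mismatch,
    )
    accepted = [c for c in candidates if c.accepted]
    _write_mirna_outputs(mirna_dir, candidates, genome, artifacts)
    summary["n_mirna_candidates"] = len(candidates)
    summary["n_mirna_accepted"] = len(accepted)
    mature_seq = accepted[0].mature_seq if accepted else ""
    summary["mature_seq"] = mature_seq
    _stage_log(cfg, "mirna", f"candidates={len(candidates)} accepted={len(accepted)}")

    # ---- slicing -----------------------------------------------------
    slice_dir = ensure_dir(os.path.join(outdir, "slice"))
    tx_alignments = (
        mirna_mod.map_reads(records, transcripts, max_mismatch=cfg.max_mismatch)
        if records else []
    )
    all_sites: List[slicing_mod.TargetAlignment] = []
    if mature_seq:
        for tx_id in sorted(transcripts):
            all_sites.extend(
                slicing_mod.detect_slice_sites(
                    mature_seq, tx_id, transcripts[tx_id], tx_alignments,
                    penalty_max=cfg.penalty_max, category_max=cfg.category_max,
                )
            )
        all_sites.sort(key=lambda h: (h.category, h.penalty, h.transcript_id))
    _write_slice_outputs(slice_dir, all_sites, transcripts, tx_alignments, artifacts)
    summary["n_slice_sites"] = len(all_sites)
    if all_sites:
        best = all_sites[0]
        summary["best_site_transcript"] = best.transcript_id
        summary["best_site_slice_position"] = best.slice_position
        summary["best_site_category"] = best.category
        summary["best_site_penalty"] = best.penalty
    else:
        summary["best_site_transcript"] = ""
        summary["best_site_slice_position"] = -1
        summary["best_site_category"] = -1
        summary["best_site_penalty"] = float("nan")
    _stage_log(cfg, "slice", f"sites={len(all_sites)}")

    # ---- phasing -----------------------------------------------------
    phase_dir = ensure_dir(os.path.join(outdir, "phase"))
    anchors_by_tx: Dict[str, List[int]] = {}
    for site in all_sites:
        anchors_by_tx.setdefault(site.transcript_id, []).append(site.slice_position)
    best_report: Optional[phasing_mod.PhaseReport] = None
    all_reports: List[phasing_mod.PhaseReport] = []
    for tx_id in sorted(anchors_by_tx):
        reports = phasing_mod.call_phas(
            tx_id, tx_alignments, anchors_by_tx[tx_id],
            score_min=cfg.score_min, period=cfg.period,
            window_cycles=cfg.window_cycles,
        )
        all_reports.extend(reports)
        for rep in reports:
            if rep.best and (best_report is None or rep.score > best_report.score):
                best_report = rep
    _write_phase_outputs(phase_dir, all_reports, transcripts, artifacts)
    if best_report is not None:
        summary["phase_transcript"] = best_report.transcript_id
        summary["phase_anchor"] = best_report.anchor
        summary["phase_k"] = best_report.stats.k
        summary["phase_P"] = best_report.stats.P
        summary["phase_U"] = best_report.stats.U
        summary["phase_score"] = best_report.stats.score
        summary["phase_pass"] = int(best_report.passed)
    else:
        summary["phase_transcript"] = ""
        summary["phase_anchor"] = -1
        summary["phase_k"] = 0
        summary["phase_P"] = 0.0
        summary["phase_U"] = 0.0
        summary["phase_score"] = 0.0
        summary["phase_pass"] = 0
    _stage_log(cfg, "phase", f"best_score={summary['phase_score']:.3f}"
               if best_report else "no anchors")

    # ---- tails -------------------------------------------------------
    tails_dir = ensure_dir(os.path.join(outdir, "tails"))
    locus = None
    if accepted:
        locus = (accepted[0].seqid, accepted[0].window[0], accepted[0].window[1])
    calls, unanchored, report = tails_mod.run_tails(records, genome, locus=locus)
    report.to_csv(os.path.join(tails_dir, "tail_report.tsv"), sep="\t", index=False)
    with open(os.path.join(tails_dir, "tail_calls.tsv"), "w") as fh:
        fh.write("sequence\tcount\tclass\ttemplated_prefix_len\ttail\tseqid\tstrand\n")
        for c in sorted(calls, key=lambda c: (-c.read.count, c.read.sequence)):
            fh.write(
                f"{c.read.sequence}\t{c.read.count}\t{c.klass}\t"
                f"{c.templated_prefix_len}\t{c.tail}\t{c.anchor.seqid}\t{c.anchor.strand}\n"
            )
    artifacts += [os.path.join(tails_dir, "tail_report.tsv"),
                  os.path.join(tails_dir, "tail_calls.tsv")]
    mono_u_22 = float("nan")
    if len(report):
        row = report[report["length"] == 22]
        if len(row):
            mono_u_22 = float(row["frac_mono_U"].iloc[0])
    summary["tail_mono_u_fraction_22nt"] = mono_u_22
    summary["n_unanchored_reads"] = len(unanchored)
    _stage_log(cfg, "tails", f"calls={len(calls)} unanchored={len(unanchored)}")

    # ---- quant -------------------------------------------------------
    quant_dir = ensure_dir(os.path.join(outdir, "quant"))
    loci = [
        (gid, sid, start, end)
        for gid, sid, start, end, _ in sorted(gene_intervals(db))
    ]
    expr = quant_mod.count_locus_reads(sam_path, loci)
    with open(os.path.join(quant_dir, "expr.tsv"), "w") as fh:
        fh.write(quant_mod.EXPR_HEADER_NOTE + "\n")
        expr.to_csv(fh, sep="\t", index=False)
    junctions = quant_mod.extract_junctions(sam_path)
    junctions.to_csv(os.path.join(quant_dir, "junctions.tsv"), sep="\t", index=False)
    artifacts += [os.path.join(quant_dir, "expr.tsv"),
                  os.path.join(quant_dir, "junctions.tsv")]
    summary["junction_skip_lengths"] = ",".join(
        map(str, sorted(junctions["skip_length"].unique()))
    )
    for _, row in expr.iterrows():
        summary[f"count_{row['locus']}"] = int(row["count"])
    _stage_log(cfg, "quant", f"junctions={len(junctions)}")

    # ---- summary + manifest -----------------------------------------
    summary_path = os.path.join(outdir, "summary.tsv")
    with open(summary_path, "w") as fh:
        fh.write("key\tvalue\n")
        for k, v in summary.items():
            fh.write(f"{k}\t{_fmt(v)}\n")
    manifest_path = os.path.join(outdir, "manifest.tsv")
    with open(manifest_path, "w") as fh:
        fh.write("path\tbytes\tsha256\n")
        for path in sorted(artifacts + [summary_path]):
            rel = os.path.relpath(path, outdir)
            data = open(path, "rb").read()
            fh.write(f"{rel}\t{len(data)}\t{hashlib.sha256(data).hexdigest()}\n")
    return summary


def _write_mirna_outputs(outdir, candidates, genome, artifacts) -> None:
    report_path = os.path.join(outdir, "mirna_report.tsv")
    with open(report_path, "w") as fh:
        fh.write(
            "seqid\twindow_start\twindow_end\tverdict\treasons\tmature_seq\t"
            "star_seq\tdominance\tprecision\toverhang_3p\tn_window_reads\n"
        )
        for c in candidates:
            fh.write(
                f"{c.seqid}\t{c.window[0] + 1}\t{c.window[1]}\t"
                f"{'accept' if c.accepted else 'reject'}\t"
                f"{','.join(c.reasons) or '.'}\t{c.mature_seq or '.'}\t"
                f"{c.star_seq or '.'}\t{c.dominance:.4f}\t{c.precision:.4f}\t"
                f"{c.overhang_3p if c.overhang_3p is not None else '.'}\t"
                f"{c.n_window_reads}\n"
            )
    feats = []
    for i, c in enumerate(cand for cand in candidates if cand.accepted):
        locus_id = f"MIRNA{i + 1:03d}"
        feats.append(GffFeature(c.seqid, "phasilens", "gene",
                                c.window[0] + 1, c.window[1], c.strand or "+",
                                (("ID", locus_id),)))
        if c.mature_arm:
            feats.append(GffFeature(c.seqid, "phasilens", "miRNA",
                                    c.mature_arm[0] + 1, c.mature_arm[1],
                                    c.strand or "+",
                                    (("ID", f"{locus_id}.mature"),
                                     ("Parent", locus_id))))
        if c.star_arm:
            feats.append(GffFeature(c.seqid, "phasilens", "miRNA",
                                    c.star_arm[0] + 1, c.star_arm[1],
                                    c.strand or "+",
                                    (("ID", f"{locus_id}.star"),
                                     ("Parent", locus_id))))
    gff_path = os.path.join(outdir, "mirna_loci.gff3")
    write_gff3(gff_path, feats)
    db_path = os.path.join(outdir, "structures.txt")
    with open(db_path, "w") as fh:
        for c in candidates:
            if not c.accepted:
                continue
            seq = genome[c.seqid][c.window[0] : c.window[1]]
            fh.write(f"># {c.seqid}:{c.window[0] + 1}-{c.window[1]}\n{seq}\n")
            fh.write(mirna_mod.pairing_to_dotbracket(len(seq), c.pairing) + "\n")
    artifacts += [report_path, gff_path, db_path]


def _write_slice_outputs(outdir, sites, transcripts, tx_alignments, artifacts) -> None:
    sites_path = os.path.join(outdir, "sites.tsv")
    with open(sites_path, "w") as fh:
        fh.write(
            "transcript\tsite_start\tsite_end\tpenalty\tslice_position\t"
            "slice_count\tcategory\ttrace\n"
        )
        for h in sites:
            fh.write(
                f"{h.transcript_id}\t{h.start}\t{h.end}\t{h.penalty:.2f}\t"
                f"{h.slice_position}\t{h.slice_count:g}\t{h.category}\t{h.trace}\n"
            )
    artifacts.append(sites_path)
    for tx_id in sorted(transcripts):
        tplot = slicing_mod.build_tplot(tx_alignments, len(transcripts[tx_id]), tx_id)
        path = os.path.join(outdir, f"tplot_{tx_id}.tsv")
        with open(path, "w") as fh:
            fh.write("position\tcount\n")
            for pos, count in slicing_mod.tplot_table(tplot):
                fh.write(f"{pos}\t{count:g}\n")
        artifacts.append(path)


def _write_phase_outputs(outdir, reports, transcripts, artifacts) -> None:
    report_path = os.path.join(outdir, "phase_report.tsv")
    with open(report_path, "w") as fh:
        fh.write("transcript\tanchor\tperiod\tk\tP\tU\tscore\tpassed\tbest\n")
        for r in sorted(reports, key=lambda r: (-r.score, r.transcript_id, r.anchor)):
            fh.write(
                f"{r.transcript_id}\t{r.anchor}\t{r.period}\t{r.stats.k}\t"
                f"{r.stats.P:g}\t{r.stats.U:g}\t{r.stats.score:.4f}\t"
                f"{int(r.passed)}\t{int(r.best)}\n"
            )
    registers_path = os.path.join(outdir, "registers.tsv")
    with open(registers_path, "w") as fh:
        fh.write("transcript\tanchor\tsequence\tcount\tstart\tend\tstrand\t"
                 "register\tin_phase\td_label\n")
        for r in sorted(reports, key=lambda r: (-r.score, r.transcript_id, r.anchor)):
            if not r.best:
                continue
            for call in sorted(
                r.calls, key=lambda c: (c.alignment.start, c.alignment.strand)
            ):
                a = call.alignment
                fh.write(
                    f"{r.transcript_id}\t{r.anchor}\t{a.read.sequence}\t"
                    f"{a.read.count}\t{a.start + 1}\t{a.end}\t{a.strand}\t"
                    f"{call.register}\t{int(call.in_phase)}\t{call.d_label or '.'}\n"
                )
    align_path = os.path.join(outdir, "alignment.txt")
    with open(align_path, "w") as fh:
        for r in reports:
            if r.best and r.transcript_id in transcripts:
                fh.write(phasing_mod.render_alignment(transcripts[r.transcript_id], r))
    artifacts += [report_path, registers_path, align_path]
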