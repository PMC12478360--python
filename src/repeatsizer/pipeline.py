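"""End-to-end run: ingest -> QC -> repeat calling -> consensus -> reports.

One invocation processes one sample (one FASTQ, optionally with a BAM of
alignments to the flank-only locus reference), producing per-read QC and
call tables, a sample summary with modal repeat length(s), flank
consensus sequences with outlier flags, figures, and a JSON manifest that
echoes every parameter — in FASTQ-only mode the manifest and all tabular
outputs are a pure function of the serialized configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass
from typing import Optional

import pandas as pd
import yaml

from .alignqc import (anchor_flanks, filter_high_confidence, parse_alignment,
                      reorient)
from .caller import call_read, calls_to_dataframe, summarize_sample
from .consensus import extract_flank_windows, score_and_flag_outliers
from .locus import RepeatLocus
from .simulate import read_fastq
from .viz import build_waterfall, plot_outputs

logger = logging.getLogger("repeatsizer")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Fully determines one pipeline run (FASTQ-only mode is deterministic)."""

    fastq: str
    flanks_fasta: str
    outdir: str
    sample: str = "sample"
    motif: str = "GGGGCC"
    bam: Optional[str] = None
    min_mapq: int = 20
    require_flank_cov: int = 50
    max_gap: int = 24
    length_mode: str = "span_estimate"
    window: int = 200
    k_sd: float = 2.0
    bin_width: int = 5
    split_at: Optional[int] = None
    image_format: str = "svg"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_flanks(path: str) -> tuple[str, str]:
    """Read flank5 / flank3 records from a FASTA file."""
    from Bio import SeqIO

    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(path, "fasta")}
    missing = {"flank5", "flank3"} - set(records)
    if missing:
        raise ValueError(f"{path}: missing FASTA records {sorted(missing)}")
    return records["flank5"], records["flank3"]


def _qc_bam(config: RunConfig, locus: RepeatLocus,
            reads: dict[str, str]) -> tuple[dict[str, str], pd.DataFrame, int, int]:
    """Strand per confident read from BAM alignments; returns (strand map,
    QC table, n_filtered, n_unaligned)."""
    with pysam_open(config.bam) as bam:
        summaries = [s for s in (parse_alignment(rec) for rec in bam
                                 if not rec.is_secondary and not rec.is_unmapped)
                     if s is not None]
    flagged = filter_high_confidence(summaries, config.min_mapq,
                                     config.require_flank_cov,
                                     repeat_point=locus.repeat_point)
    strand: dict[str, str] = {}
    for s in flagged:
        if s.confident and s.is_primary and s.read_id in reads:
            strand[s.read_id] = s.strand
    aligned_ids = {s.read_id for s in flagged}
    n_unaligned = sum(1 for rid in reads if rid not in aligned_ids)
    n_filtered = sum(1 for rid in reads
                     if rid in aligned_ids and rid not in strand)
    table = pd.DataFrame([{
        "read_id": s.read_id, "mapq": s.mapq, "strand": s.strand,
        "aligned_ref_len": s.aligned_ref_len,
        "aligned_read_len": s.aligned_read_len,
        "n_mismatch": s.n_mismatch, "n_ins": s.n_ins, "n_del": s.n_del,
        "is_primary": s.is_primary, "confident": s.confident,
    } for s in flagged])
    return strand, table, n_filtered, n_unaligned


def pysam_open(path: str):
    import pysam

    mode = "rb" if path.endswith(".bam") else "r"
    return pysam.AlignmentFile(path, mode, check_sq=False)


def _qc_anchor(config: RunConfig, locus: RepeatLocus,
               reads: dict[str, str]) -> tuple[dict[str, str], pd.DataFrame, int]:
    """Alignment-free path: anchor both flanks in every read."""
    strand: dict[str, str] = {}
    rows = []
    n_no_anchor = 0
    for rid, seq in reads.items():
        anchor = anchor_flanks(seq, locus)
        if anchor is None:
            n_no_anchor += 1
            rows.append({"read_id": rid, "strand": "NA", "repeat_start": -1,
                         "repeat_end": -1, "flank_edits": -1, "confident": False})
            continue
        strand[rid] = anchor.strand
        rows.append({"read_id": rid, "strand": anchor.strand,
                     "repeat_start": anchor.repeat_interval[0],
                     "repeat_end": anchor.repeat_interval[1],
                     "flank_edits": anchor.total_edits, "confident": True})
    return strand, pd.DataFrame(rows), n_no_anchor


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    os.makedirs(config.outdir, exist_ok=True)
    stage = "validate"
    try:
        for path in filter(None, (config.fastq, config.flanks_fasta, config.bam)):
            if not os.path.exists(path):
                raise FileNotFoundError(f"input not found: {path}")
        flank5, flank3 = load_flanks(config.flanks_fasta)
        locus = RepeatLocus.create(config.sample, flank5, flank3, config.motif)

        stage = "ingest"
        reads = {r.read_id: r.sequence for r in read_fastq(config.fastq)}
        logger.info("ingest: %d reads", len(reads))

        stage = "qc"
        if config.bam:
            strand, qc_table, n_filtered, n_no_anchor = _qc_bam(config, locus, reads)
        else:
            strand, qc_table, n_no_anchor = _qc_anchor(config, locus, reads)
            n_filtered = 0
        qc_path = os.path.join(config.outdir, f"{config.sample}.qc.tsv")
        qc_table.to_csv(qc_path, sep="\t", index=False)
        logger.info("qc: %d/%d reads confident", len(strand), len(reads))

        stage = "orient"
        oriented = {rid: reorient(reads[rid], strand[rid]) for rid in strand}

        stage = "call"
        calls = []
        n_no_call = 0
        for rid in oriented:
            call = call_read(oriented[rid], locus, max_gap=config.max_gap,
                             length_mode=config.length_mode, read_id=rid,
                             assume_sense=True)
            if call is None:
                n_no_call += 1
            else:
                calls.append(call)
        summary = summarize_sample(calls, bin_width=config.bin_width,
                                   sample=config.sample,
                                   n_reads_no_call=n_no_call)
        logger.info("call: %d called, modal length %s",
                    summary.n_reads_called, summary.modal_length)

        split_summaries = None
        if config.split_at is not None:
            below = [c for c in calls if c.est_units < config.split_at]
            above = [c for c in calls if c.est_units >= config.split_at]
            split_summaries = {
                f"lt{config.split_at}": summarize_sample(
                    below, config.bin_width, f"{config.sample}_lt"),
                f"ge{config.split_at}": summarize_sample(
                    above, config.bin_width, f"{config.sample}_ge"),
            }

        stage = "consensus"
        consensus_info: dict[str, dict] = {}
        outlier_ids: set[str] = set()
        consensus_fa = os.path.join(config.outdir, f"{config.sample}.consensus.fa")
        scores_path = os.path.join(config.outdir, f"{config.sample}.consensus_scores.tsv")
        score_rows = []
        with open(consensus_fa, "w") as fa:
            for side in ("left", "right"):
                windows = {c.read_id: getattr(
                    extract_flank_windows(oriented[c.read_id], c, config.window), side)
                    for c in calls}
                windows = {rid: w for rid, w in windows.items() if w}
                if len(windows) < 2:
                    continue
                ids = sorted(windows)
                result = score_and_flag_outliers(
                    [windows[i] for i in ids], k_sd=config.k_sd, ids=ids)
                outlier_ids |= set(result.outlier_ids)
                consensus_info[side] = {
                    "length": len(result.consensus_seq),
                    "mean_score": result.mean_score,
                    "sd_score": result.sd_score,
                    "n_outliers": len(result.outlier_ids),
                }
                fa.write(f">{config.sample}_{side}_flank_consensus\n"
                         f"{result.consensus_seq}\n")
                for rid in ids:
                    score_rows.append({
                        "read_id": rid, "side": side,
                        "score": result.per_read_scores[rid],
                        "outlier": rid in result.outlier_ids,
                    })
        pd.DataFrame(score_rows, columns=["read_id", "side", "score",
                                          "outlier"]).to_csv(
            scores_path, sep="\t", index=False)

        stage = "report"
        tracks = build_waterfall(calls, oriented, window=config.window)
        prefix = os.path.join(config.outdir, config.sample)
        plot_paths = plot_outputs(summary, tracks, prefix,
                                  image_format=config.image_format)

        stage = "manifest"
        manifest = {
            "sample": config.sample,
            "parameters": config.to_dict(),
            "counts": {
                "reads_in": len(reads),
                "confident": len(strand),
                "filtered": n_filtered,
                "no_anchor": n_no_anchor,
                "called": summary.n_reads_called,
                "no_call": n_no_call,
                "consensus_outliers": len(outlier_ids),
            },
            "modal_length": summary.modal_length,
            "all_modes": list(summary.all_modes),
            "histogram": {str(k): v for k, v in sorted(summary.histogram.items())},
            "consensus": consensus_info,
            "outputs": {"qc": qc_path, "consensus_fasta": consensus_fa,
                        "consensus_scores": scores_path, **plot_paths},
        }
        if split_summaries is not None:
            manifest["split_modes"] = {
                key: s.modal_length for key, s in split_summaries.items()}
        manifest_path = os.path.join(config.outdir, f"{config.sample}.manifest.json")
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest["outputs"]["manifest"] = manifest_path
        return manifest
    except PipelineError:
        raise
    except Exception as exc:  # annotate failures with the stage that died
        marker = os.path.join(config.outdir, "FAILED")
        try:
            with open(marker, "w") as fh:
                fh.write(f"{stage}: {exc}\n")
        except OSError:
            pass
        raise PipelineError(stage, str(exc)) from exc
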