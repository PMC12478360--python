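"""Alignment quality control and read orientation.

Consumes aligner output (SAM/BAM against the flank-only locus reference)
and computes per-read statistics from the CIGAR string and standard tags:
aligned lengths, mismatch and indel counts, mapping quality, strand.
High-confidence reads are selected on mapping quality, consistent
directionality across all alignment segments of a read, and coverage of
the repeat insertion point.  When no aligner output is supplied, a
lightweight internal anchorer locates the two flanks in each read by
exact k-mer seeding plus bounded-edit-distance verification, so the
pipeline can run on FASTQ alone.

Coordinates are 0-based half-open throughout; SAM's 1-based positions are
converted on ingest (pysam already does this).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Optional

import edlib
import pysam

from .locus import RepeatLocus, reverse_complement, validate_dna

# CIGAR operation codes (SAM spec): which ops consume reference / read.
_REF_CONSUMING = {0, 2, 3, 7, 8}   # M, D, N, =, X
_READ_ALIGNED = {0, 1, 7, 8}       # M, I, =, X  (soft clips excluded)

_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


@dataclass(frozen=True)
class AlignmentSummary:
    """Per-alignment-record statistics derived from the CIGAR and tags."""

    read_id: str
    mapq: int
    strand: str                      # "sense" | "antisense"
    ref_start: int
    ref_end: int
    aligned_ref_len: int
    aligned_read_len: int
    n_mismatch: Optional[int]        # None when neither NM nor MD present
    n_ins: int                       # insertion events
    n_del: int                       # deletion events
    ins_bases: int
    del_bases: int
    is_primary: bool
    n_supplementary: int
    confident: bool = False


class CigarError(ValueError):
    pass


def _mismatches_from_md(md: str) -> int:
    """Count substituted reference bases recorded in an MD tag."""
    n = 0
    for num, dele, sub in _MD_TOKEN.findall(md):
        if sub:
            n += 1
    return n


def parse_alignment(record: pysam.AlignedSegment) -> Optional[AlignmentSummary]:
    """Summarise one mapped SAM/BAM record; returns ``None`` for unmapped.

    Mismatch count is ``NM - inserted - deleted bases`` when the NM tag is
    present, otherwise taken from the MD tag, otherwise left unknown.
    """
    if record.is_unmapped:
        return None
    cig = record.cigartuples
    if not cig:
        raise CigarError(f"{record.query_name}: missing CIGAR on mapped record")
    ref_len = read_len = 0
    n_ins = n_del = ins_bases = del_bases = 0
    for op, length in cig:
        if length < 0:
            raise CigarError(f"{record.query_name}: negative CIGAR length")
        if op in _REF_CONSUMING:
            ref_len += length
        if op in _READ_ALIGNED:
            read_len += length
        if op == 1:
            n_ins += 1
            ins_bases += length
        elif op == 2:
            n_del += 1
            del_bases += length
    n_mismatch: Optional[int] = None
    if record.has_tag("NM"):
        n_mismatch = int(record.get_tag("NM")) - ins_bases - del_bases
    elif record.has_tag("MD"):
        n_mismatch = _mismatches_from_md(str(record.get_tag("MD")))
    n_supp = 0
    if record.has_tag("SA"):
        n_supp = str(record.get_tag("SA")).rstrip(";").count(";") + 1
    return AlignmentSummary(
        read_id=record.query_name,
        mapq=record.mapping_quality,
        strand="antisense" if record.is_reverse else "sense",
        ref_start=record.reference_start,
        ref_end=record.reference_start + ref_len,
        aligned_ref_len=ref_len,
        aligned_read_len=read_len,
        n_mismatch=n_mismatch,
        n_ins=n_ins,
        n_del=n_del,
        ins_bases=ins_bases,
        del_bases=del_bases,
        is_primary=not (record.is_supplementary or record.is_secondary),
        n_supplementary=n_supp,
    )


def filter_high_confidence(
    summaries: Iterable[AlignmentSummary],
    min_mapq: int = 20,
    require_flank_cov: int = 50,
    repeat_point: Optional[int] = None,
) -> list[AlignmentSummary]:
    """Set the ``confident`` flag on each summary; order is preserved.

    A read is confident iff its primary alignment has ``mapq >= min_mapq``,
    every supplementary segment of the read maps to the same strand as the
    primary, and (when ``repeat_point`` is given) the primary alignment
    covers at least ``require_flank_cov`` reference bases on each side of
    the repeat insertion point.  Idempotent.
    """
    summaries = list(summaries)
    by_read: dict[str, list[AlignmentSummary]] = {}
    for s in summaries:
        by_read.setdefault(s.read_id, []).append(s)

    verdict: dict[str, bool] = {}
    for read_id, group in by_read.items():
        primaries = [s for s in group if s.is_primary]
        ok = len(primaries) == 1
        if ok:
            p = primaries[0]
            ok = p.mapq >= min_mapq
            ok = ok and all(s.strand == p.strand for s in group)
            if ok and repeat_point is not None:
                ok = (p.ref_start <= repeat_point - require_flank_cov
                      and p.ref_end >= repeat_point + require_flank_cov)
        verdict[read_id] = ok
    return [replace(s, confident=verdict[s.read_id]) for s in summaries]


def reorient(sequence: str, strand: str) -> str:
    """Return the sense-oriented sequence.

    Sense input is returned unchanged; antisense input is
    reverse-complemented.  Applying the antisense transform twice is the
    identity.
    """
    sequence = validate_dna(sequence, name="read", allow_n=True)
    if strand == "sense":
        return sequence
    if strand == "antisense":
        return reverse_complement(sequence)
    raise ValueError(f"unknown strand {strand!r}")


@dataclass(frozen=True)
class AnchorResult:
    """Flank anchoring of one read, in sense-oriented read coordinates."""

    strand: str
    flank5_interval: tuple[int, int]
    flank3_interval: tuple[int, int]
    repeat_interval: tuple[int, int]   # candidate repeat region between flanks
    total_edits: int


def _seed_hit(query: str, target: str, k: int) -> bool:
    """True iff any k-mer of ``query`` (sampled every k bases) occurs exactly
    in ``target``."""
    for off in range(0, max(1, len(query) - k + 1), k):
        if target.find(query[off:off + k]) >= 0:
            return True
    return False


def _locate(query: str, target: str, k: int, max_edit_frac: float,
            min_start: int = 0) -> Optional[tuple[int, int, int]]:
    """Best infix match of ``query`` in ``target[min_start:]``.

    Exact k-mer seeding gates a bounded-edit-distance (edlib, infix mode)
    verification.  Returns (start, end, edits) in ``target`` coordinates,
    or None.
    """
    sub = target[min_start:]
    if len(sub) < k or not _seed_hit(query, sub, k):
        return None
    max_ed = int(max_edit_frac * len(query))
    res = edlib.align(query, sub, mode="HW", task="locations", k=max_ed)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end_incl = res["locations"][0]
    return min_start + start, min_start + end_incl + 1, res["editDistance"]


def anchor_flanks(read_seq: str, locus: RepeatLocus, seed_k: int = 13,
                  flank_window: int = 100,
                  max_edit_frac: float = 0.3) -> Optional[AnchorResult]:
    """Locate both flanks in a read without an external aligner.

    Searches for the 3'-most ``flank_window`` bases of flank5 and the
    5'-most ``flank_window`` bases of flank3 (or their reverse
    complements) via exact k-mer seeding followed by bounded-edit-distance
    verification.  The strand is sense iff the sense-orientation flank
    pair is found in order; the inter-flank interval is the candidate
    repeat region.  Returns ``None`` when neither orientation anchors
    both flanks.
    """
    if seed_k < 11:
        raise ValueError("seed_k must be >= 11")
    q5 = locus.flank5[-flank_window:]
    q3 = locus.flank3[:flank_window]
    best: Optional[AnchorResult] = None
    for strand in ("sense", "antisense"):
        seq = read_seq if strand == "sense" else reverse_complement(read_seq)
        hit5 = _locate(q5, seq, seed_k, max_edit_frac)
        if hit5 is None:
            continue
        hit3 = _locate(q3, seq, seed_k, max_edit_frac, min_start=hit5[1])
        if hit3 is None:
            continue
        result = AnchorResult(
            strand=strand,
            flank5_interval=(hit5[0], hit5[1]),
            flank3_interval=(hit3[0], hit3[1]),
            repeat_interval=(hit5[1], hit3[0]),
            total_edits=hit5[2] + hit3[2],
        )
        if best is None or result.total_edits < best.total_edits:
            best = result
    return best
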