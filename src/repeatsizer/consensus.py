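"""Flank consensus via center-star MSA with score-based outlier rejection.

The sequence on either side of the repeat is extracted from each called
read (a fixed window abutting the tract), the windows are multiply
aligned, and a majority-vote consensus is taken per column.  Each read is
then globally aligned against the consensus; reads whose alignment score
falls more than ``k_sd`` standard deviations below the mean are flagged
as outliers, and the consensus may be rebuilt once without them.

The MSA is a progressive center-star alignment: the center is the
sequence with the greatest summed pairwise global-alignment score to the
others, and every other sequence is merged in through its pairwise
alignment to the center.  For near-identical flank reads this is
deterministic and accurate; the interface takes plain sequence lists so
an external MSA tool can be substituted upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align

from .caller import RepeatCall

GAP = "-"

DEFAULT_SCORING = {"match": 2.0, "mismatch": -1.0,
                   "gap_open": -2.0, "gap_extend": -1.0}


@dataclass(frozen=True)
class FlankWindows:
    left: str
    right: str
    left_truncated: bool
    right_truncated: bool


@dataclass(frozen=True)
class ConsensusResult:
    consensus_seq: str
    per_read_scores: dict[str, float]
    mean_score: float
    sd_score: float
    outlier_ids: frozenset[str]
    k_sd: float


def extract_flank_windows(read_seq: str, call: RepeatCall,
                          window: int = 200) -> FlankWindows:
    """Windows of up to ``window`` bases immediately left and right of the
    called tract, in the read orientation the call refers to.  A window is
    flagged truncated when the read ends inside it."""
    if call.tract_start < 0 or call.tract_end > len(read_seq):
        raise ValueError(f"call does not fit read {call.read_id!r}")
    left_start = max(0, call.tract_start - window)
    right_end = min(len(read_seq), call.tract_end + window)
    return FlankWindows(
        left=read_seq[left_start:call.tract_start],
        right=read_seq[call.tract_end:right_end],
        left_truncated=call.tract_start - left_start < window,
        right_truncated=right_end - call.tract_end < window,
    )


def _aligner(scoring: dict[str, float]) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = scoring["match"]
    a.mismatch_score = scoring["mismatch"]
    a.open_gap_score = scoring["gap_open"]
    a.extend_gap_score = scoring["gap_extend"]
    return a


def _pick_center(seqs: Sequence[str], aligner: Align.PairwiseAligner,
                 max_sample: int = 30) -> int:
    """Index of the sequence maximising summed pairwise score.

    With more than ``max_sample`` sequences both candidates and scoring
    partners are an evenly spaced deterministic subsample."""
    if len(seqs) <= max_sample:
        idx = list(range(len(seqs)))
    else:
        idx = sorted({int(round(i * (len(seqs) - 1) / (max_sample - 1)))
                      for i in range(max_sample)})
    best_i, best_score = idx[0], -np.inf
    for i in idx:
        total = sum(aligner.score(seqs[i], seqs[j]) for j in idx if j != i)
        if total > best_score:
            best_i, best_score = i, total
    return best_i


def build_msa(seqs: Sequence[str],
              scoring: Optional[dict[str, float]] = None) -> list[str]:
    """Progressive center-star multiple alignment.

    Returns gapped rows in input order, all of equal length; removing the
    gap symbol from row *i* recovers ``seqs[i]`` exactly.
    """
    if len(seqs) < 2:
        raise ValueError("build_msa needs at least 2 sequences")
    if any(not s for s in seqs):
        raise ValueError("empty sequence in MSA input")
    aligner = _aligner(scoring or DEFAULT_SCORING)
    center_idx = _pick_center(seqs, aligner)
    center = seqs[center_idx]

    master = list(center)                      # center row with accumulated gaps
    rows: list[list[str]] = []                 # merged non-center rows
    order: list[int] = []                      # original index of each row
    for i, seq in enumerate(seqs):
        if i == center_idx:
            continue
        aln = aligner.align(center, seq)[0]
        c_g, s_g = str(aln[0]), str(aln[1])
        merged: list[str] = []
        mi = ci = 0
        while mi < len(master) or ci < len(c_g):
            a = master[mi] if mi < len(master) else None
            b = c_g[ci] if ci < len(c_g) else None
            if a == GAP and b != GAP:
                # column introduced by a previous sequence
                merged.append(GAP)
                mi += 1
            elif b == GAP and a != GAP:
                # new column: this alignment gaps the center here
                for r in rows:
                    r.insert(mi, GAP)
                master.insert(mi, GAP)
                merged.append(s_g[ci])
                mi += 1
                ci += 1
            else:
                # both consume the same center character (or both gap)
                merged.append(s_g[ci] if b is not None else GAP)
                mi += 1
                ci += 1
        rows.append(merged)
        order.append(i)

    out = [""] * len(seqs)
    out[center_idx] = "".join(master)
    for orig, row in zip(order, rows):
        out[orig] = "".join(row)
    assert len({len(r) for r in out}) == 1
    return out


def consensus_from_msa(matrix: Sequence[str]) -> str:
    """Column-majority consensus: majority non-gap symbol per column, ties
    become ``N``, majority-gap columns are dropped."""
    if not matrix:
        raise ValueError("empty alignment matrix")
    ncol = len(matrix[0])
    if any(len(r) != ncol for r in matrix):
        raise ValueError("alignment rows differ in length")
    out = []
    nrow = len(matrix)
    for c in range(ncol):
        column = [r[c] for r in matrix]
        n_gap = column.count(GAP)
        if n_gap * 2 > nrow:
            continue
        counts: dict[str, int] = {}
        for ch in column:
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        top = max(counts.values())
        winners = [ch for ch, n in counts.items() if n == top]
        out.append(winners[0] if len(winners) == 1 else "N")
    return "".join(out)


def score_and_flag_outliers(
    seqs: Sequence[str],
    consensus: Optional[str] = None,
    k_sd: float = 2.0,
    scoring: Optional[dict[str, float]] = None,
    ids: Optional[Sequence[str]] = None,
    passes: int = 1,
) -> ConsensusResult:
    """Score every sequence against the consensus and flag outliers.

    Outliers are sequences whose global-alignment score is below
    ``mean - k_sd * sd`` of the pre-removal score set (population SD).
    When ``consensus`` is None it is built from the input via
    :func:`build_msa` / :func:`consensus_from_msa`; ``passes`` extra
    consensus rebuilds are done after outlier removal (scores and the
    outlier set always refer to the original consensus).
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if ids is None:
        ids = [f"seq{i}" for i in range(len(seqs))]
    if len(ids) != len(seqs):
        raise ValueError("ids and seqs must be index-aligned")
    scoring = scoring or DEFAULT_SCORING
    aligner = _aligner(scoring)
    if consensus is None:
        consensus = consensus_from_msa(build_msa(seqs, scoring))
    scores = {rid: float(aligner.score(consensus, s))
              for rid, s in zip(ids, seqs)}
    values = np.fromiter(scores.values(), dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=0))
    threshold = mean - k_sd * sd
    outliers = frozenset(rid for rid, sc in scores.items()
                         if sd > 0 and sc < threshold)
    final = consensus
    if outliers and passes > 0:
        kept = [s for rid, s in zip(ids, seqs) if rid not in outliers]
        for _ in range(passes):
            if len(kept) >= 2:
                final = consensus_from_msa(build_msa(kept, scoring))
            elif kept:
                final = kept[0]
    return ConsensusResult(
        consensus_seq=final,
        per_read_scores=scores,
        mean_score=mean,
        sd_score=sd,
        outlier_ids=outliers,
        k_sd=k_sd,
    )
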