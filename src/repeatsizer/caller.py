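"""Gap-tolerant repeat-tract detection and per-sample length summaries.

A repeat tract is the longest stretch of exact motif occurrences chained
left to right, where short gaps between consecutive units are allowed (to
absorb sequencing errors and sequence variants) and the tract must begin
and end on a perfect repeat unit.  The repeat length of a read is, by
default, the tract span divided by the motif length and rounded — robust
to errors that interrupt individual units — with an exact perfect-unit
count available as an alternative mode.  The modal repeat length of a
sample is the most frequent per-read length estimate.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .locus import RepeatLocus, reverse_complement

LENGTH_MODES = ("span_estimate", "unit_count")


@dataclass(frozen=True)
class Tract:
    """A chained repeat tract in sequence coordinates (0-based, half-open)."""

    start: int
    end: int
    n_perfect_units: int
    n_gaps: int
    gap_bases: int
    unit_starts: tuple[int, ...]

    @property
    def span_bases(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepeatCall:
    read_id: str
    tract_start: int
    tract_end: int
    n_perfect_units: int
    span_bases: int
    est_units: int
    n_gaps: int
    gap_bases: int
    orientation_used: str
    unit_starts: tuple[int, ...] = field(default=(), repr=False)


@dataclass(frozen=True)
class SampleSummary:
    sample: str
    calls: tuple[RepeatCall, ...]
    modal_length: Optional[int]
    all_modes: tuple[int, ...]
    histogram: dict[int, int]        # bin start (units) -> read count
    bin_width: int
    n_reads_called: int
    n_reads_no_call: int


def find_motif_occurrences(seq: str, motif: str) -> list[int]:
    """All start positions of exact ``motif`` occurrences, overlapping
    included, sorted ascending."""
    if not motif:
        raise ValueError("motif must be non-empty")
    positions: list[int] = []
    i = seq.find(motif)
    while i >= 0:
        positions.append(i)
        i = seq.find(motif, i + 1)
    return positions


def chain_tract(positions: list[int], motif_len: int, max_gap: int,
                seq_len: int) -> Optional[Tract]:
    """Best gap-tolerant chain of perfect repeat units.

    Chains consist of non-overlapping motif occurrences read left to
    right, with at most ``max_gap`` bases between the end of one unit and
    the start of the next; every chain begins and ends on a perfect unit.
    The best chain maximises span, then perfect-unit count, then has the
    leftmost start.  Computed by dynamic programming over compatible
    successors, which is exact (a nearest next unit that dead-ends is
    bypassed when a slightly farther one chains on).  ``None`` when no
    occurrence exists.
    """
    if not positions:
        return None
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    n = len(positions)
    if any(positions[i] > positions[i + 1] for i in range(n - 1)):
        raise ValueError("positions must be sorted ascending")
    if positions[-1] + motif_len > seq_len or positions[0] < 0:
        raise ValueError("positions out of sequence bounds")

    # end_[i], units[i], ... describe the best chain starting at unit i.
    end_ = [0] * n
    units = [0] * n
    gaps = [0] * n
    gapb = [0] * n
    nxt = [-1] * n
    for i in range(n - 1, -1, -1):
        unit_end = positions[i] + motif_len
        lo = bisect_left(positions, unit_end, i + 1)
        hi = bisect_right(positions, unit_end + max_gap, lo)
        best_j = -1
        for j in range(lo, hi):
            if best_j < 0 or (end_[j], units[j]) > (end_[best_j], units[best_j]):
                best_j = j
        if best_j < 0:
            end_[i], units[i], gaps[i], gapb[i] = unit_end, 1, 0, 0
        else:
            g = positions[best_j] - unit_end
            end_[i] = end_[best_j]
            units[i] = units[best_j] + 1
            gaps[i] = gaps[best_j] + (1 if g > 0 else 0)
            gapb[i] = gapb[best_j] + g
            nxt[i] = best_j

    best_i = 0
    for i in range(1, n):
        key = (end_[i] - positions[i], units[i], -positions[i])
        best_key = (end_[best_i] - positions[best_i], units[best_i], -positions[best_i])
        if key > best_key:
            best_i = i
    chain = []
    i = best_i
    while i >= 0:
        chain.append(positions[i])
        i = nxt[i]
    return Tract(
        start=positions[best_i],
        end=end_[best_i],
        n_perfect_units=units[best_i],
        n_gaps=gaps[best_i],
        gap_bases=gapb[best_i],
        unit_starts=tuple(chain),
    )


def _estimate_units(tract: Tract, motif_len: int, length_mode: str) -> int:
    if length_mode == "span_estimate":
        return int(tract.span_bases / motif_len + 0.5)
    if length_mode == "unit_count":
        return tract.n_perfect_units
    raise ValueError(f"unknown length_mode {length_mode!r}")


def call_read(sequence: str, locus: RepeatLocus, max_gap: int = 24,
              length_mode: str = "span_estimate",
              read_id: str = "", assume_sense: bool = False) -> Optional[RepeatCall]:
    """Call the repeat tract of one read.

    Unless ``assume_sense``, both orientations are scanned and the one
    with the larger tract span wins (ties go to sense); the winning
    orientation is recorded, and tract coordinates refer to the read in
    that orientation.  Returns ``None`` when no motif occurrence exists
    in either orientation.
    """
    motif = locus.motif
    L = len(motif)

    def tract_of(seq: str) -> Optional[Tract]:
        return chain_tract(find_motif_occurrences(seq, motif), L, max_gap, len(seq))

    t_sense = tract_of(sequence)
    if assume_sense:
        chosen, orientation = t_sense, "sense"
    else:
        t_anti = tract_of(reverse_complement(sequence))
        if t_sense is None and t_anti is None:
            return None
        if t_anti is None or (t_sense is not None
                              and t_sense.span_bases >= t_anti.span_bases):
            chosen, orientation = t_sense, "sense"
        else:
            chosen, orientation = t_anti, "antisense"
    if chosen is None:
        return None
    return RepeatCall(
        read_id=read_id,
        tract_start=chosen.start,
        tract_end=chosen.end,
        n_perfect_units=chosen.n_perfect_units,
        span_bases=chosen.span_bases,
        est_units=_estimate_units(chosen, L, length_mode),
        n_gaps=chosen.n_gaps,
        gap_bases=chosen.gap_bases,
        orientation_used=orientation,
        unit_starts=chosen.unit_starts,
    )


def summarize_sample(calls: Iterable[RepeatCall], bin_width: int = 5,
                     sample: str = "sample",
                     n_reads_no_call: int = 0) -> SampleSummary:
    """Length distribution, modal length(s) and binned histogram.

    The mode is computed on raw integer length estimates, not on bins;
    the histogram (bins ``[k*w, (k+1)*w)`` aligned to zero) is for
    presentation.  Ties are reported in ``all_modes`` with
    ``modal_length`` the smallest; an empty call set yields
    ``modal_length None``.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    calls = tuple(calls)
    if not calls:
        return SampleSummary(sample=sample, calls=(), modal_length=None,
                             all_modes=(), histogram={}, bin_width=bin_width,
                             n_reads_called=0, n_reads_no_call=n_reads_no_call)
    lengths = pd.Series([c.est_units for c in calls])
    freq = lengths.value_counts()
    top = freq[freq == freq.max()]
    all_modes = tuple(sorted(int(v) for v in top.index))
    hist_counts = (lengths // bin_width * bin_width).value_counts().sort_index()
    histogram = {int(k): int(v) for k, v in hist_counts.items()}
    return SampleSummary(
        sample=sample,
        calls=calls,
        modal_length=all_modes[0],
        all_modes=all_modes,
        histogram=histogram,
        bin_width=bin_width,
        n_reads_called=len(calls),
        n_reads_no_call=n_reads_no_call,
    )


CALL_COLUMNS = ("read_id", "tract_start", "tract_end", "n_perfect_units",
                "span_bases", "est_units", "n_gaps", "gap_bases",
                "orientation_used")


def calls_to_dataframe(calls: Iterable[RepeatCall]) -> pd.DataFrame:
    """Per-read call table with one row per called read."""
    rows = [{col: getattr(c, col) for col in CALL_COLUMNS} for c in calls]
    return pd.DataFrame(rows, columns=list(CALL_COLUMNS))
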