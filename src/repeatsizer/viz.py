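"""Waterfall and repeat-length histogram reports.

The waterfall plot stacks one horizontal track per read, ordered by
estimated repeat length, showing the repeat tract (perfect units and
tolerated gaps) with a fixed window of flanking sequence on either side —
the read-level picture behind a sample's length distribution.  The
histogram bins per-read length estimates (bin width 5 repeats by default)
and marks the modal repeat length with a dashed green line.  Everything
plotted is also written as a TSV so no number exists only in a figure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .caller import RepeatCall, SampleSummary, calls_to_dataframe

STYLE = {
    "flank": "#b8b8b8",
    "unit": "#d62728",
    "gap": "#ffd54f",
    "modal_line": "green",
    "hist_bar": "#4878cf",
}

plt.rcParams["svg.hashsalt"] = "repeatsizer"


@dataclass(frozen=True)
class WaterfallTrack:
    """One read's display track; coordinates are read positions relative to
    the tract start, so the tract begins at 0 in every track."""

    read_id: str
    segments: tuple[tuple[tuple[int, int], str], ...]  # ((start, end), category)
    sort_key: int  # est_units


def build_waterfall(calls: Iterable[RepeatCall], reads: Mapping[str, str],
                    window: int = 200) -> list[WaterfallTrack]:
    """Build display tracks from calls and their (oriented) read sequences.

    Each track tiles ``[tract_start - window, tract_end + window)``
    (truncated at read ends) with flank, perfect-unit and gap segments.
    Tracks are sorted by estimated units descending, ties by read id.
    """
    tracks = []
    for call in calls:
        if call.read_id not in reads:
            raise KeyError(f"no read sequence for call {call.read_id!r}")
        read_len = len(reads[call.read_id])
        origin = call.tract_start
        win_start = max(0, call.tract_start - window)
        win_end = min(read_len, call.tract_end + window)
        # the tract ends on a perfect unit, so the last chained start
        # recovers the motif length without carrying it separately
        motif_len = (call.tract_end - call.unit_starts[-1]
                     if call.unit_starts else 0)
        segments: list[tuple[tuple[int, int], str]] = []
        if win_start < call.tract_start:
            segments.append(((win_start - origin, 0), "flank"))
        prev_end = call.tract_start
        for pos in call.unit_starts:
            if pos > prev_end:
                segments.append(((prev_end - origin, pos - origin), "gap"))
            segments.append(((pos - origin, pos + motif_len - origin), "unit"))
            prev_end = pos + motif_len
        if win_end > call.tract_end:
            segments.append(((call.tract_end - origin, win_end - origin), "flank"))
        tracks.append(WaterfallTrack(read_id=call.read_id,
                                     segments=tuple(segments),
                                     sort_key=call.est_units))
    tracks.sort(key=lambda t: (-t.sort_key, t.read_id))
    return tracks


def _plot_waterfall(tracks: list[WaterfallTrack], path: str) -> None:
    fig, ax = plt.subplots(figsize=(8, max(2.0, 0.035 * len(tracks) + 1)))
    if not tracks:
        ax.text(0.5, 0.5, "no calls", ha="center", va="center",
                transform=ax.transAxes)
    for y, track in enumerate(tracks):
        for (s, e), cat in track.segments:
            ax.broken_barh([(s, e - s)], (len(tracks) - 1 - y, 0.9),
                           facecolors=STYLE[cat], edgecolors="none")
    ax.set_xlabel("Position relative to tract start (bases)")
    ax.set_ylabel("Reads (longest tract on top)")
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None} if path.endswith(".svg") else None)
    plt.close(fig)


def _plot_histogram(summary: SampleSummary, path: str) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    if summary.n_reads_called == 0:
        ax.text(0.5, 0.5, "no calls", ha="center", va="center",
                transform=ax.transAxes)
    else:
        starts = sorted(summary.histogram)
        counts = [summary.histogram[s] for s in starts]
        ax.bar(starts, counts, width=summary.bin_width, align="edge",
               color=STYLE["hist_bar"], edgecolor="white")
        ax.axvline(summary.modal_length, linestyle="--",
                   color=STYLE["modal_line"],
                   label=f"modal length {summary.modal_length}")
        ax.legend(frameon=False)
    ax.set_xlabel("Repeat length (units)")
    ax.set_ylabel("Read count")
    ax.set_title(summary.sample)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None} if path.endswith(".svg") else None)
    plt.close(fig)


def plot_outputs(summary: SampleSummary, tracks: list[WaterfallTrack],
                 out_prefix: str, image_format: str = "svg") -> dict[str, str]:
    """Write the waterfall image, the binned histogram with its modal line,
    and the per-read summary TSV.  Returns output paths."""
    paths = {
        "waterfall": f"{out_prefix}.waterfall.{image_format}",
        "histogram": f"{out_prefix}.histogram.{image_format}",
        "calls_tsv": f"{out_prefix}.calls.tsv",
    }
    _plot_waterfall(tracks, paths["waterfall"])
    _plot_histogram(summary, paths["histogram"])
    calls_to_dataframe(summary.calls).to_csv(paths["calls_tsv"], sep="\t",
                                             index=False)
    return paths
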