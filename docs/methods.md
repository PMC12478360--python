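# Methods

## Problem and model

A repeat-expansion locus is modelled as `flank5 + m×N + flank3`: two fixed
flanking sequences with `N` copies of a short motif `m` (default the
`GGGGCC` hexanucleotide) inserted between them. Sequencing reads are assumed
to **span** the entire tract plus some flank on each side — the situation
created by Cas9-targeted nanopore enrichment, where cut sites bracket the
locus. Under that assumption the repeat length of a read is a local,
per-read measurement; no assembly or allele phasing is needed, and a sample's
allele sizes appear as modes of the per-read length distribution.

## Pipeline stages

1. **Ingest and QC.** With a BAM (alignments to the flank-only reference,
   i.e. the two flanks joined with zero repeat units), each record's CIGAR is
   summarised: reference-consuming ops (`M/D/N/=/X`) give the aligned
   reference length, read-consuming aligned ops (`M/I/=/X`, soft clips
   excluded) the aligned read length; insertion/deletion events and bases are
   counted, and the mismatch count is `NM − inserted − deleted bases` (MD-tag
   walk as fallback, unknown when neither tag is present — such reads are
   kept, since mismatch count is reported, not filtered on). A read is
   *high-confidence* iff its primary alignment has `mapq ≥ min_mapq`
   (default 20), all its supplementary segments share the primary's strand
   (consistent directionality; secondary alignments are ignored), and the
   primary covers `require_flank_cov` (default 50) reference bases on each
   side of the repeat insertion point.
2. **Internal anchorer (FASTQ-only mode).** Without alignments, the
   `flank_window` (default 100) bases of each flank adjacent to the repeat
   are located in the read by exact k-mer seeding (k = 13, sampled every k
   bases) followed by bounded-edit-distance infix alignment (edlib, at most
   30% of the window in edits). The window is kept at the scale of the
   guaranteed flank margin so that even reads entering the flank shallowly
   still contain the whole query. Sense is the orientation in which the
   5′ flank precedes the 3′ flank; the inter-flank interval is the candidate
   repeat region. Reads anchoring in neither orientation are excluded and
   counted (`no_anchor`).
3. **Orientation.** Antisense reads are reverse-complemented so all
   downstream coordinates and the consensus are on the sense strand.
4. **Tract calling.** All exact motif occurrences (overlaps included) are
   chained: consecutive non-overlapping units may be separated by at most
   `max_gap` bases, the tract must begin and end on a perfect unit, and the
   best tract maximises span, then perfect-unit count, then leftmost start.
   The chain is found by dynamic programming over compatible successors
   rather than nearest-next greedy chaining: a nearest next unit whose own
   chain dead-ends (e.g. occurrences at 0, 7, 12 with `max_gap` 6) must be
   bypassed for the result to equal the true maximal anchored tract, and the
   test suite checks equivalence against exhaustive enumeration. Gap
   content is not inspected — only gap length is constrained.
5. **Length estimate.** `span_estimate` (default) divides the tract span by
   the motif length and rounds; `unit_count` reports perfect units only.
   Errors inside a real tract destroy individual perfect units but barely
   change the span (insertions and deletions roughly cancel), so span
   estimation is robust where unit counting systematically undercounts; both
   modes are kept because either is a defensible reading of "longest stretch
   of repeat units".
6. **Sample summary.** The mode is taken on raw integer estimates; the
   histogram (bin width 5 repeats, bins aligned to zero) is presentation
   only. Ties are all reported with the smallest as the headline mode. Allele
   assignment is not attempted: a heterozygous sample shows two modes, and an
   optional `--split-at` threshold summarises the two length classes
   separately.
7. **Flank consensus.** The up-to-200-base windows abutting the tract on
   each side are multiply aligned (center-star: the center maximises summed
   pairwise global score, computed on a deterministic evenly spaced subsample
   of ≤ 30 sequences when the depth is higher; every row de-gaps to its
   input). Consensus is the per-column majority non-gap symbol, ties become
   `N`, majority-gap columns are dropped. Each window is then globally
   aligned to the consensus (match +2, mismatch −1, gap open −2, gap extend
   −1) and flagged as an outlier when its score is below
   `mean − k_sd·sd` (population SD over the pre-removal score set,
   `k_sd` default 2.0); one rebuild pass without outliers produces the final
   consensus, while scores and the outlier set always refer to the original.
8. **Reports.** Waterfall tracks (one per read, sorted by estimated length
   descending, tract start at x = 0, flank/unit/gap segments tiling a
   200-base window beyond the tract on each side) and the binned histogram
   with a dashed green line at the modal length, as SVG by default with a
   fixed style; every plotted number also lands in a TSV or the JSON
   manifest.

## Key parameters

| parameter | default | unit | why |
|---|---|---|---|
| `max_gap` | 24 | bases | see below |
| `min_mapq` | 20 | phred-like | conventional "confident" mapping cut-off |
| `require_flank_cov` | 50 | bases/side | read must genuinely bridge the insertion point |
| `flank_window` (anchorer) | 100 | bases | ≤ guaranteed flank margin of spanning reads |
| `window` (consensus/waterfall) | 200 | bases | flank context reported per read |
| `k_sd` | 2.0 | SDs | standard two-sigma outlier rule |
| `bin_width` | 5 | repeats | histogram presentation |
| scoring | +2/−1/−2/−1 | — | mild gap penalties suited to indel-rich reads |

**Why `max_gap` = 24.** A gap is the distance between consecutive perfect
units in the chain. At ONT-like error rates (~5%/base) the probability that
a given 6-base unit is imperfect is ≈ 1 − 0.95⁶ ≈ 26%, so short runs of
consecutive damaged units are common in long tracts, and a single inserted
base inside a unit already produces a 7-base gap. A tolerance of one motif
length therefore fragments every long tract (measured on 186-unit
simulations: modal estimate 33 at `max_gap` 6, 65 at 12, 186 at ≥ 18),
while four motif lengths absorb runs of up to ~3 damaged units. The cost of
a larger tolerance — chaining across a genuine interruption or a chance
motif occurrence in the flank — grows only linearly in `max_gap` bases and
is bounded by the anchoring requirement that chains start and end on perfect
units. 24 bases is the smallest round multiple of the motif with headroom
above the recovery threshold.

## The simulator

`simulate_reads` emulates the statistical structure of Cas9-enriched
spanning reads: per allele, each read covers the full tract plus a uniform
margin of at least `min_flank_emitted` (default 250) bases of each flank;
per base, one of deletion / substitution (to a uniformly chosen different
base) / insertion (of a uniform random base) occurs mutually exclusively
with the configured probabilities (defaults 1.5% / 2% / 1.5%) in a single
left-to-right pass; the read is reverse-complemented with probability
`frac_antisense` (default 0.5). Per-read truth (allele, unit count, strand,
error count) is emitted alongside. Defaults of 200 reads per allele match
the depth scale of a targeted nanopore run. Everything is driven by one
seeded generator, so identical configurations produce byte-identical FASTQ,
truth and reference files.

It does **not** model homopolymer- or GC-dependent error bias, signal-level
artefacts, chimeras, non-spanning fragments (a `allow_partial` flag exists
but is off by default, since the anchored-tract rule presumes spanning
reads), or enrichment efficiency. Passing tests on simulated data therefore
demonstrates the correctness of the chain/consensus/summary logic and
robustness to uniform indel/substitution noise — not immunity to the
structured error modes of real nanopore data, where the modal estimate may
shift by a few units (real G₄C₂ tracts are themselves somatically unstable,
which dominates that uncertainty anyway).

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; SAM positions are converted
  on ingest.
- `round(span/|m|)` uses half-up rounding so x.5 spans resolve
  deterministically upward rather than to even.
- Tract ties (equal span) resolve to more perfect units, then leftmost
  start; orientation ties resolve to sense.
- The alignment-free anchorer is a deliberately small substitute for a
  general long-read aligner: exact seeding makes random sequence fail fast,
  and the edit bound (30%) is far above real per-window error (~5%) while
  far below the ~75% distance of unrelated sequence.
- The flank-only reference carries zero repeat units between the flanks;
  spanning reads then align with the tract as one insertion, which keeps the
  repeat out of the alignment score entirely. The unit count of the emitted
  reference is configurable at locus construction if a different reference
  design is wanted.
- Center-star MSA was chosen over guide-tree progressive alignment because
  the inputs are near-identical windows of one locus: the center-star
  result is deterministic, order-independent, and exact enough that the
  majority consensus recovers the flank at depth 30 and 2% noise; the MSA
  function is a plain `list[str] -> list[str]` so an external aligner can be
  slotted in.
- One invocation of the consensus stage treats its input as one cluster;
  grouping reads (per allele, per clone) is the caller's choice, e.g. via
  `--split-at`.

## Known limitations

- Repeat lengths close to zero are reported only when at least one perfect
  unit survives; a fully destroyed short tract is a `no_call`, not a zero.
- Chain breaks in very noisy reads yield under-length calls; these populate
  the low tail of the distribution and are visible in the waterfall, but are
  not flagged per read.
- The antisense (C₄G₂-strand) motif is handled purely by reorientation;
  strand-specific biology (e.g. antisense transcription) is out of scope.
- Base qualities are carried through but never used.
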