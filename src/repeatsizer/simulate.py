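"""Synthetic targeted long reads over a repeat locus, with per-read truth.

Emulates the statistical structure of Cas9-enriched nanopore data over an
expansion locus: every read spans the full repeat tract plus a guaranteed
margin of each flank, carries ONT-like substitution/insertion/deletion
noise applied independently per base, and is emitted on a random strand.
The true unit count, strand and error count of every read are recorded in
a truth table so downstream stages can be tested against known answers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .locus import RepeatLocus, reverse_complement

_BASES = "ACGT"
# Q20 placeholder quality; the pipeline never consumes base qualities.
_QUAL_CHAR = chr(33 + 20)


class ConfigError(ValueError):
    """Simulation configuration inconsistent with the locus."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated sequencing run.

    Defaults mirror the study conditions the pipeline is meant to analyse:
    two-hundred spanning reads per allele, ~5% total error split between
    substitutions (2%), insertions (1.5%) and deletions (1.5%), and an
    even mix of sense and antisense reads.
    """

    unit_counts: tuple[int, ...] = (186, 208)
    reads_per_allele: int = 200
    sub_rate: float = 0.02
    ins_rate: float = 0.015
    del_rate: float = 0.015
    frac_antisense: float = 0.5
    min_flank_emitted: int = 250
    allow_partial: bool = False
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "unit_counts", tuple(int(u) for u in self.unit_counts))
        for name in ("sub_rate", "ins_rate", "del_rate"):
            r = getattr(self, name)
            if not (0.0 <= r < 1.0):
                raise ConfigError(f"{name} must be in [0, 1), got {r}")
        if self.sub_rate + self.ins_rate + self.del_rate >= 1.0:
            raise ConfigError("sub_rate + ins_rate + del_rate must be < 1")
        if not (0.0 <= self.frac_antisense <= 1.0):
            raise ConfigError("frac_antisense must be in [0, 1]")
        if self.reads_per_allele < 1:
            raise ConfigError("reads_per_allele must be >= 1")
        if any(u < 0 for u in self.unit_counts):
            raise ConfigError("unit_counts must all be >= 0")
        if not self.unit_counts:
            raise ConfigError("at least one allele (unit_counts) required")


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    allele_index: int
    true_units: int
    emitted_strand: str  # "sense" | "antisense"
    n_errors_introduced: int


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    quality: str = ""

    def __post_init__(self):
        if not self.quality:
            object.__setattr__(self, "quality", _QUAL_CHAR * len(self.sequence))


def _apply_errors(seq: str, config: SimConfig, rng: np.random.Generator) -> tuple[str, int]:
    """One left-to-right pass; each base independently deleted, substituted,
    or followed by an inserted random base (mutually exclusive per base)."""
    p_del, p_sub, p_ins = config.del_rate, config.sub_rate, config.ins_rate
    if p_del == p_sub == p_ins == 0.0:
        return seq, 0
    u = rng.random(len(seq))
    out: list[str] = []
    n_err = 0
    for i, base in enumerate(seq):
        x = u[i]
        if x < p_del:
            n_err += 1
            continue
        if x < p_del + p_sub:
            choices = [b for b in _BASES if b != base]
            out.append(choices[rng.integers(3)])
            n_err += 1
            continue
        out.append(base)
        if x < p_del + p_sub + p_ins:
            out.append(_BASES[rng.integers(4)])
            n_err += 1
    return "".join(out), n_err


def simulate_reads(locus: RepeatLocus, config: SimConfig) -> tuple[list[ReadRecord], list[TruthRecord]]:
    """Simulate spanning reads for every allele in ``config.unit_counts``.

    Each read covers the full repeat tract plus at least
    ``config.min_flank_emitted`` bases of each flank (uniformly chosen
    margins), then receives per-base errors and, with probability
    ``frac_antisense``, is reverse-complemented.  Fully deterministic
    under ``config.seed``.
    """
    mfe = config.min_flank_emitted
    if not config.allow_partial:
        if len(locus.flank5) < mfe or len(locus.flank3) < mfe:
            raise ConfigError(
                f"flanks ({len(locus.flank5)}/{len(locus.flank3)} bp) shorter than "
                f"min_flank_emitted={mfe}"
            )
    rng = np.random.default_rng(config.seed)
    reads: list[ReadRecord] = []
    truth: list[TruthRecord] = []
    for ai, n_units in enumerate(config.unit_counts):
        allele = locus.allele(n_units)
        tract_end = len(locus.flank5) + n_units * len(locus.motif)
        for ri in range(config.reads_per_allele):
            if config.allow_partial:
                start = int(rng.integers(0, len(allele) - 1))
                end = int(rng.integers(start + 1, len(allele) + 1))
            else:
                start = int(rng.integers(0, len(locus.flank5) - mfe + 1))
                end = int(rng.integers(tract_end + mfe, len(allele) + 1))
            fragment = allele[start:end]
            seq, n_err = _apply_errors(fragment, config, rng)
            antisense = bool(rng.random() < config.frac_antisense)
            if antisense:
                seq = reverse_complement(seq)
            read_id = f"{locus.name}_a{ai}_r{ri:04d}"
            reads.append(ReadRecord(read_id=read_id, sequence=seq))
            truth.append(TruthRecord(
                read_id=read_id,
                allele_index=ai,
                true_units=n_units,
                emitted_strand="antisense" if antisense else "sense",
                n_errors_introduced=n_err,
            ))
    return reads, truth


TRUTH_COLUMNS = ("read_id", "allele_index", "true_units", "emitted_strand",
                 "n_errors_introduced")


def emit_dataset(reads: Iterable[ReadRecord], truth: Iterable[TruthRecord],
                 out_prefix: str, locus: RepeatLocus) -> dict[str, str]:
    """Write ``<prefix>.fastq``, ``<prefix>.truth.tsv`` and ``<prefix>.ref.fa``.

    The reference FASTA carries the flank-only (zero repeat unit) locus
    sequence used for alignment.  Returns the mapping of output kinds to
    paths.  Output bytes are a pure function of the inputs.
    """
    reads = list(reads)
    truth = list(truth)
    if len(reads) != len(truth):
        raise ValueError("reads and truth must be index-aligned")
    out_dir = os.path.dirname(os.path.abspath(out_prefix))
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "fastq": f"{out_prefix}.fastq",
        "truth": f"{out_prefix}.truth.tsv",
        "reference": f"{out_prefix}.ref.fa",
    }
    with open(paths["fastq"], "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truth:
            fh.write(f"{t.read_id}\t{t.allele_index}\t{t.true_units}\t"
                     f"{t.emitted_strand}\t{t.n_errors_introduced}\n")
    ref = locus.reference
    with open(paths["reference"], "w") as fh:
        fh.write(f">{locus.name} flank-only reference, repeat_point={locus.repeat_point}\n")
        for i in range(0, len(ref), 70):
            fh.write(ref[i:i + 70] + "\n")
    return paths


def read_fastq(path: str) -> list[ReadRecord]:
    """Load a FASTQ file into :class:`ReadRecord` objects."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(path, "fastq"):
        qual = "".join(chr(33 + q) for q in rec.letter_annotations["phred_quality"])
        out.append(ReadRecord(read_id=rec.id, sequence=str(rec.seq).upper(), quality=qual))
    return out


def random_flanks(length5: int = 1000, length3: int = 1000, seed: int = 99,
                  motif: str = "GGGGCC") -> tuple[str, str]:
    """Random flank sequences free of the repeat motif in either orientation.

    Defaults give a 1 kb flank on each side, comparable to the homology-arm
    scale of engineered expansion loci.
    """
    rng = np.random.default_rng(seed)

    def draw(n: int) -> str:
        while True:
            s = "".join(_BASES[i] for i in rng.integers(0, 4, size=n))
            if motif not in s and reverse_complement(motif) not in s:
                return s

    return draw(length5), draw(length3)
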