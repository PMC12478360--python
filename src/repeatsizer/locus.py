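"""The target repeat locus: motif, flanks, and sequence construction."""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_DNA = frozenset("ACGT")
_DNA_N = frozenset("ACGTN")


class SequenceError(ValueError):
    """A sequence contains characters outside the expected DNA alphabet."""


def validate_dna(seq: str, *, name: str = "sequence", allow_n: bool = False) -> str:
    """Uppercase ``seq`` and verify it is plain DNA.

    Raises :class:`SequenceError` naming the first offending position.
    """
    seq = seq.upper()
    alphabet = _DNA_N if allow_n else _DNA
    for i, ch in enumerate(seq):
        if ch not in alphabet:
            raise SequenceError(
                f"{name}: invalid character {ch!r} at position {i}"
            )
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatLocus:
    """A repeat locus: two flanking sequences and the repeat motif between them.

    ``repeat_point`` is the 0-based offset on the flank-only reference
    (``flank5 + flank3``) at which repeat units are inserted; for any locus
    built through :func:`RepeatLocus.create` it equals ``len(flank5)``.
    """

    name: str
    flank5: str
    flank3: str
    motif: str = "GGGGCC"
    repeat_point: int = field(default=-1)

    @classmethod
    def create(cls, name: str, flank5: str, flank3: str, motif: str = "GGGGCC") -> "RepeatLocus":
        flank5 = validate_dna(flank5, name="flank5")
        flank3 = validate_dna(flank3, name="flank3")
        motif = validate_dna(motif, name="motif")
        if not motif:
            raise SequenceError("motif: must be non-empty")
        return cls(name=name, flank5=flank5, flank3=flank3, motif=motif,
                   repeat_point=len(flank5))

    @property
    def reference(self) -> str:
        """Flank-only reference sequence (zero repeat units between flanks)."""
        return self.flank5 + self.flank3

    def allele(self, n_units: int) -> str:
        """Full allele sequence carrying ``n_units`` repeat units."""
        return build_locus(self.flank5, self.flank3, n_units, self.motif)


def build_locus(flank5: str, flank3: str, n_units: int, motif: str = "GGGGCC") -> str:
    """Concatenate ``flank5 + motif * n_units + flank3``.

    All inputs are validated as plain A/C/G/T DNA; ``n_units`` may be zero,
    in which case the two flanks are joined directly.
    """
    if n_units < 0:
        raise ValueError(f"n_units must be >= 0, got {n_units}")
    flank5 = validate_dna(flank5, name="flank5")
    flank3 = validate_dna(flank3, name="flank3")
    motif = validate_dna(motif, name="motif")
    if not motif:
        raise SequenceError("motif: must be non-empty")
    return flank5 + motif * n_units + flank3
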