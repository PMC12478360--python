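import numpy as np
import pytest

from repeatsizer import RepeatLocus, SimConfig, simulate_reads
from repeatsizer.simulate import random_flanks


@pytest.fixture(scope="session")
def small_locus() -> RepeatLocus:
    """400 bp motif-free random flanks on each side of a GGGGCC insertion."""
    f5, f3 = random_flanks(400, 400, seed=1234)
    return RepeatLocus.create("test_locus", f5, f3, "GGGGCC")


@pytest.fixture(scope="session")
def kb_locus() -> RepeatLocus:
    """1 kb flanks, the scale of the engineered homology arms."""
    f5, f3 = random_flanks(1000, 1000, seed=4321)
    return RepeatLocus.create("kb_locus", f5, f3, "GGGGCC")


@pytest.fixture(scope="session")
def clean_dataset(small_locus):
    """Error-free mixed-strand reads from a 20-unit allele."""
    config = SimConfig(unit_counts=(20,), reads_per_allele=30, sub_rate=0.0,
                       ins_rate=0.0, del_rate=0.0, frac_antisense=0.5,
                       min_flank_emitted=100, seed=11)
    reads, truth = simulate_reads(small_locus, config)
    return reads, truth, config


def random_repeatish_sequence(rng: np.random.Generator, motif: str = "GGGGCC",
                              max_len: int = 300) -> str:
    """Random sequence interleaving motif units with random spacers, so that
    motif occurrence patterns (abutting, gapped, isolated) all arise."""
    parts = []
    length = 0
    while length < rng.integers(20, max_len):
        if rng.random() < 0.5:
            n = int(rng.integers(1, 5))
            parts.append(motif * n)
            length += 6 * n
        else:
            n = int(rng.integers(1, 15))
            parts.append("".join("ACGT"[i] for i in rng.integers(0, 4, n)))
            length += n
    return "".join(parts)[:max_len]
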