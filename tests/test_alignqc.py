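import re

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repeatsizer import (anchor_flanks, filter_high_confidence, parse_alignment,
                         reorient, reverse_complement, simulate_reads, SimConfig)
from repeatsizer.alignqc import AlignmentSummary

HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6"}, "SQ": [{"SN": "ref", "LN": 100000}]})


def make_record(cigar: str, flag: int = 0, mapq: int = 60, pos: int = 100,
                name: str = "r1", tags: str = "") -> pysam.AlignedSegment:
    read_len = sam_walk(cigar)["read_total"]
    seq = "A" * read_len if read_len else "*"
    line = f"{name}\t{flag}\tref\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t*"
    if tags:
        line += "\t" + tags
    return pysam.AlignedSegment.fromstring(line, HEADER)


def sam_walk(cigar: str) -> dict:
    """Independent CIGAR accounting straight from the SAM format definition:
    M/D/N/=/X consume reference, M/I/S/=/X consume the read."""
    out = {"ref": 0, "read_aligned": 0, "read_total": 0,
           "ins_events": 0, "ins_bases": 0, "del_events": 0, "del_bases": 0}
    for length, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        n = int(length)
        if op in "MDN=X":
            out["ref"] += n
        if op in "MIS=X":
            out["read_total"] += n
        if op in "MI=X":
            out["read_aligned"] += n
        if op == "I":
            out["ins_events"] += 1
            out["ins_bases"] += n
        if op == "D":
            out["del_events"] += 1
            out["del_bases"] += n
    return out


def random_cigar(rng: np.random.Generator) -> str:
    parts = []
    if rng.random() < 0.3:
        parts.append(f"{rng.integers(1, 50)}S")
    parts.append(f"{rng.integers(1, 200)}M")
    for _ in range(rng.integers(0, 8)):
        op = "ID"[rng.integers(2)]
        parts.append(f"{rng.integers(1, 20)}{op}")
        parts.append(f"{rng.integers(1, 200)}M")
    if rng.random() < 0.3:
        parts.append(f"{rng.integers(1, 50)}S")
    return "".join(parts)


def test_cigar_arithmetic_example():
    s = parse_alignment(make_record("10M2I5M1D20M"))
    assert s.aligned_ref_len == 36
    assert s.aligned_read_len == 37
    assert (s.n_ins, s.ins_bases) == (1, 2)
    assert (s.n_del, s.del_bases) == (1, 1)


def test_cigar_arithmetic_matches_sam_spec_walk_on_random_cigars():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        cigar = random_cigar(rng)
        s = parse_alignment(make_record(cigar))
        w = sam_walk(cigar)
        assert s.aligned_ref_len == w["ref"], cigar
        assert s.aligned_read_len == w["read_aligned"], cigar
        assert (s.n_ins, s.ins_bases) == (w["ins_events"], w["ins_bases"]), cigar
        assert (s.n_del, s.del_bases) == (w["del_events"], w["del_bases"]), cigar
        assert s.ref_end - s.ref_start == w["ref"]


def test_mismatch_from_nm_tag():
    assert parse_alignment(make_record("50M", tags="NM:i:3")).n_mismatch == 3
    # NM counts inserted/deleted bases too; they must be subtracted
    assert parse_alignment(make_record("10M1I10M", tags="NM:i:4")).n_mismatch == 3
    assert parse_alignment(make_record("10M2D10M", tags="NM:i:5")).n_mismatch == 3


def test_mismatch_from_md_tag_when_nm_absent():
    # MD walk: 3 matches, sub, 2 matches, sub, 6 matches, sub, 6 matches
    s = parse_alignment(make_record("20M", tags="MD:Z:3C2A6T6"))
    assert s.n_mismatch == 3
    # deletions in MD (^-prefixed) are not substitutions
    s = parse_alignment(make_record("10M2D10M", tags="MD:Z:4G5^AC10"))
    assert s.n_mismatch == 1


def test_mismatch_unknown_without_tags():
    assert parse_alignment(make_record("50M")).n_mismatch is None


def test_unmapped_record_is_skipped_not_raised():
    rec = pysam.AlignedSegment.fromstring(
        "r9\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*", HEADER)
    assert parse_alignment(rec) is None


def _summary(read_id="r", mapq=60, strand="sense", primary=True,
             ref_start=0, ref_end=800):
    return AlignmentSummary(
        read_id=read_id, mapq=mapq, strand=strand, ref_start=ref_start,
        ref_end=ref_end, aligned_ref_len=ref_end - ref_start,
        aligned_read_len=ref_end - ref_start, n_mismatch=0, n_ins=0, n_del=0,
        ins_bases=0, del_bases=0, is_primary=primary, n_supplementary=0)


class TestHighConfidenceFilter:
    REPEAT_POINT = 400

    def run(self, summaries):
        return filter_high_confidence(summaries, min_mapq=20,
                                      require_flank_cov=50,
                                      repeat_point=self.REPEAT_POINT)

    def test_good_primary_is_confident(self):
        out = self.run([_summary(mapq=60)])
        assert out[0].confident

    def test_low_mapq_not_confident(self):
        assert not self.run([_summary(mapq=5)])[0].confident

    def test_insufficient_flank_coverage_not_confident(self):
        assert not self.run([_summary(ref_start=380)])[0].confident
        assert not self.run([_summary(ref_end=420)])[0].confident

    def test_all_strand_combinations_of_two_segments(self):
        """Only same-strand primary+supplementary sets pass the
        consistent-directionality rule (brute force over combinations)."""
        for p_strand in ("sense", "antisense"):
            for s_strand in ("sense", "antisense"):
                out = self.run([
                    _summary(strand=p_strand),
                    _summary(strand=s_strand, primary=False),
                ])
                expected = p_strand == s_strand
                assert all(s.confident == expected for s in out)

    def test_idempotent_and_order_preserving(self):
        summaries = [_summary(read_id=f"r{i}", mapq=10 + 5 * i)
                     for i in range(6)]
        once = self.run(summaries)
        twice = self.run(once)
        assert once == twice
        assert [s.read_id for s in once] == [s.read_id for s in summaries]


def test_reorient_sense_identity_and_antisense_revcomp():
    assert reorient("GGGGCC", "sense") == "GGGGCC"
    assert reorient("GGCCCC", "antisense") == "GGGGCC"
    with pytest.raises(ValueError):
        reorient("ACGT", "up")
    with pytest.raises(ValueError):
        reorient("ACGU", "sense")


@settings(derandomize=True, max_examples=50)
@given(st.text(alphabet="ACGTN", min_size=1, max_size=1000))
def test_reorient_antisense_is_involution(seq):
    assert reorient(reorient(seq, "antisense"), "antisense") == seq


class TestAnchorFlanks:
    def test_error_free_read_anchors_with_exact_interval(self, clean_dataset,
                                                         small_locus):
        reads, truth, _ = clean_dataset
        for r, t in zip(reads[:10], truth[:10]):
            anchor = anchor_flanks(r.sequence, small_locus)
            assert anchor is not None
            assert anchor.strand == t.emitted_strand
            start, end = anchor.repeat_interval
            assert end - start == 6 * t.true_units
            assert anchor.total_edits == 0

    def test_revcomp_flips_strand_same_interval(self, clean_dataset, small_locus):
        reads, truth, _ = clean_dataset
        r, t = reads[0], truth[0]
        a1 = anchor_flanks(r.sequence, small_locus)
        a2 = anchor_flanks(reverse_complement(r.sequence), small_locus)
        assert {a1.strand, a2.strand} == {"sense", "antisense"}
        assert (a1.repeat_interval[1] - a1.repeat_interval[0]
                == a2.repeat_interval[1] - a2.repeat_interval[0])

    def test_random_sequence_gets_no_anchor(self, small_locus):
        rng = np.random.default_rng(3)
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        assert anchor_flanks(junk, small_locus) is None

    def test_noisy_reads_still_anchor(self, small_locus):
        config = SimConfig(unit_counts=(20,), reads_per_allele=20,
                           frac_antisense=0.5, min_flank_emitted=100, seed=8)
        reads, truth = simulate_reads(small_locus, config)
        hits = sum(anchor_flanks(r.sequence, small_locus) is not None
                   for r in reads)
        assert hits == len(reads)

    def test_seed_k_floor(self, small_locus):
        with pytest.raises(ValueError):
            anchor_flanks("ACGT" * 100, small_locus, seed_k=8)
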