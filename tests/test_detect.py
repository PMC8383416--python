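"""Junction-pair classification against an exhaustive circular-traversal
oracle, plus candidate selection and clustering."""

import itertools

import pandas as pd
import pytest

from circlechrom.detect import (
    EcDNARecord,
    JunctionCandidate,
    classify_pair,
    cluster_junctions,
    detect_junctions,
)
from circlechrom.io import SegmentAlignment, ALIGNMENT_COLUMNS

from conftest import oracle_is_junction_pair


def seg(read_id, rs, re, chrom, fs, fe, strand):
    return SegmentAlignment(read_id, rs, re, chrom, fs, fe, strand)


class TestClassifyPair:
    def test_outward_pair_yields_candidate(self):
        a = seg("read1", 0, 3000, "chr1", 50_000, 53_000, "+")
        b = seg("read1", 3000, 6000, "chr1", 47_000, 50_000, "+")
        cand = classify_pair(a, b)
        assert (cand.chrom, cand.circle_start, cand.circle_end) == ("chr1", 47_000, 53_000)
        assert cand.size == 6000
        assert oracle_is_junction_pair(a, b) == ("chr1", "+", 47_000, 53_000)

    def test_colinear_inward_pair_rejected(self):
        a = seg("read1", 0, 3000, "chr1", 47_000, 50_000, "+")
        b = seg("read1", 3000, 6000, "chr1", 50_000, 53_000, "+")
        assert classify_pair(a, b) is None
        assert oracle_is_junction_pair(a, b) is None

    def test_different_chromosomes_rejected(self):
        a = seg("r", 0, 3000, "chr1", 50_000, 53_000, "+")
        b = seg("r", 3000, 6000, "chr2", 47_000, 50_000, "+")
        assert classify_pair(a, b) is None

    def test_opposite_strands_rejected(self):
        a = seg("r", 0, 3000, "chr1", 50_000, 53_000, "+")
        b = seg("r", 3000, 6000, "chr1", 47_000, 50_000, "-")
        assert classify_pair(a, b) is None

    def test_segment_at_exactly_min_length_rejected(self):
        a = seg("r", 0, 1000, "chr1", 52_000, 53_000, "+")
        b = seg("r", 1000, 2000, "chr1", 47_000, 48_000, "+")
        assert classify_pair(a, b) is None  # strict > 1 kb

    def test_minus_strand_outward_pair(self):
        # read descends: first arm at the circle's low end, then re-enters high
        a = seg("r", 0, 3000, "chr1", 47_000, 50_000, "-")
        b = seg("r", 3000, 6000, "chr1", 50_000, 53_000, "-")
        cand = classify_pair(a, b)
        assert (cand.circle_start, cand.circle_end) == (47_000, 53_000)
        assert oracle_is_junction_pair(a, b) is not None

    def test_different_reads_error(self):
        a = seg("r1", 0, 3000, "chr1", 50_000, 53_000, "+")
        b = seg("r2", 3000, 6000, "chr1", 47_000, 50_000, "+")
        with pytest.raises(ValueError):
            classify_pair(a, b)

    def test_large_read_overlap_rejected_not_error(self):
        a = seg("r", 0, 3000, "chr1", 50_000, 53_000, "+")
        b = seg("r", 2000, 5000, "chr1", 47_000, 50_000, "+")
        assert classify_pair(a, b) is None

    def test_agrees_with_circular_traversal_oracle_on_grid(self):
        """Exhaustive agreement over >= 500 two-segment geometries."""
        intervals = [(s, s + l) for s in range(0, 18, 3) for l in (2, 4)]
        n = 0
        for (a_lo, a_hi), (b_lo, b_hi) in itertools.product(intervals, repeat=2):
            for strand in "+-":
                for chrom_b in ("chr1", "chr2"):
                    a = seg("r", 0, a_hi - a_lo, "chr1", a_lo, a_hi, strand)
                    b = seg("r", a_hi - a_lo, a_hi - a_lo + (b_hi - b_lo),
                            chrom_b, b_lo, b_hi, strand)
                    got = classify_pair(a, b, min_seg_len=1)
                    want = oracle_is_junction_pair(a, b, min_seg_len=1)
                    n += 1
                    if want is None:
                        assert got is None, (a, b)
                    else:
                        assert got is not None, (a, b)
                        assert (got.chrom, got.strand, got.circle_start, got.circle_end) == want
        assert n >= 500


class TestDetectJunctions:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=list(ALIGNMENT_COLUMNS))

    def test_single_segment_read_yields_nothing(self):
        df = self._frame([("r", 0, 5000, "chr1", 0, 5000, "+")])
        assert detect_junctions(df) == []

    def test_three_segments_only_trailing_pair_head_to_tail(self):
        df = self._frame(
            [
                ("r", 0, 2000, "chr2", 10_000, 12_000, "+"),   # unrelated chrom
                ("r", 2000, 5000, "chr1", 50_000, 53_000, "+"),
                ("r", 5000, 8000, "chr1", 47_000, 50_000, "+"),
            ]
        )
        (cand,) = detect_junctions(df)
        assert (cand.circle_start, cand.circle_end) == (47_000, 53_000)

    def test_oversized_candidate_dropped(self):
        df = self._frame(
            [
                ("r", 0, 3000, "chr1", 200_000, 203_000, "+"),
                ("r", 3000, 6000, "chr1", 50_000, 53_000, "+"),
            ]
        )
        assert detect_junctions(df) == []  # size 153 kb > default 100 kb
        assert len(detect_junctions(df, size_range=(50, 200_000))) == 1

    def test_one_candidate_per_read_largest_pair_wins(self):
        df = self._frame(
            [
                ("r", 0, 1500, "chr1", 30_000, 31_500, "+"),
                ("r", 1500, 3000, "chr1", 25_000, 26_500, "+"),   # small pair
                ("r", 3000, 8000, "chr1", 90_000, 95_000, "+"),
                ("r", 8000, 13_000, "chr1", 80_000, 85_000, "+"),  # big pair
            ]
        )
        cands = detect_junctions(df)
        assert len(cands) == 1
        assert (cands[0].circle_start, cands[0].circle_end) == (80_000, 95_000)

    def test_simulated_junction_reads_recover_truth(self, default_sim):
        cands = detect_junctions(default_sim.alignments)
        truth = {(c.start, c.end) for c in default_sim.truth.circles}
        for cand in cands:
            assert (cand.circle_start, cand.circle_end) in truth


class TestClusterJunctions:
    def test_median_breakpoints_and_support(self):
        cands = [
            JunctionCandidate(f"r{i}", "chr1", "+", s, e)
            for i, (s, e) in enumerate([(47_000, 53_000), (47_004, 52_998), (46_990, 53_010)])
        ]
        (rec,) = cluster_junctions(cands, tolerance=50)
        assert (rec.start, rec.end, rec.support) == (47_000, 53_000, 3)

    def test_distant_candidates_stay_separate(self):
        cands = [
            JunctionCandidate("r1", "chr1", "+", 10_000, 15_000),
            JunctionCandidate("r2", "chr1", "+", 20_000, 25_000),
        ]
        assert len(cluster_junctions(cands, 50)) == 2

    def test_empty_input(self):
        assert cluster_junctions([], 50) == []

    def test_support_counts_distinct_reads(self):
        cands = [
            JunctionCandidate("r1", "chr1", "+", 100, 600),
            JunctionCandidate("r1", "chr1", "-", 110, 610),
            JunctionCandidate("r2", "chr1", "+", 105, 605),
        ]
        (rec,) = cluster_junctions(cands, 50)
        assert rec.support == 2

    def test_record_invariants(self):
        with pytest.raises(ValueError):
            EcDNARecord("chr1", 100, 100, 1)
        with pytest.raises(ValueError):
            EcDNARecord("chr1", 100, 200, 0)
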