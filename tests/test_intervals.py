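"""Interval algebra: overlap, reciprocal overlap, coverage, stitching, probes."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from triocnv.intervals import (
    GenomicInterval, ProbeMap, count_probes, coverage_fraction, overlap_length,
    reciprocal_overlap, stitch_fragments,
)

from .conftest import gi, make_call


def brute_force_ro(a: GenomicInterval, b: GenomicInterval) -> float:
    """Per-base set-membership oracle for reciprocal overlap."""
    if a.chrom != b.chrom:
        return 0.0
    shared = len(set(range(a.start, a.end)) & set(range(b.start, b.end)))
    return shared / max(a.length, b.length)


class TestOverlapAndRO:
    @pytest.mark.parametrize("a,b,expected", [
        (gi("chr1", 0, 100), gi("chr1", 0, 100), 100),
        (gi("chr1", 0, 100), gi("chr2", 0, 100), 0),
        (gi("chr1", 0, 100), gi("chr1", 50, 150), 50),
        (gi("chr1", 0, 100), gi("chr1", 200, 300), 0),
    ])
    def test_overlap_length(self, a, b, expected):
        assert overlap_length(a, b) == expected

    @pytest.mark.parametrize("a,b,expected", [
        (gi("chr1", 0, 100), gi("chr1", 0, 100), 1.0),
        (gi("chr1", 0, 100), gi("chr1", 50, 150), 0.5),
        # asymmetric sizes: overlap 10 bp over max length 1000
        (gi("chr1", 0, 1000), gi("chr1", 900, 910), 0.01),
    ])
    def test_reciprocal_overlap_values(self, a, b, expected):
        assert reciprocal_overlap(a, b) == pytest.approx(expected)
        assert reciprocal_overlap(a, b) == pytest.approx(brute_force_ro(a, b))

    @given(
        st.integers(0, 9_000), st.integers(1, 1_000),
        st.integers(0, 9_000), st.integers(1, 1_000),
    )
    def test_ro_matches_per_base_oracle_and_is_symmetric(self, s1, l1, s2, l2):
        a, b = gi("chr1", s1, s1 + l1), gi("chr1", s2, s2 + l2)
        ro = reciprocal_overlap(a, b)
        assert 0.0 <= ro <= 1.0
        assert ro == reciprocal_overlap(b, a)
        assert ro == pytest.approx(brute_force_ro(a, b))
        assert (ro == 1.0) == (a == b)
        assert (ro == 0.0) == (overlap_length(a, b) == 0)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            gi("chr1", 100, 100)
        with pytest.raises(ValueError):
            gi("", 0, 100)


class TestCoverageFraction:
    def test_partial_coverage_from_two_regions(self):
        # bases 100..149 covered by the first region, 160..199 by the second
        regions = [gi("chr1", 0, 150), gi("chr1", 160, 300)]
        assert coverage_fraction(gi("chr1", 100, 200), regions) == pytest.approx(0.9)

    def test_empty_regions_and_full_containment(self):
        assert coverage_fraction(gi("chr1", 100, 200), []) == 0.0
        assert coverage_fraction(gi("chr1", 100, 200), [gi("chr1", 0, 1000)]) == 1.0

    def test_overlapping_regions_are_merged_first(self):
        regions = [gi("chr1", 0, 120), gi("chr1", 100, 150)]
        assert coverage_fraction(gi("chr1", 100, 200), regions) == pytest.approx(0.5)

    @given(st.lists(st.tuples(st.integers(0, 5_000), st.integers(1, 2_000)),
                    max_size=8),
           st.integers(0, 5_000), st.integers(1, 2_000))
    def test_matches_per_base_oracle(self, regions, qs, ql):
        query = gi("chr1", qs, qs + ql)
        region_ivs = [gi("chr1", s, s + l) for s, l in regions]
        covered = set()
        for r in region_ivs:
            covered |= set(range(r.start, r.end))
        expected = len(covered & set(range(query.start, query.end))) / query.length
        assert coverage_fraction(query, region_ivs) == pytest.approx(expected)


class TestCountProbes:
    def test_containment_and_missing_chromosome(self):
        probes = ProbeMap({"chr1": [10, 20, 30, 40, 50]})
        assert count_probes(gi("chr1", 0, 100), probes) == 5
        assert count_probes(gi("chr3", 0, 100), probes) == 0
        assert count_probes(gi("chr1", 25, 45), probes) == 2

    @given(st.lists(st.integers(0, 10_000), unique=True, max_size=50),
           st.integers(0, 10_000), st.integers(1, 3_000))
    def test_matches_linear_scan(self, positions, qs, ql):
        probes = ProbeMap({"chr1": positions})
        query = gi("chr1", qs, qs + ql)
        expected = sum(1 for p in positions if qs <= p < qs + ql)
        assert count_probes(query, probes) == expected

    def test_duplicate_probe_positions_rejected(self):
        with pytest.raises(ValueError):
            ProbeMap({"chr1": [10, 10, 20]})


class TestStitchFragments:
    def test_small_gap_merges_and_probe_counts_sum(self):
        calls = [
            make_call("chr2", 0, 1_000_000, "del", n_probes=800, confidence=0.9),
            make_call("chr2", 1_050_000, 2_000_000, "del", n_probes=700, confidence=0.7),
        ]
        out = stitch_fragments(calls, max_gap_bp=100_000)
        assert len(out) == 1
        merged = out[0]
        assert (merged.interval.start, merged.interval.end) == (0, 2_000_000)
        assert merged.n_probes == 1500
        assert merged.confidence == 0.7  # min of members
        assert merged.stitched_from == 2

    def test_type_mismatch_never_merges(self):
        calls = [make_call("chr2", 0, 1_000_000, "del"),
                 make_call("chr2", 1_050_000, 2_000_000, "dup")]
        assert len(stitch_fragments(calls, max_gap_bp=100_000)) == 2

    def test_gap_beyond_fractional_threshold_stays_split(self):
        # gap 4,990,000 > max(100,000, 0.2 x 5,010,000) = 1,002,000
        calls = [make_call("chr2", 0, 10_000, "del"),
                 make_call("chr2", 5_000_000, 5_010_000, "del")]
        out = stitch_fragments(calls, max_gap_bp=100_000, max_gap_fraction=0.2)
        assert len(out) == 2

    def test_mixed_sample_or_caller_rejected_naming_offender(self):
        calls = [make_call(sample="S1"), make_call(sample="S2", start=200_000,
                                                   end=300_000)]
        with pytest.raises(ValueError, match="S2"):
            stitch_fragments(calls)

    @given(st.lists(
        st.tuples(st.integers(0, 80), st.integers(1, 30),
                  st.sampled_from(["del", "dup"])),
        min_size=1, max_size=12))
    def test_idempotent_and_coverage_never_shrinks(self, raw):
        scale = 100_000
        calls = [make_call("chr1", s * scale, (s + l) * scale, t) for s, l, t in raw]
        once = stitch_fragments(calls)
        twice = stitch_fragments(once)
        assert once == twice

        def covered(calls, cnv_type):
            bases = set()
            for c in calls:
                if c.cnv_type == cnv_type:
                    bases |= set(range(c.interval.start // scale,
                                       -(-c.interval.end // scale)))
            return bases

        for t in ("del", "dup"):
            assert covered(calls, t) <= covered(once, t)
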