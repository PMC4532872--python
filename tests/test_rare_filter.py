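"""Frequency/size/probe/stable-region gates and their audit trail."""

import dataclasses

import pytest
from hypothesis import given, strategies as st

from triocnv.consensus import ConsensusCnv
from triocnv.intervals import GenomicInterval, ProbeMap
from triocnv.io_model import Region
from triocnv.rare_filter import (
    ControlCohortIndex, RareFilterConfig, apply_rare_filters, control_frequency,
)

from .conftest import gi, make_call


def consensus(chrom="chr1", start=0, end=100_000, cnv_type="del", sample="S1",
              n_probes=50):
    return ConsensusCnv(sample, gi(chrom, start, end), cnv_type,
                        frozenset(["ipattern", "penncnv"]), "ipattern",
                        True, n_probes)


def dense_probes(spacing=1_000, length=10_000_000):
    return ProbeMap({c: list(range(0, length, spacing))
                     for c in ("chr1", "chr2")})


WHOLE_GENOME = [Region(gi("chr1", 0, 10_000_000)), Region(gi("chr2", 0, 10_000_000))]


class TestControlFrequency:
    def test_no_overlap_zero_frequency(self):
        cohort = ControlCohortIndex("c", 1000, [
            make_call("chr2", 0, 100_000, "del", sample="K1", caller="control")])
        assert control_frequency(consensus("chr1"), cohort) == (0, 0.0)

    def test_identical_interval_carriers_counted(self):
        calls = [make_call("chr1", 0, 100_000, "del", sample=f"K{i}",
                           caller="control") for i in (1, 2)]
        cohort = ControlCohortIndex("c", 1000, calls)
        assert control_frequency(consensus(), cohort) == (2, 0.002)

    def test_fragmented_control_event_not_unioned(self):
        # two fragments each RO=0.4 vs the query must NOT count as a carrier
        calls = [make_call("chr1", 0, 40_000, "del", sample="K1", caller="control"),
                 make_call("chr1", 60_000, 100_000, "del", sample="K1",
                           caller="control")]
        cohort = ControlCohortIndex("c", 1000, calls)
        assert control_frequency(consensus(), cohort, min_ro=0.5) == (0, 0.0)

    def test_same_sample_multiple_matches_counted_once(self):
        calls = [make_call("chr1", 0, 100_000, "del", sample="K1", caller="control"),
                 make_call("chr1", 1_000, 99_000, "del", sample="K1",
                           caller="control")]
        cohort = ControlCohortIndex("c", 1000, calls)
        assert control_frequency(consensus(), cohort)[0] == 1

    def test_type_must_match(self):
        cohort = ControlCohortIndex("c", 1000, [
            make_call("chr1", 0, 100_000, "dup", sample="K1", caller="control")])
        assert control_frequency(consensus(cnv_type="del"), cohort) == (0, 0.0)


class TestGates:
    def empty_cohort(self, n=1000):
        return ControlCohortIndex("c", n, [])

    def run(self, calls, cohorts=None, config=RareFilterConfig(),
            stable=WHOLE_GENOME, probes=None):
        return apply_rare_filters(calls, cohorts or [self.empty_cohort()],
                                  stable, probes or dense_probes(), config)

    def test_size_gate_strictly_above_10kb(self):
        survivors, audit = self.run([consensus(end=9_000),
                                     consensus(start=20_000, end=30_000),
                                     consensus(start=50_000, end=60_001)])
        assert [s.interval.length for s in survivors] == [10_001]
        size_rows = [a for a in audit if a.gate == "size"]
        assert [a.passed for a in size_rows] == [False, False, True]

    def test_probe_gate(self):
        sparse = ProbeMap({"chr1": [0, 15_000, 30_000, 45_000]})
        survivors, audit = self.run([consensus(end=50_000)], probes=sparse)
        assert survivors == []
        assert any(a.gate == "probes" and a.value == 4 and not a.passed
                   for a in audit)

    def test_stable_coverage_gate_strictly_above_75pct(self):
        # exactly 75% covered -> fails; just above -> passes
        stable = [Region(gi("chr1", 0, 75_000))]
        survivors, _ = self.run([consensus(end=100_000)], stable=stable)
        assert survivors == []
        stable = [Region(gi("chr1", 0, 75_100))]
        survivors, _ = self.run([consensus(end=100_000)], stable=stable)
        assert len(survivors) == 1

    def test_rare_everywhere_conjunction_across_cohorts(self):
        call = consensus()
        primary = ControlCohortIndex("primary", 2988, [])
        refinement = ControlCohortIndex("refine", 1000, [
            make_call("chr1", 0, 100_000, "del", sample=f"K{i}", caller="control")
            for i in range(10)])  # 1% in the refinement cohort
        survivors, audit = apply_rare_filters(
            [call], [primary, refinement], WHOLE_GENOME, dense_probes())
        assert survivors == []
        freq_rows = {a.gate: a.passed for a in audit if a.gate.startswith("frequency")}
        assert freq_rows == {"frequency:primary": True, "frequency:refine": False}

    def test_carrier_threshold_documented_in_audit(self):
        _, audit = apply_rare_filters([consensus()],
                                      [ControlCohortIndex("primary", 2988, [])],
                                      WHOLE_GENOME, dense_probes())
        freq = next(a for a in audit if a.gate == "frequency:primary")
        assert "<= 2" in freq.detail  # <0.1% of 2,988 means at most 2 carriers

    def test_all_gates_always_evaluated(self):
        _, audit = self.run([consensus(end=5_000)])  # fails size immediately
        gates = {a.gate for a in audit}
        assert gates == {"size", "probes", "stable_coverage", "frequency:c"}

    def test_no_cohorts_is_error(self):
        with pytest.raises(ValueError, match="cohort"):
            apply_rare_filters([consensus()], [], WHOLE_GENOME, dense_probes())

    def test_removing_a_cohort_never_shrinks_survivors(self):
        calls = [consensus(), consensus(start=200_000, end=400_000)]
        noisy = ControlCohortIndex("noisy", 100, [
            make_call("chr1", 200_000, 400_000, "del", sample=f"K{i}",
                      caller="control") for i in range(5)])
        both, _ = apply_rare_filters(calls, [self.empty_cohort(), noisy],
                                     WHOLE_GENOME, dense_probes())
        fewer, _ = apply_rare_filters(calls, [self.empty_cohort()],
                                      WHOLE_GENOME, dense_probes())
        assert {repr(s) for s in both} <= {repr(s) for s in fewer}

    @given(st.integers(0, 2**31 - 1))
    def test_tightening_any_gate_shrinks_survivors(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        calls = []
        for i in range(15):
            start = int(rng.integers(0, 5_000_000))
            size = int(rng.integers(5_000, 300_000))
            calls.append(consensus("chr1", start, start + size,
                                   "del" if rng.random() < 0.5 else "dup",
                                   sample=f"S{i}"))
        control = [make_call("chr1", int(rng.integers(0, 5_000_000)),
                             int(rng.integers(5_000_001, 5_400_000)), "del",
                             sample=f"K{i}", caller="control")
                   for i in range(20)]
        cohort = ControlCohortIndex("c", 50, control)
        stable = [Region(gi("chr1", 0, int(rng.integers(2_000_000, 10_000_000))))]
        weak = RareFilterConfig(max_control_freq=0.5, min_stable_coverage=0.5,
                                min_probes=2, min_size_bp=6_000)
        survivors_weak, _ = apply_rare_filters(calls, [cohort], stable,
                                               dense_probes(), weak)
        for field, tight_value in [("max_control_freq", 0.01),
                                   ("min_stable_coverage", 0.9),
                                   ("min_probes", 20),
                                   ("min_size_bp", 50_000)]:
            tight = dataclasses.replace(weak, **{field: tight_value})
            survivors_tight, _ = apply_rare_filters(calls, [cohort], stable,
                                                    dense_probes(), tight)
            assert {repr(s) for s in survivors_tight} <= {repr(s) for s in survivors_weak}
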