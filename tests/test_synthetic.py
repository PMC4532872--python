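"""Generator contracts: determinism, planted structure, caller error models."""

import dataclasses
import filecmp
from pathlib import Path

import pytest

from triocnv.intervals import reciprocal_overlap, stitch_fragments
from triocnv.synthetic import (
    CallerModel, SimConfig, generate_bundle, simulate_caller_outputs,
    simulate_phenotypes_and_qc, simulate_truth_cohort,
)

SMALL = dict(n_trios=12, n_controls_per_cohort=(150,))


def small_zero_noise(seed=5, **kw):
    return SimConfig.zero_noise(seed=seed, **{**SMALL, **kw})


class TestTruthCohort:
    def test_de_novo_trio_count_forced_by_rounding(self):
        ledger = simulate_truth_cohort(SimConfig.zero_noise(seed=3, n_trios=115,
                                                            n_controls_per_cohort=(50,)))
        assert len(ledger.de_novo_children) == 8  # round(8/115 * 115)
        assert len(ledger.inherited_clinical_children) == 3

    def test_polymorphic_frequency_one_means_every_parent_carries(self):
        cfg = small_zero_noise()
        poly = tuple(dataclasses.replace(r, frequency=1.0)
                     for r in cfg.polymorphic_regions[:2])
        cfg = dataclasses.replace(cfg, polymorphic_regions=poly)
        ledger = simulate_truth_cohort(cfg)
        for trio in ledger.trios:
            for parent in (trio.father_id, trio.mother_id):
                carried = {(e.interval.chrom, e.interval.start)
                           for e in ledger.events[parent]
                           if e.origin == "polymorphic"}
                assert len(carried) == 2

    def test_rare_inherited_child_events_have_exact_parental_copy(self):
        ledger = simulate_truth_cohort(small_zero_noise())
        for trio in ledger.trios:
            for e in ledger.events[trio.child_id]:
                if not e.origin.startswith("rare_inherited"):
                    continue
                parent = (trio.father_id if e.origin.endswith("father")
                          else trio.mother_id)
                ros = [reciprocal_overlap(e.interval, pe.interval)
                       for pe in ledger.events[parent]
                       if pe.cnv_type == e.cnv_type]
                assert max(ros) == 1.0

    def test_de_novo_events_absent_from_both_parents(self):
        ledger = simulate_truth_cohort(small_zero_noise())
        for trio in ledger.trios:
            for e in ledger.events[trio.child_id]:
                if e.origin != "de_novo":
                    continue
                for parent in (trio.father_id, trio.mother_id):
                    for pe in ledger.events[parent]:
                        if pe.cnv_type == e.cnv_type:
                            assert reciprocal_overlap(e.interval, pe.interval) < 0.5


class TestCallerOutputs:
    def test_zero_noise_reproduces_ledger_for_every_caller(self):
        cfg = small_zero_noise()
        ledger = simulate_truth_cohort(cfg)
        calls = simulate_caller_outputs(ledger, cfg)
        assert ledger.fp_records == []
        by_caller_sample = {}
        for c in calls:
            by_caller_sample.setdefault((c.sample_id, c.caller), set()).add(
                (c.interval.chrom, c.interval.start, c.interval.end, c.cnv_type))
        for sid, events in ledger.events.items():
            truth = {(e.interval.chrom, e.interval.start, e.interval.end,
                      e.cnv_type) for e in events}
            for caller in cfg.caller_models:
                assert by_caller_sample.get((sid, caller), set()) == truth

    def test_zero_sensitivity_caller_emits_only_false_positives(self):
        cfg = small_zero_noise()
        models = dict(cfg.caller_models)
        models["quantisnp"] = CallerModel(sensitivity=0.0, fp_rate=1.0,
                                          boundary_jitter_sd=0.0,
                                          fragmentation_prob=0.0,
                                          stringent_prob=1.0)
        cfg = dataclasses.replace(cfg, caller_models=models)
        ledger = simulate_truth_cohort(cfg)
        calls = simulate_caller_outputs(ledger, cfg)
        q_calls = [c for c in calls if c.caller == "quantisnp"]
        fps = {(c.sample_id, c.interval.chrom, c.interval.start)
               for c in ledger.fp_records if c.caller == "quantisnp"}
        assert q_calls and all(
            (c.sample_id, c.interval.chrom, c.interval.start) in fps
            for c in q_calls)

    def test_forced_fragmentation_stitches_back_to_truth(self):
        cfg = small_zero_noise()
        models = {name: CallerModel(sensitivity=1.0, fp_rate=0.0,
                                    boundary_jitter_sd=0.0,
                                    fragmentation_prob=1.0, stringent_prob=1.0)
                  for name in cfg.caller_models}
        cfg = dataclasses.replace(cfg, caller_models=models)
        ledger = simulate_truth_cohort(cfg)
        calls = simulate_caller_outputs(ledger, cfg)
        large = [(sid, e) for sid, evs in ledger.events.items() for e in evs
                 if e.interval.length > 2_000_000]
        assert large, "fixture must contain at least one fragmentable event"
        for sid, event in large:
            fragments = [c for c in calls
                         if c.sample_id == sid and c.caller == "ipattern"
                         and c.cnv_type == event.cnv_type
                         and c.interval.chrom == event.interval.chrom
                         and c.interval.start >= event.interval.start
                         and c.interval.end <= event.interval.end]
            assert len(fragments) >= 2
            stitched = stitch_fragments(fragments)
            assert len(stitched) == 1
            merged = stitched[0].interval
            assert merged.start == event.interval.start
            assert merged.end == event.interval.end

    def test_jitter_never_inverts_intervals(self):
        cfg = small_zero_noise()
        models = {name: CallerModel(sensitivity=1.0, fp_rate=0.0,
                                    boundary_jitter_sd=50_000.0,
                                    fragmentation_prob=0.0, stringent_prob=1.0)
                  for name in cfg.caller_models}
        cfg = dataclasses.replace(cfg, caller_models=models)
        ledger = simulate_truth_cohort(cfg)
        for c in simulate_caller_outputs(ledger, cfg):
            assert c.interval.end > c.interval.start


class TestPhenotypesAndQc:
    def test_forced_probabilities_leave_no_mild_carriers(self):
        cfg = dataclasses.replace(small_zero_noise(n_trios=40),
                                  severe_gmfcs_prob_base=0.0,
                                  severe_gmfcs_prob_large_de_novo=1.0,
                                  gmfcs_unknown_rate=0.0)
        ledger = simulate_truth_cohort(cfg)
        phen, _ = simulate_phenotypes_and_qc(ledger, cfg)
        carriers = {t.child_id for t in ledger.trios
                    if any(e.origin == "de_novo"
                           and e.interval.length >= cfg.large_cnv_bp
                           for e in ledger.events[t.child_id])}
        assert carriers
        for p in phen:
            severe = p.gmfcs in ("IV", "V")
            assert severe == (p.sample_id in carriers)

    def test_zero_outlier_rate_excludes_nobody(self):
        from triocnv.qc import filter_samples

        cfg = small_zero_noise(n_trios=40)
        ledger = simulate_truth_cohort(cfg)
        _, metrics = simulate_phenotypes_and_qc(ledger, cfg)
        report = filter_samples(metrics)
        assert report.excluded == {}

    def test_outliers_are_flagged(self):
        from triocnv.qc import filter_samples

        cfg = dataclasses.replace(small_zero_noise(n_trios=40),
                                  qc_outlier_rate=0.1)
        ledger = simulate_truth_cohort(cfg)
        _, metrics = simulate_phenotypes_and_qc(ledger, cfg)
        report = filter_samples(metrics)
        assert len(report.excluded) > 0


class TestDeterminism:
    def test_bundles_are_byte_identical_for_same_seed(self, tmp_path):
        cfg = small_zero_noise(seed=9)
        generate_bundle(cfg, tmp_path / "a")
        generate_bundle(cfg, tmp_path / "b")
        files = ["calls.tsv", "pedigree.ped", "probes.tsv", "qc_metrics.tsv",
                 "phenotypes.tsv", "truth_ledger.tsv", "manifest.yaml",
                 "genes.bed", "known_loci.bed", "stable_regions.bed",
                 "controls/manifest.tsv", "controls/cohort1.tsv"]
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", files, shallow=False)
        assert mismatch == [] and errors == []
        assert sorted(match) == sorted(files)

    def test_different_seeds_differ(self, tmp_path):
        generate_bundle(small_zero_noise(seed=9), tmp_path / "a")
        generate_bundle(small_zero_noise(seed=10), tmp_path / "b")
        assert (tmp_path / "a" / "calls.tsv").read_text() != \
            (tmp_path / "b" / "calls.tsv").read_text()
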