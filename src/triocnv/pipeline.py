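"""Stage orchestration: QC → stitch → consensus → rare filter → trio
inheritance → clinical tiering → cohort report.

Every stage writes a TSV with a provenance header (pipeline version, config
hash, seed); rerunning with unchanged inputs and config reproduces
byte-identical outputs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import classify as classify_mod
from . import io_model, qc as qc_mod, stats as stats_mod
from .consensus import ConsensusCnv, consensus_call_set, match_calls_across_callers
from .intervals import stitch_fragments
from .io_model import CnvCall, TrioRecord
from .rare_filter import ControlCohortIndex, RareFilterConfig, apply_rare_filters
from .trio import InheritanceVerdict, classify_inheritance, de_novo_summary

__all__ = ["PipelineConfig", "StageError", "run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str, kind: str = "data"):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage
        self.kind = kind  # config | data | internal


@dataclass
class PipelineConfig:
    calls: str = "calls.tsv"
    pedigree: str = "pedigree.ped"
    control_manifest: str = "controls/manifest.tsv"
    stable_regions: str = "stable_regions.bed"
    genes: str = "genes.bed"
    known_loci: str = "known_loci.bed"
    probes: str = "probes.tsv"
    qc_metrics: str = "qc_metrics.tsv"
    phenotypes: str = "phenotypes.tsv"
    dialect: str = "one_based_inclusive"
    qc: qc_mod.QcThresholds = field(default_factory=qc_mod.QcThresholds)
    max_gap_bp: int = 100_000
    max_gap_fraction: float = 0.2
    consensus_min_ro: float = 0.5
    rare: RareFilterConfig = field(default_factory=RareFilterConfig)
    trio_min_ro: float = 0.5
    tier: classify_mod.TierRules = field(default_factory=classify_mod.TierRules)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = Path(path).parent
        kwargs: Dict = {}
        for key in ("calls", "pedigree", "control_manifest", "stable_regions",
                    "genes", "known_loci", "probes", "qc_metrics", "phenotypes"):
            if key in raw:
                p = Path(raw[key])
                kwargs[key] = str(p if p.is_absolute() else base / p)
        for key in ("dialect", "max_gap_bp", "max_gap_fraction",
                    "consensus_min_ro", "trio_min_ro", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "qc" in raw:
            kwargs["qc"] = qc_mod.QcThresholds(**raw["qc"])
        if "rare" in raw:
            kwargs["rare"] = RareFilterConfig(**raw["rare"])
        if "tier" in raw:
            kwargs["tier"] = classify_mod.TierRules(**raw["tier"])
        return cls(**kwargs)

    _PATH_FIELDS = ("calls", "pedigree", "control_manifest", "stable_regions",
                    "genes", "known_loci", "probes", "qc_metrics", "phenotypes")

    def to_dict(self) -> Dict:
        """Analysis parameters only — the provenance hash fingerprints the
        configuration, not where the input files happen to live."""
        d = {k: v for k, v in vars(self).items()
             if k not in self._PATH_FIELDS
             and not isinstance(v, (qc_mod.QcThresholds, RareFilterConfig,
                                    classify_mod.TierRules))}
        d["qc"] = vars(self.qc).copy()
        d["rare"] = vars(self.rare).copy()
        d["tier"] = vars(self.tier).copy()
        return d

    def provenance(self) -> Dict:
        return {"seed": self.seed, "config_hash": io_model.config_hash(self.to_dict())}


def _stitch_all(calls: Sequence[CnvCall], config: PipelineConfig) -> Dict[str, List[CnvCall]]:
    """Stitch fragments per (sample, caller); returns calls grouped by sample."""
    by_sample_caller: Dict[Tuple[str, str], List[CnvCall]] = defaultdict(list)
    for c in calls:
        by_sample_caller[(c.sample_id, c.caller)].append(c)
    by_sample: Dict[str, List[CnvCall]] = defaultdict(list)
    for (sample, _caller), group in sorted(by_sample_caller.items()):
        by_sample[sample].extend(
            stitch_fragments(group, config.max_gap_bp, config.max_gap_fraction)
        )
    return by_sample


def _consensus_for(sample_calls: Sequence[CnvCall], min_ro: float,
                   child_sex: str = "unknown") -> List[ConsensusCnv]:
    groups = match_calls_across_callers(sample_calls, min_ro)
    return consensus_call_set(groups, child_sex)


def run_all(config: PipelineConfig, outdir) -> Dict:
    """Execute every stage, write per-stage TSVs plus report.txt, and return
    the cohort summary as a dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()

    # --- load -------------------------------------------------------------
    try:
        loaded = io_model.load_call_set(config.calls, config.dialect)
        pedigree = io_model.load_pedigree(config.pedigree)
        stable = io_model.load_bed_regions(config.stable_regions)
        genes = io_model.load_bed_regions(config.genes)
        known_loci = io_model.load_bed_regions(config.known_loci)
        probes = io_model.load_probe_map(config.probes)
        phenotypes = io_model.load_phenotypes(config.phenotypes)
    except (OSError, ValueError) as exc:
        raise StageError("load", str(exc)) from exc
    try:
        manifest = io_model.load_control_manifest(config.control_manifest)
        cohorts = []
        for name, path, n in manifest:
            cohorts.append(ControlCohortIndex(
                name, n, io_model.load_call_set(path, config.dialect).calls))
    except (OSError, ValueError) as exc:
        raise StageError("rare_filter", f"control cohorts unavailable: {exc}") from exc

    # --- qc ---------------------------------------------------------------
    try:
        metrics = io_model.load_qc_metrics(config.qc_metrics)
        qc_report = qc_mod.filter_samples(metrics, config.qc)
    except (OSError, ValueError) as exc:
        raise StageError("qc", str(exc)) from exc
    passing = set(qc_report.passing)
    _write_qc(qc_report, outdir / "qc_report.tsv", prov)

    complete_trios = [t for t in pedigree.trios
                      if {t.child_id, t.father_id, t.mother_id} <= passing]
    dropped_trios = [t.family_id for t in pedigree.trios if t not in complete_trios]

    # --- stitch + consensus ----------------------------------------------
    try:
        study_calls = [c for c in loaded.calls if c.sample_id in passing]
        by_sample = _stitch_all(study_calls, config)
        sex_by_child = {t.child_id: t.child_sex for t in complete_trios}
        consensus_by_sample: Dict[str, List[ConsensusCnv]] = {}
        for t in complete_trios:
            for sid in (t.child_id, t.father_id, t.mother_id):
                consensus_by_sample[sid] = _consensus_for(
                    by_sample.get(sid, []), config.consensus_min_ro,
                    sex_by_child.get(sid, "unknown"))
    except ValueError as exc:
        raise StageError("consensus", str(exc)) from exc
    child_consensus = [c for t in complete_trios for c in consensus_by_sample[t.child_id]]
    io_model.write_consensus_set(child_consensus, outdir / "consensus_children.tsv", prov)

    # --- rare filter ------------------------------------------------------
    try:
        survivors, audit = apply_rare_filters(
            child_consensus, cohorts, stable, probes, config.rare)
    except ValueError as exc:
        raise StageError("rare_filter", str(exc)) from exc
    io_model.write_gate_audit(audit, outdir / "rare_filter_audit.tsv", prov)
    io_model.write_consensus_set(survivors, outdir / "rare_survivors.tsv", prov)

    # --- trio inheritance -------------------------------------------------
    trio_by_child = {t.child_id: t for t in complete_trios}
    verdicts_by_trio: Dict[str, List[InheritanceVerdict]] = {
        t.family_id: [] for t in complete_trios}
    verdicts: List[InheritanceVerdict] = []
    for call in survivors:
        t = trio_by_child[call.sample_id]
        v = classify_inheritance(
            call,
            by_sample.get(t.father_id, []),
            by_sample.get(t.mother_id, []),
            config.trio_min_ro,
        )
        verdicts.append(v)
        verdicts_by_trio[t.family_id].append(v)
    io_model.write_verdicts(verdicts_by_trio, outdir / "verdicts.tsv", prov)

    # --- clinical classification -------------------------------------------
    variants = classify_mod.build_classified_variants(
        verdicts, genes, known_loci, config.tier)
    io_model.write_classified_variants(variants, outdir / "classified_variants.tsv", prov)

    # --- cohort report ------------------------------------------------------
    summary = summarize(
        variants=variants,
        verdicts_by_trio=verdicts_by_trio,
        complete_trios=complete_trios,
        consensus_by_sample=consensus_by_sample,
        phenotypes=phenotypes,
        large_cnv_bp=config.tier.large_cnv_bp,
    )
    summary["qc_excluded"] = sorted(qc_report.excluded)
    summary["trios_dropped_by_qc"] = sorted(dropped_trios)
    _write_report(summary, outdir / "report.txt", prov)
    return summary


def summarize(
    variants: Sequence[classify_mod.ClassifiedVariant],
    verdicts_by_trio: Dict[str, List[InheritanceVerdict]],
    complete_trios: Sequence[TrioRecord],
    consensus_by_sample: Dict[str, List[ConsensusCnv]],
    phenotypes: Sequence[io_model.PhenotypeRecord],
    large_cnv_bp: int = 5_000_000,
) -> Dict:
    """Headline cohort statistics from classified variants."""
    n_trios = len(complete_trios)
    dn = de_novo_summary(verdicts_by_trio)

    child_of = {t.family_id: t.child_id for t in complete_trios}
    inherited_clinical_trios = sorted({
        v.consensus.sample_id for v in variants
        if v.known_locus_hits and v.inheritance.status in
        ("maternal", "paternal", "biparental")
    })
    de_novo_children = sorted({
        child_of[fam] for fam, vs in verdicts_by_trio.items()
        if any(v.status == "de_novo" for v in vs)
    })
    impacted = sorted(set(de_novo_children) | set(inherited_clinical_trios))

    large_dn_carriers = sorted({
        v.consensus.sample_id for v in variants
        if v.inheritance.status == "de_novo"
        and v.consensus.interval.length >= large_cnv_bp
    })
    table = stats_mod.build_severity_table(large_dn_carriers, phenotypes)
    fisher_p = None
    if table.total > 0 and (table.a + table.c) > 0:
        fisher_p = stats_mod.fisher_exact_two_sided(table)

    # Burden comparison: per-sample consensus call count and mean size,
    # probands vs parents.
    child_ids = {t.child_id for t in complete_trios}
    counts_child, counts_parent, sizes_child, sizes_parent = [], [], [], []
    for sid, calls in consensus_by_sample.items():
        counts = len(calls)
        sizes = [c.interval.length for c in calls]
        if sid in child_ids:
            counts_child.append(counts)
            if sizes:
                sizes_child.append(sum(sizes) / len(sizes))
        else:
            counts_parent.append(counts)
            if sizes:
                sizes_parent.append(sum(sizes) / len(sizes))
    burden = {}
    try:
        t_stat, p = stats_mod.burden_t_test(counts_child, counts_parent)
        burden["call_count"] = {"t": t_stat, "p": p}
        t_stat, p = stats_mod.burden_t_test(sizes_child, sizes_parent)
        burden["mean_size"] = {"t": t_stat, "p": p}
    except ValueError:
        burden = {}

    tier_counts: Dict[str, int] = defaultdict(int)
    for v in variants:
        tier_counts[v.tier] += 1

    summary = {
        "n_complete_trios": n_trios,
        "n_rare_variants": len(variants),
        "n_trios_with_de_novo": dn.n_trios_with_de_novo,
        "total_de_novo_events": dn.total_de_novo_events,
        "de_novo_children": de_novo_children,
        "inherited_clinical_children": inherited_clinical_trios,
        "n_inherited_clinical_trios": len(inherited_clinical_trios),
        "n_impacted_families": len(impacted),
        "large_de_novo_carriers": large_dn_carriers,
        "n_large_de_novo_carriers": len(large_dn_carriers),
        "tier_counts": dict(tier_counts),
        "severity_table": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
        "fisher_p_severity": fisher_p,
        "burden": burden,
    }
    if n_trios:
        summary["rates"] = {
            "de_novo": stats_mod.rate_report(dn.n_trios_with_de_novo, n_trios),
            "impacted": stats_mod.rate_report(len(impacted), n_trios),
            "inherited_clinical": stats_mod.rate_report(
                len(inherited_clinical_trios), n_trios),
            "large_de_novo": stats_mod.rate_report(len(large_dn_carriers), n_trios),
        }
    return summary


def _write_qc(report: qc_mod.QcReport, path, prov: Dict) -> None:
    import pandas as pd

    rows = [{"sample": s, "status": "pass", "reason": ""} for s in report.passing]
    rows += [{"sample": s, "status": "excluded", "reason": r}
             for s, r in sorted(report.excluded.items())]
    rows.sort(key=lambda r: r["sample"])
    bounds = {f"bounds_{k}": f"{lo:.6g}..{hi:.6g}"
              for k, (lo, hi) in report.bounds.items()}
    io_model._write_table(pd.DataFrame(rows, columns=["sample", "status", "reason"]),
                          path, {**prov, **bounds})


def _write_report(summary: Dict, path, prov: Dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# triocnv {io_model.PIPELINE_VERSION}\n")
        for k in sorted(prov):
            fh.write(f"# {k}: {prov[k]}\n")
        n = summary["n_complete_trios"]
        fh.write(f"complete trios analysed\t{n}\n")
        fh.write(f"rare variants in probands\t{summary['n_rare_variants']}\n")
        if n and "rates" in summary:
            r = summary["rates"]
            fh.write(f"trios with de novo CNV\t{summary['n_trios_with_de_novo']}/{n}"
                     f" ({r['de_novo']})\n")
            fh.write(f"trios with known-locus inherited CNV\t"
                     f"{summary['n_inherited_clinical_trios']}/{n}"
                     f" ({r['inherited_clinical']})\n")
            fh.write(f"families with clinically relevant CNV\t"
                     f"{summary['n_impacted_families']}/{n} ({r['impacted']})\n")
            fh.write(f"large (>=5 Mb) de novo carriers\t"
                     f"{summary['n_large_de_novo_carriers']}/{n}"
                     f" ({r['large_de_novo']})\n")
        t = summary["severity_table"]
        fh.write("severity 2x2 (severe/mild x carrier/non-carrier)\t"
                 f"a={t['a']} b={t['b']} c={t['c']} d={t['d']}\n")
        if summary["fisher_p_severity"] is not None:
            fh.write(f"Fisher two-sided p (severity vs large de novo)\t"
                     f"{summary['fisher_p_severity']:.4f}\n")
        for name, res in summary.get("burden", {}).items():
            fh.write(f"burden t-test ({name}), probands vs parents\t"
                     f"t={res['t']:.3f} p={res['p']:.3f}\n")
        for tier in ("pathogenic", "likely_pathogenic", "vus", "likely_benign"):
            fh.write(f"tier {tier}\t{summary['tier_counts'].get(tier, 0)}\n")
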