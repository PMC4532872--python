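"""Seeded generator of complete pipeline inputs with a ground-truth ledger.

Emulates the statistical structure the trio analysis assumes: parents carry
polymorphic CNVs at population frequencies and transmit each with
probability 0.5; rare inherited events arise per parent genome and are
transmitted likewise; a fixed fraction of trios carries a planted de novo
event (half of them large, mirroring the 4-of-8 large events among 8 de
novo carriers in a 115-trio cohort); a small number of additional trios
inherits a CNV at a known clinical locus.  Control samples draw only
polymorphic and rare background events.  Four caller error models add
sensitivity losses, boundary jitter, fragmentation of large events and
false positives on top of the truth; motor-severity phenotypes are elevated
for carriers of large de novo events.

The genome is scaled (three 100 Mb autosomes plus a 100 Mb X) so fixtures
stay small, but coordinates keep realistic magnitudes so the 10 kb and 5 Mb
size gates remain meaningful.  Identical config and seed give byte-identical
outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .intervals import GenomicInterval, ProbeMap, overlap_length
from .io_model import (
    CnvCall, PhenotypeRecord, Region, SampleQCMetrics, TrioRecord,
    config_hash, write_call_set,
)

__all__ = ["CallerModel", "PolymorphicRegion", "SimConfig", "TrueEvent",
           "TruthLedger", "simulate_truth_cohort", "simulate_caller_outputs",
           "simulate_phenotypes_and_qc", "generate_bundle", "default_genes",
           "default_known_loci"]

DEFAULT_GENOME: Dict[str, int] = {
    "chr1": 200_000_000, "chr2": 150_000_000, "chr3": 120_000_000,
    "chrX": 150_000_000,
}

CP_SUBTYPES = [
    ("spastic_hemiplegia", 0.374), ("spastic_diplegia", 0.231),
    ("spastic_triplegia", 0.041), ("spastic_quadriplegia", 0.211),
    ("ataxic", 0.027), ("dyskinetic", 0.082), ("unknown", 0.034),
]


@dataclass(frozen=True)
class CallerModel:
    sensitivity: float = 0.95
    fp_rate: float = 2.0            # false positives per genome (Poisson mean)
    boundary_jitter_sd: float = 5_000.0
    fragmentation_prob: float = 0.3  # for events > 2 Mb
    stringent_prob: float = 0.9


@dataclass(frozen=True)
class PolymorphicRegion:
    interval: GenomicInterval
    cnv_type: str
    frequency: float


def _default_polymorphic() -> Tuple[PolymorphicRegion, ...]:
    # Polymorphic territory is clustered near the start of each autosome,
    # leaving long CNV-polymorphism-free corridors where very large de novo
    # events can arise without abutting a common variant.
    spec = [
        ("chr1", 2_000_000, "del", 0.30), ("chr1", 6_000_000, "dup", 0.15),
        ("chr1", 10_000_000, "del", 0.10), ("chr1", 14_000_000, "dup", 0.40),
        ("chr2", 3_000_000, "dup", 0.25), ("chr2", 9_000_000, "del", 0.35),
        ("chr2", 15_000_000, "dup", 0.12), ("chr3", 2_000_000, "del", 0.20),
        ("chr3", 8_000_000, "dup", 0.30), ("chr3", 14_000_000, "del", 0.18),
    ]
    out = []
    for i, (chrom, start, typ, freq) in enumerate(spec):
        size = 40_000 + 20_000 * (i % 5)
        out.append(PolymorphicRegion(GenomicInterval(chrom, start, start + size), typ, freq))
    return tuple(out)


def default_known_loci() -> List[Region]:
    """Demo known-pathogenic-locus set (variable-expressivity and syndromic loci)."""
    return [
        Region(GenomicInterval("chr1", 20_000_000, 22_100_000), "1q21.1-like", ()),
        Region(GenomicInterval("chr2", 20_000_000, 21_400_000), "16p13.11-like", ()),
        Region(GenomicInterval("chr3", 18_000_000, 23_800_000), "AS-like", ("dominant",)),
    ]


def default_genes(genome: Dict[str, int], spacing: int = 150_000,
                  gene_len: int = 20_000) -> List[Region]:
    """Deterministic synthetic gene annotation: one gene every ``spacing`` bp."""
    genes: List[Region] = []
    for chrom in sorted(genome):
        n = 0
        pos = 50_000
        while pos + gene_len < genome[chrom]:
            genes.append(Region(GenomicInterval(chrom, pos, pos + gene_len),
                                f"G{chrom[3:]}_{n:04d}"))
            pos += spacing
            n += 1
    return genes


@dataclass
class SimConfig:
    """Study-scale defaults: 115 complete trios, a 2,988-sample primary
    control cohort, de novo events in 8/115 trios (half large), known-locus
    inherited events in 3/115, severe-GMFCS probability 0.22 at baseline and
    0.75 for large-de-novo carriers, 103/115 probands phenotyped."""

    seed: int = 0
    n_trios: int = 115
    n_controls_per_cohort: Tuple[int, ...] = (2988,)
    genome: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENOME))
    probe_spacing_bp: int = 1_200
    polymorphic_regions: Tuple[PolymorphicRegion, ...] = field(
        default_factory=_default_polymorphic)
    rare_inherited_rate: float = 2.0     # events per parent genome
    inherited_clinical_rate: float = 3 / 115  # trios with a known-locus inherited CNV
    de_novo_rate: float = 8 / 115        # fraction of trios with a planted de novo
    de_novo_large_fraction: float = 0.5
    de_novo_small_range: Tuple[int, int] = (20_000, 500_000)
    de_novo_large_range: Tuple[int, int] = (5_000_000, 75_000_000)
    rare_size_range: Tuple[int, int] = (20_000, 1_000_000)
    caller_models: Dict[str, CallerModel] = field(default_factory=lambda: {
        "ipattern": CallerModel(sensitivity=0.96),
        "penncnv": CallerModel(sensitivity=0.95),
        "quantisnp": CallerModel(sensitivity=0.92, fp_rate=3.0),
        "cnvpartition": CallerModel(sensitivity=0.90, fp_rate=3.0),
    })
    qc_outlier_rate: float = 0.0  # the modelled cohort is the post-QC trio set
    gmfcs_unknown_rate: float = 12 / 115
    severe_gmfcs_prob_base: float = 0.22
    severe_gmfcs_prob_large_de_novo: float = 0.75
    large_cnv_bp: int = 5_000_000

    @classmethod
    def zero_noise(cls, **overrides) -> "SimConfig":
        """All callers perfect: sensitivity 1, no jitter/fragmentation/FPs,
        every call stringent. The consensus and trio stages then must recover
        the truth ledger exactly."""
        models = {name: CallerModel(sensitivity=1.0, fp_rate=0.0,
                                    boundary_jitter_sd=0.0, fragmentation_prob=0.0,
                                    stringent_prob=1.0)
                  for name in ("ipattern", "penncnv", "quantisnp", "cnvpartition")}
        cfg = cls(caller_models=models, qc_outlier_rate=0.0)
        return replace(cfg, **overrides)

    def probe_map(self) -> ProbeMap:
        offset = self.probe_spacing_bp // 2
        return ProbeMap({
            chrom: np.arange(offset, length, self.probe_spacing_bp)
            for chrom, length in sorted(self.genome.items())
        })

    def to_dict(self) -> Dict:
        return {
            "seed": self.seed, "n_trios": self.n_trios,
            "n_controls_per_cohort": list(self.n_controls_per_cohort),
            "genome": dict(self.genome), "probe_spacing_bp": self.probe_spacing_bp,
            "rare_inherited_rate": self.rare_inherited_rate,
            "inherited_clinical_rate": self.inherited_clinical_rate,
            "de_novo_rate": self.de_novo_rate,
            "de_novo_large_fraction": self.de_novo_large_fraction,
            "qc_outlier_rate": self.qc_outlier_rate,
            "gmfcs_unknown_rate": self.gmfcs_unknown_rate,
            "severe_gmfcs_prob_base": self.severe_gmfcs_prob_base,
            "severe_gmfcs_prob_large_de_novo": self.severe_gmfcs_prob_large_de_novo,
            "caller_models": {k: vars(v).copy() for k, v in sorted(self.caller_models.items())},
        }


@dataclass(frozen=True)
class TrueEvent:
    sample_id: str
    interval: GenomicInterval
    cnv_type: str
    origin: str  # polymorphic | rare_inherited:<parent> | inherited_clinical:<parent> | de_novo | rare_background
    copy_number: int


@dataclass
class TruthLedger:
    """Ground truth for every simulated genome; the test oracle."""

    config: SimConfig
    trios: List[TrioRecord]
    events: Dict[str, List[TrueEvent]]                 # study samples
    control_events: Dict[str, Dict[str, List[TrueEvent]]]  # cohort -> sample -> events
    de_novo_children: List[str]
    inherited_clinical_children: List[str]
    genes: List[Region]
    known_loci: List[Region]
    fp_records: List[CnvCall] = field(default_factory=list)

    def child_rare_events(self, child_id: str) -> List[TrueEvent]:
        """Planted events expected to survive the rare filter (non-polymorphic)."""
        return [e for e in self.events.get(child_id, [])
                if e.origin not in ("polymorphic", "rare_background")]

    def expected_inheritance(self, event: TrueEvent) -> str:
        if event.origin == "de_novo":
            return "de_novo"
        if ":" in event.origin:
            parent = event.origin.split(":")[1]
            return "paternal" if parent == "father" else "maternal"
        return "biparental"  # polymorphic events may come from either parent


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _weighted_chrom(rng: np.random.Generator, genome: Dict[str, int], size: int) -> str:
    chroms = [c for c in sorted(genome) if genome[c] > size]
    if not chroms:
        raise ValueError(f"no chromosome can host an event of {size} bp")
    weights = np.array([genome[c] for c in chroms], dtype=float)
    return chroms[rng.choice(len(chroms), p=weights / weights.sum())]


def _required_gap(size_a: int, size_b: int) -> int:
    """Smallest distance keeping two same-type calls un-stitchable.

    The stitcher merges same-type calls with gap <= max(100 kb, 0.2 x merged
    span); a gap strictly above 0.25 x (sum of lengths) and above 100 kb can
    never satisfy that, whatever the span, so planted events stay distinct
    calls under zero caller noise.
    """
    return max(100_000, (size_a + size_b) // 4) + 10_000


def _place_interval(
    rng: np.random.Generator,
    genome: Dict[str, int],
    size: int,
    cnv_type: str,
    blocked: Sequence[Tuple[GenomicInterval, Optional[str]]],
    genes: Optional[Sequence[Region]] = None,
    max_tries: int = 500,
    mode: str = "stitch",
) -> GenomicInterval:
    """Uniform placement keeping clear of ``blocked`` entries.

    ``blocked`` entries carry a CNV type, or ``None`` to block both types.
    In ``stitch`` mode (study genomes) same-type blockers must stay outside
    stitch range so planted events remain distinct calls; opposite-type
    events may be adjacent (real genomes show adjacent del+dup patterns)
    but never overlap.  In ``ro`` mode (control genomes) the only
    requirement is reciprocal overlap < 0.5 against same-type blockers, so
    a small control event may sit inside a proband's large one without
    making it look common.  Optionally the placement must overlap >= 1 gene.
    """
    by_chrom: Dict[str, List[Tuple[int, int, Optional[str]]]] = {}
    for b, b_type in blocked:
        by_chrom.setdefault(b.chrom, []).append((b.start, b.end, b_type))
    arrays: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom, rows in by_chrom.items():
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        ends = np.array([r[1] for r in rows], dtype=np.int64)
        lens = ends - starts
        same = np.array([r[2] is None or r[2] == cnv_type for r in rows])
        if mode == "stitch":
            req = np.where(
                same,
                np.maximum(100_000, (size + lens) // 4) + 10_000,
                10_000,
            )
        else:  # "ro": forbid overlap >= 40% of the larger interval
            req = np.where(same, -(0.4 * np.maximum(size, lens)), -np.inf)
        arrays[chrom] = (starts, ends, req)
    gene_arrays: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    if genes is not None:
        for g in genes:
            gene_arrays.setdefault(g.interval.chrom, ([], []))
            gene_arrays[g.interval.chrom][0].append(g.interval.start)
            gene_arrays[g.interval.chrom][1].append(g.interval.end)
        gene_arrays = {c: (np.asarray(s), np.asarray(e))
                       for c, (s, e) in gene_arrays.items()}
    for _ in range(max_tries):
        chrom = _weighted_chrom(rng, genome, size)
        start = int(rng.integers(0, genome[chrom] - size))
        end = start + size
        if chrom in arrays:
            starts, ends, req = arrays[chrom]
            gap = np.maximum(starts - end, start - ends)
            if np.any(gap < req):
                continue
        if genes is not None:
            gs, ge = gene_arrays.get(chrom, (None, None))
            if gs is None or not np.any((gs < end) & (ge > start)):
                continue
        return GenomicInterval(chrom, start, end)
    raise RuntimeError(f"could not place a {size} bp event after {max_tries} tries")


def _copy_number(cnv_type: str, chrom: str, sex: str) -> int:
    hemi = chrom.lower() in ("chrx", "x") and sex == "male"
    if cnv_type == "del":
        return 0 if hemi else 1
    return 2 if hemi else 3


def _log_uniform_size(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(np.exp(rng.uniform(math.log(lo), math.log(hi))))


def simulate_truth_cohort(config: SimConfig) -> TruthLedger:
    """Draw the true CNV content of every trio member and control sample."""
    rng = _rng(config, stage=1)
    genes = default_genes(config.genome)
    known_loci = default_known_loci()

    trios: List[TrioRecord] = []
    events: Dict[str, List[TrueEvent]] = {}
    sexes: Dict[str, str] = {}
    for i in range(1, config.n_trios + 1):
        sex = "male" if rng.random() < 0.5 else "female"
        trio = TrioRecord(
            family_id=f"F{i:03d}", child_id=f"T{i:03d}C",
            father_id=f"T{i:03d}F", mother_id=f"T{i:03d}M", child_sex=sex,
        )
        trios.append(trio)
        sexes[trio.child_id] = sex
        sexes[trio.father_id] = "male"
        sexes[trio.mother_id] = "female"
        for sid in (trio.child_id, trio.father_id, trio.mother_id):
            events[sid] = []

    # Polymorphic events: parents draw per population frequency; children
    # inherit each parental event with probability 0.5.
    for trio in trios:
        for region in config.polymorphic_regions:
            carried_by = []
            for parent, tag in ((trio.father_id, "father"), (trio.mother_id, "mother")):
                if rng.random() < region.frequency:
                    events[parent].append(TrueEvent(
                        parent, region.interval, region.cnv_type, "polymorphic",
                        _copy_number(region.cnv_type, region.interval.chrom, sexes[parent]),
                    ))
                    carried_by.append(tag)
            transmitted = [tag for tag in carried_by if rng.random() < 0.5]
            if transmitted:
                events[trio.child_id].append(TrueEvent(
                    trio.child_id, region.interval, region.cnv_type, "polymorphic",
                    _copy_number(region.cnv_type, region.interval.chrom, sexes[trio.child_id]),
                ))

    # Universal blockers: polymorphic territory and known loci are kept out
    # of stitch range of every planted event, whatever its type.
    fixed_blocks: List[Tuple[GenomicInterval, Optional[str]]] = (
        [(l.interval, None) for l in known_loci]
        + [(r.interval, None) for r in config.polymorphic_regions]
    )

    def family_blocks(trio: TrioRecord) -> List[Tuple[GenomicInterval, Optional[str]]]:
        return [(e.interval, e.cnv_type)
                for sid in (trio.child_id, trio.father_id, trio.mother_id)
                for e in events[sid]]

    # Planted de novo and known-locus inherited trios (disjoint sets), placed
    # before the rare-inherited background so the very large events still
    # find room.
    n_de_novo = int(round(config.de_novo_rate * config.n_trios))
    n_clinical = int(round(config.inherited_clinical_rate * config.n_trios))
    order = rng.permutation(config.n_trios)
    de_novo_trios = [trios[i] for i in sorted(order[:n_de_novo])]
    clinical_trios = [trios[i] for i in sorted(order[n_de_novo:n_de_novo + n_clinical])]

    for trio in de_novo_trios:
        large = rng.random() < config.de_novo_large_fraction
        lo, hi = config.de_novo_large_range if large else config.de_novo_small_range
        size = _log_uniform_size(rng, lo, hi)
        cnv_type = "del" if rng.random() < 0.5 else "dup"
        iv = _place_interval(rng, config.genome, size, cnv_type,
                             family_blocks(trio) + fixed_blocks, genes=genes)
        events[trio.child_id].append(TrueEvent(
            trio.child_id, iv, cnv_type, "de_novo",
            _copy_number(cnv_type, iv.chrom, sexes[trio.child_id])))

    for trio in clinical_trios:
        candidates = [l for l in known_loci if "dominant" not in l.flags]
        locus = candidates[int(rng.integers(len(candidates)))]
        parent, tag = ((trio.father_id, "father") if rng.random() < 0.5
                       else (trio.mother_id, "mother"))
        cnv_type = "del" if rng.random() < 0.5 else "dup"
        for sid in (parent, trio.child_id):
            events[sid].append(TrueEvent(
                sid, locus.interval, cnv_type, f"inherited_clinical:{tag}",
                _copy_number(cnv_type, locus.interval.chrom, sexes[sid])))

    # Rare inherited background: Poisson per parent genome, transmitted with
    # probability 0.5, kept out of stitch range of every same-type family event.
    for trio in trios:
        blocks = family_blocks(trio) + fixed_blocks
        for parent, tag in ((trio.father_id, "father"), (trio.mother_id, "mother")):
            for _ in range(int(rng.poisson(config.rare_inherited_rate))):
                size = _log_uniform_size(rng, *config.rare_size_range)
                cnv_type = "del" if rng.random() < 0.5 else "dup"
                iv = _place_interval(rng, config.genome, size, cnv_type, blocks)
                blocks.append((iv, cnv_type))
                events[parent].append(TrueEvent(
                    parent, iv, cnv_type, f"rare_inherited:{tag}",
                    _copy_number(cnv_type, iv.chrom, sexes[parent])))
                if rng.random() < 0.5:
                    events[trio.child_id].append(TrueEvent(
                        trio.child_id, iv, cnv_type, f"rare_inherited:{tag}",
                        _copy_number(cnv_type, iv.chrom, sexes[trio.child_id])))

    # Control samples: polymorphic + rare background only.  Background
    # placement stays below 50% reciprocal overlap with every planted study
    # event: the planted events are rare by definition, and on a scaled
    # genome chance collisions would otherwise push them over the carrier
    # threshold regularly.
    study_blocks: List[Tuple[GenomicInterval, Optional[str]]] = [
        (e.interval, e.cnv_type)
        for sid in sorted(events)
        for e in events[sid] if e.origin != "polymorphic"
    ]
    control_events: Dict[str, Dict[str, List[TrueEvent]]] = {}
    for ci, n_controls in enumerate(config.n_controls_per_cohort):
        cohort = f"cohort{ci + 1}"
        control_events[cohort] = {}
        for j in range(1, n_controls + 1):
            sid = f"K{ci + 1}_{j:05d}"
            evs: List[TrueEvent] = []
            sex = "male" if rng.random() < 0.5 else "female"
            for region in config.polymorphic_regions:
                if rng.random() < region.frequency:
                    evs.append(TrueEvent(
                        sid, region.interval, region.cnv_type, "polymorphic",
                        _copy_number(region.cnv_type, region.interval.chrom, sex)))
            blocked = ([(e.interval, e.cnv_type) for e in evs]
                       + [(l.interval, None) for l in known_loci]
                       + study_blocks)
            for _ in range(int(rng.poisson(config.rare_inherited_rate))):
                size = _log_uniform_size(rng, *config.rare_size_range)
                cnv_type = "del" if rng.random() < 0.5 else "dup"
                iv = _place_interval(rng, config.genome, size, cnv_type, blocked,
                                     mode="ro")
                blocked.append((iv, cnv_type))
                evs.append(TrueEvent(sid, iv, cnv_type, "rare_background",
                                     _copy_number(cnv_type, iv.chrom, sex)))
            control_events[cohort][sid] = evs

    return TruthLedger(
        config=config, trios=trios, events=events, control_events=control_events,
        de_novo_children=[t.child_id for t in de_novo_trios],
        inherited_clinical_children=[t.child_id for t in clinical_trios],
        genes=genes, known_loci=known_loci,
    )


def _emit_event(
    rng: np.random.Generator,
    event: TrueEvent,
    caller: str,
    model: CallerModel,
    probes: ProbeMap,
    genome: Dict[str, int],
) -> List[CnvCall]:
    iv = event.interval
    if model.boundary_jitter_sd > 0:
        # Truncated jitter: each boundary moves at most 40% of the event
        # length, so the emitted interval can never invert.
        bound = 0.4 * iv.length
        js = float(np.clip(rng.normal(0, model.boundary_jitter_sd), -bound, bound))
        je = float(np.clip(rng.normal(0, model.boundary_jitter_sd), -bound, bound))
        start = max(0, int(iv.start + js))
        end = min(genome[iv.chrom], int(iv.end + je))
        if end <= start:  # pragma: no cover - excluded by truncation
            end = start + 1
        iv = GenomicInterval(iv.chrom, start, end)
    pieces = [iv]
    if iv.length > 2_000_000 and rng.random() < model.fragmentation_prob:
        k = int(rng.integers(2, 5))
        cuts = np.sort(rng.uniform(0.15, 0.85, size=k - 1)) * iv.length
        gap = min(50_000, int(0.05 * iv.length / k))
        bounds = [iv.start] + [int(iv.start + c) for c in cuts] + [iv.end]
        pieces = []
        for s, e in zip(bounds[:-1], bounds[1:]):
            e_adj = e - gap if e != iv.end else e
            if e_adj > s:
                pieces.append(GenomicInterval(iv.chrom, s, e_adj))
    calls = []
    for piece in pieces:
        n_probes = probes.count_in(piece)
        if n_probes < 1:
            continue
        calls.append(CnvCall(
            sample_id=event.sample_id, caller=caller, interval=piece,
            cnv_type=event.cnv_type, copy_number=event.copy_number,
            confidence=round(float(rng.uniform(0.5, 1.0)), 4),
            n_probes=n_probes,
            stringent=bool(rng.random() < model.stringent_prob),
        ))
    return calls


def simulate_caller_outputs(
    ledger: TruthLedger, config: Optional[SimConfig] = None
) -> List[CnvCall]:
    """Per-sample, per-caller calls for the study samples (trio members).

    Every emitted call traces to a true event or to a false-positive record
    kept in ``ledger.fp_records``.
    """
    config = config or ledger.config
    rng = _rng(config, stage=2)
    probes = config.probe_map()
    calls: List[CnvCall] = []
    ledger.fp_records = []
    for sid in sorted(ledger.events):
        for caller in sorted(config.caller_models):
            model = config.caller_models[caller]
            for event in ledger.events[sid]:
                if rng.random() < model.sensitivity:
                    calls.extend(_emit_event(rng, event, caller, model, probes,
                                             config.genome))
            for _ in range(int(rng.poisson(model.fp_rate))):
                size = _log_uniform_size(rng, 10_000, 200_000)
                chrom = _weighted_chrom(rng, config.genome, size)
                start = int(rng.integers(0, config.genome[chrom] - size))
                iv = GenomicInterval(chrom, start, start + size)
                n_probes = probes.count_in(iv)
                if n_probes < 1:
                    continue
                fp = CnvCall(
                    sample_id=sid, caller=caller, interval=iv,
                    cnv_type="del" if rng.random() < 0.5 else "dup",
                    copy_number=None,
                    confidence=round(float(rng.uniform(0.3, 0.8)), 4),
                    n_probes=n_probes,
                    stringent=bool(rng.random() < model.stringent_prob),
                )
                ledger.fp_records.append(fp)
                calls.append(fp)
    return calls


def control_calls(ledger: TruthLedger, cohort: str) -> List[CnvCall]:
    """Control cohorts are published as call sets, not raw caller output:
    emitted 1:1 from the truth (caller name 'control')."""
    calls = []
    for sid in sorted(ledger.control_events[cohort]):
        for event in ledger.control_events[cohort][sid]:
            calls.append(CnvCall(
                sample_id=sid, caller="control", interval=event.interval,
                cnv_type=event.cnv_type, copy_number=event.copy_number,
            ))
    return calls


def simulate_phenotypes_and_qc(
    ledger: TruthLedger, config: Optional[SimConfig] = None
) -> Tuple[List[PhenotypeRecord], List[SampleQCMetrics]]:
    """Draw GMFCS phenotypes (severity elevated for large-de-novo carriers)
    and per-sample array QC metrics."""
    config = config or ledger.config
    rng = _rng(config, stage=3)
    subtype_names = [s for s, _ in CP_SUBTYPES]
    subtype_p = np.array([p for _, p in CP_SUBTYPES])
    subtype_p = subtype_p / subtype_p.sum()

    phenotypes: List[PhenotypeRecord] = []
    for trio in ledger.trios:
        carrier = any(
            e.origin == "de_novo" and e.interval.length >= config.large_cnv_bp
            for e in ledger.events[trio.child_id]
        )
        subtype = subtype_names[int(rng.choice(len(subtype_names), p=subtype_p))]
        if rng.random() < config.gmfcs_unknown_rate:
            gmfcs = "unknown"
        else:
            p_severe = (config.severe_gmfcs_prob_large_de_novo if carrier
                        else config.severe_gmfcs_prob_base)
            if rng.random() < p_severe:
                gmfcs = ("IV", "V")[int(rng.integers(2))]
            else:
                gmfcs = ("I", "II", "III")[int(rng.integers(3))]
        phenotypes.append(PhenotypeRecord(trio.child_id, gmfcs, subtype))

    # Baseline metrics are drawn from bounded uniforms (±2 reference s.d.):
    # a uniform's sample s.d. is range/sqrt(12) ≈ 1.15 reference s.d., so no
    # baseline draw can sit outside cohort mean ± 3 s.d. and qc_outlier_rate=0
    # really does mean the QC stage excludes nobody.  Outliers are pushed to
    # 6–10 reference s.d. (or a sub-threshold call rate) explicitly.
    metrics: List[SampleQCMetrics] = []
    for sid in sorted(ledger.events):
        call_rate = float(rng.uniform(0.96, 1.0))
        lrr_sd = float(rng.uniform(0.12 - 0.03, 0.12 + 0.03))
        baf_sd = float(rng.uniform(0.03 - 0.008, 0.03 + 0.008))
        if rng.random() < config.qc_outlier_rate:
            which = int(rng.integers(3))
            if which == 0:
                call_rate = float(rng.uniform(0.85, 0.945))
            elif which == 1:
                lrr_sd = 0.12 + 0.015 * float(rng.uniform(6.0, 10.0))
            else:
                baf_sd = 0.03 + 0.004 * float(rng.uniform(6.0, 10.0))
        metrics.append(SampleQCMetrics(sid, round(call_rate, 5),
                                       round(lrr_sd, 5), round(baf_sd, 5)))
    return phenotypes, metrics


def generate_bundle(config: SimConfig, outdir) -> TruthLedger:
    """Generate and write the complete input bundle plus the truth ledger.

    Files: calls.tsv, pedigree.ped, controls/*.tsv + manifest, probes.tsv,
    stable_regions.bed, genes.bed, known_loci.bed, qc_metrics.tsv,
    phenotypes.tsv, truth_ledger.tsv, manifest.yaml.  Deterministic and
    byte-identical for a fixed (config, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "controls").mkdir(exist_ok=True)

    ledger = simulate_truth_cohort(config)
    calls = simulate_caller_outputs(ledger, config)
    phenotypes, metrics = simulate_phenotypes_and_qc(ledger, config)
    prov = {"seed": config.seed, "config_hash": config_hash(config.to_dict())}

    write_call_set(calls, outdir / "calls.tsv", prov)

    with open(outdir / "pedigree.ped", "w") as fh:
        fh.write("family\tindividual\tfather\tmother\tsex\trole\n")
        sex_code = {"male": 1, "female": 2, "unknown": 0}
        for t in ledger.trios:
            fh.write(f"{t.family_id}\t{t.father_id}\t0\t0\t1\tfather\n")
            fh.write(f"{t.family_id}\t{t.mother_id}\t0\t0\t2\tmother\n")
            fh.write(f"{t.family_id}\t{t.child_id}\t{t.father_id}\t{t.mother_id}"
                     f"\t{sex_code[t.child_sex]}\tchild\n")

    with open(outdir / "controls" / "manifest.tsv", "w") as fh:
        fh.write("cohort_name\tpath\tn_samples\n")
        for ci, n in enumerate(config.n_controls_per_cohort):
            cohort = f"cohort{ci + 1}"
            write_call_set(control_calls(ledger, cohort),
                           outdir / "controls" / f"{cohort}.tsv", prov)
            fh.write(f"{cohort}\t{cohort}.tsv\t{n}\n")

    probes = config.probe_map()
    with open(outdir / "probes.tsv", "w") as fh:
        fh.write("chrom\tposition\n")
        for chrom in sorted(config.genome):
            for pos in probes.positions(chrom):
                fh.write(f"{chrom}\t{pos}\n")

    with open(outdir / "stable_regions.bed", "w") as fh:
        fh.write("# copy-number-stable regions (synthetic: whole scaled genome)\n")
        for chrom in sorted(config.genome):
            fh.write(f"{chrom}\t0\t{config.genome[chrom]}\n")

    with open(outdir / "genes.bed", "w") as fh:
        for g in ledger.genes:
            fh.write(f"{g.interval.chrom}\t{g.interval.start}\t{g.interval.end}\t{g.name}\n")

    with open(outdir / "known_loci.bed", "w") as fh:
        for l in ledger.known_loci:
            flags = ",".join(l.flags)
            fh.write(f"{l.interval.chrom}\t{l.interval.start}\t{l.interval.end}"
                     f"\t{l.name}\t{flags}\n")

    with open(outdir / "qc_metrics.tsv", "w") as fh:
        fh.write("sample\tcall_rate\tlrr_sd\tbaf_sd\n")
        for m in metrics:
            fh.write(f"{m.sample_id}\t{m.call_rate}\t{m.lrr_sd}\t{m.baf_sd}\n")

    with open(outdir / "phenotypes.tsv", "w") as fh:
        fh.write("sample\tgmfcs\tcp_subtype\n")
        for p in phenotypes:
            fh.write(f"{p.sample_id}\t{p.gmfcs}\t{p.cp_subtype}\n")

    with open(outdir / "truth_ledger.tsv", "w") as fh:
        fh.write("# coordinates: 0-based half-open\n")
        fh.write("sample\tchrom\tstart\tend\ttype\torigin\tcopy_number\n")
        for sid in sorted(ledger.events):
            for e in sorted(ledger.events[sid],
                            key=lambda e: (e.interval.chrom, e.interval.start)):
                fh.write(f"{sid}\t{e.interval.chrom}\t{e.interval.start}"
                         f"\t{e.interval.end}\t{e.cnv_type}\t{e.origin}"
                         f"\t{e.copy_number}\n")

    manifest = {
        "seed": config.seed,
        "config_hash": config_hash(config.to_dict()),
        "n_trios": config.n_trios,
        "n_controls_per_cohort": list(config.n_controls_per_cohort),
        "de_novo_children": ledger.de_novo_children,
        "inherited_clinical_children": ledger.inherited_clinical_children,
        "files": ["calls.tsv", "pedigree.ped", "controls/manifest.tsv",
                  "probes.tsv", "stable_regions.bed", "genes.bed",
                  "known_loci.bed", "qc_metrics.tsv", "phenotypes.tsv",
                  "truth_ledger.tsv"],
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return ledger
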