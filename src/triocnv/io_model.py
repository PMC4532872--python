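"""Readers/writers for pipeline files and the shared record types.

Three coordinate conventions coexist.  Internally everything is 0-based
half-open.  CNV call tables default to the 1-based inclusive dialect most
array callers print; BED region files are 0-based half-open; output tables
are written 1-based inclusive for human readability.  Conversion happens
only here, at the I/O boundary.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .intervals import GenomicInterval, ProbeMap

PIPELINE_VERSION = "0.1.0"

PRIMARY_CALLERS = ("ipattern", "penncnv")
KNOWN_CALLERS = ("ipattern", "penncnv", "quantisnp", "cnvpartition")
CNV_TYPES = ("del", "dup")
GMFCS_LEVELS = ("I", "II", "III", "IV", "V", "unknown")

CALL_COLUMNS = [
    "sample", "caller", "chrom", "start", "end", "type",
    "copy_number", "confidence", "n_probes", "stringent",
]


@dataclass(frozen=True)
class CnvCall:
    """One CNV interval from one caller on one sample."""

    sample_id: str
    caller: str
    interval: GenomicInterval
    cnv_type: str
    copy_number: Optional[int] = None
    confidence: Optional[float] = None
    n_probes: Optional[int] = None
    stringent: bool = False
    stitched_from: int = 1

    def __post_init__(self) -> None:
        if self.cnv_type not in CNV_TYPES:
            raise ValueError(f"unknown CNV type {self.cnv_type!r}")
        if self.n_probes is not None and self.n_probes < 1:
            raise ValueError("n_probes must be >= 1 when present")


@dataclass(frozen=True)
class TrioRecord:
    """Child plus both biological parents; the unit of segregation analysis."""

    family_id: str
    child_id: str
    father_id: str
    mother_id: str
    child_sex: str = "unknown"  # male / female / unknown

    def __post_init__(self) -> None:
        if len({self.child_id, self.father_id, self.mother_id}) != 3:
            raise ValueError(
                f"family {self.family_id}: child/father/mother ids must be distinct"
            )


@dataclass(frozen=True)
class SampleQCMetrics:
    """Per-sample array quality metrics: call rate and LRR/BAF noise."""

    sample_id: str
    call_rate: float
    lrr_sd: float
    baf_sd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.call_rate <= 1.0:
            raise ValueError("call_rate must be in [0,1]")
        if self.lrr_sd < 0 or self.baf_sd < 0:
            raise ValueError("lrr_sd/baf_sd must be non-negative")


@dataclass(frozen=True)
class PhenotypeRecord:
    sample_id: str
    gmfcs: str = "unknown"
    cp_subtype: str = ""

    def __post_init__(self) -> None:
        if self.gmfcs not in GMFCS_LEVELS:
            raise ValueError(f"unknown GMFCS level {self.gmfcs!r}")


@dataclass(frozen=True)
class Region:
    """Named BED region with optional flags (e.g. 'dominant' for known loci)."""

    interval: GenomicInterval
    name: str = ""
    flags: Tuple[str, ...] = ()


@dataclass
class LoadedCalls:
    calls: List[CnvCall]
    errors: List[str] = field(default_factory=list)


@dataclass
class LoadedPedigree:
    trios: List[TrioRecord]
    incomplete: List[str] = field(default_factory=list)  # family ids lacking a parent
    errors: List[str] = field(default_factory=list)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def load_call_set(path, dialect: str = "one_based_inclusive") -> LoadedCalls:
    """Load a CNV call TSV, normalizing coordinates to 0-based half-open.

    ``dialect`` is ``one_based_inclusive`` (caller convention; a row with
    start=100001, end=250000 spans 150,000 bp) or ``bed_half_open``.
    Malformed rows are collected into ``errors`` rather than aborting the
    load; a missing mandatory column aborts naming the column.
    """
    if dialect not in ("one_based_inclusive", "bed_half_open"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _read_tsv(path)
    for col in CALL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"call set {path}: missing mandatory column {col!r}")
    calls: List[CnvCall] = []
    errors: List[str] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            start, end = int(row.start), int(row.end)
            if dialect == "one_based_inclusive":
                start -= 1
            if end <= start:
                raise ValueError(f"end <= start after normalization ({start},{end})")
            calls.append(CnvCall(
                sample_id=str(row.sample),
                caller=str(row.caller),
                interval=GenomicInterval(str(row.chrom), start, end),
                cnv_type=str(row.type),
                copy_number=int(row.copy_number) if row.copy_number != "" else None,
                confidence=float(row.confidence) if row.confidence != "" else None,
                n_probes=int(row.n_probes) if row.n_probes != "" else None,
                stringent=str(row.stringent) in ("1", "True", "true"),
            ))
        except (ValueError, TypeError) as exc:
            errors.append(f"{path} line {idx}: {exc}")
    calls.sort(key=lambda c: (c.sample_id, c.caller, c.interval.chrom,
                              c.interval.start, c.interval.end, c.cnv_type))
    return LoadedCalls(calls=calls, errors=errors)


def write_call_set(calls: Sequence[CnvCall], path, provenance: Optional[Dict] = None) -> None:
    """Write calls in the 1-based inclusive dialect with a '#' provenance header."""
    rows = []
    for c in sorted(calls, key=lambda c: (c.sample_id, c.caller, c.interval.chrom,
                                          c.interval.start, c.interval.end, c.cnv_type)):
        rows.append({
            "sample": c.sample_id,
            "caller": c.caller,
            "chrom": c.interval.chrom,
            "start": c.interval.start + 1,
            "end": c.interval.end,
            "type": c.cnv_type,
            "copy_number": "" if c.copy_number is None else c.copy_number,
            "confidence": "" if c.confidence is None else repr(c.confidence),
            "n_probes": "" if c.n_probes is None else c.n_probes,
            "stringent": int(c.stringent),
        })
    _write_table(pd.DataFrame(rows, columns=CALL_COLUMNS), path, provenance,
                 extra=["# coordinates: 1-based inclusive"])


def load_pedigree(path) -> LoadedPedigree:
    """Load a PED-like TSV (family, individual, father, mother, sex, role).

    Only complete trios — child with both parents present as rows — become
    :class:`TrioRecord`; incomplete families are reported separately.
    """
    df = _read_tsv(path)
    for col in ("family", "individual", "father", "mother", "sex"):
        if col not in df.columns:
            raise ValueError(f"pedigree {path}: missing mandatory column {col!r}")
    sex_map = {"1": "male", "2": "female", "0": "unknown"}
    individuals = set()
    errors: List[str] = []
    rows = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        if str(row.sex) not in sex_map:
            errors.append(f"{path} line {idx}: invalid sex code {row.sex!r}")
            continue
        if str(row.individual) in (str(row.father), str(row.mother)):
            raise ValueError(
                f"pedigree {path} line {idx}: individual {row.individual} "
                "listed as its own parent"
            )
        individuals.add(str(row.individual))
        rows.append(row)
    trios: List[TrioRecord] = []
    incomplete: List[str] = []
    for row in rows:
        father, mother = str(row.father), str(row.mother)
        if father == "0" and mother == "0":
            continue  # founder
        if father in individuals and mother in individuals:
            trios.append(TrioRecord(
                family_id=str(row.family),
                child_id=str(row.individual),
                father_id=father,
                mother_id=mother,
                child_sex=sex_map[str(row.sex)],
            ))
        else:
            incomplete.append(str(row.family))
    return LoadedPedigree(trios=trios, incomplete=incomplete, errors=errors)


def load_bed_regions(path) -> List[Region]:
    """BED3/BED4(+flags) loader; 0-based half-open; '#' comments ignored."""
    regions: List[Region] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: BED line has <3 columns: {line!r}")
            interval = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            name = parts[3] if len(parts) > 3 else ""
            flags = tuple(parts[4].split(",")) if len(parts) > 4 and parts[4] else ()
            regions.append(Region(interval=interval, name=name, flags=flags))
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
    return regions


def load_probe_map(path) -> ProbeMap:
    """Two-column TSV (chrom, 0-based position); sorted on load."""
    positions: Dict[str, List[int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos = line.split("\t")[:2]
            if chrom == "chrom":
                continue
            positions.setdefault(chrom, []).append(int(pos))
    return ProbeMap(positions)


def load_qc_metrics(path) -> List[SampleQCMetrics]:
    df = _read_tsv(path)
    for col in ("sample", "call_rate", "lrr_sd", "baf_sd"):
        if col not in df.columns:
            raise ValueError(f"QC table {path}: missing mandatory column {col!r}")
    return [
        SampleQCMetrics(str(r.sample), float(r.call_rate), float(r.lrr_sd), float(r.baf_sd))
        for r in df.itertuples(index=False)
    ]


def load_phenotypes(path) -> List[PhenotypeRecord]:
    df = _read_tsv(path)
    for col in ("sample", "gmfcs"):
        if col not in df.columns:
            raise ValueError(f"phenotype table {path}: missing mandatory column {col!r}")
    out = []
    for r in df.itertuples(index=False):
        subtype = str(getattr(r, "cp_subtype", ""))
        out.append(PhenotypeRecord(str(r.sample), str(r.gmfcs), subtype))
    return out


def load_control_manifest(path) -> List[Tuple[str, str, int]]:
    """Manifest TSV (cohort_name, path, n_samples); paths relative to the manifest."""
    df = _read_tsv(path)
    for col in ("cohort_name", "path", "n_samples"):
        if col not in df.columns:
            raise ValueError(f"control manifest {path}: missing mandatory column {col!r}")
    base = Path(path).parent
    out = []
    for r in df.itertuples(index=False):
        p = Path(str(r.path))
        if not p.is_absolute():
            p = base / p
        out.append((str(r.cohort_name), str(p), int(r.n_samples)))
    return out


def write_classified_variants(variants, path, provenance: Optional[Dict] = None) -> None:
    """Write the final variant table, 1-based inclusive, deterministically ordered."""
    rows = []
    for v in variants:
        iv = v.consensus.interval
        rows.append({
            "sample": v.consensus.sample_id,
            "chrom": iv.chrom,
            "start": iv.start + 1,
            "end": iv.end,
            "size_bp": iv.length,
            "type": v.consensus.cnv_type,
            "inheritance": v.inheritance.status,
            "n_genes": v.n_genes,
            "gene_names": ",".join(v.gene_names),
            "known_locus_hits": ";".join(f"{n}:{ro:.3f}" for n, ro, _ in v.known_locus_hits),
            "tier": v.tier,
            "rule_fired": v.rule_fired,
            "supporting_callers": ",".join(sorted(v.consensus.supporting_callers)),
            "filter_audit": v.filter_audit,
        })
    cols = ["sample", "chrom", "start", "end", "size_bp", "type", "inheritance",
            "n_genes", "gene_names", "known_locus_hits", "tier", "rule_fired",
            "supporting_callers", "filter_audit"]
    df = pd.DataFrame(rows, columns=cols)
    if len(df):
        df = df.sort_values(["sample", "chrom", "start", "end"], kind="mergesort")
    _write_table(df, path, provenance, extra=["# coordinates: 1-based inclusive"])


def write_consensus_set(calls, path, provenance: Optional[Dict] = None) -> None:
    """Consensus TSV: CnvCall dialect plus supporting callers and stitch count."""
    rows = []
    for c in sorted(calls, key=lambda c: (c.sample_id, c.interval.chrom,
                                          c.interval.start, c.interval.end, c.cnv_type)):
        rows.append({
            "sample": c.sample_id,
            "chrom": c.interval.chrom,
            "start": c.interval.start + 1,
            "end": c.interval.end,
            "type": c.cnv_type,
            "supporting_callers": ",".join(sorted(c.supporting_callers)),
            "representative_caller": c.representative_caller,
            "stringent_support": int(c.stringent_support),
            "n_probes": "" if c.n_probes is None else c.n_probes,
            "stitched_from": c.stitched_from,
        })
    cols = ["sample", "chrom", "start", "end", "type", "supporting_callers",
            "representative_caller", "stringent_support", "n_probes", "stitched_from"]
    _write_table(pd.DataFrame(rows, columns=cols), path, provenance,
                 extra=["# coordinates: 1-based inclusive"])


def load_consensus_set(path):
    """Inverse of :func:`write_consensus_set`."""
    from .consensus import ConsensusCnv  # local import: avoid a cycle

    df = _read_tsv(path)
    out = []
    for row in df.itertuples(index=False):
        out.append(ConsensusCnv(
            sample_id=str(row.sample),
            interval=GenomicInterval(str(row.chrom), int(row.start) - 1, int(row.end)),
            cnv_type=str(row.type),
            supporting_callers=frozenset(str(row.supporting_callers).split(",")),
            representative_caller=str(row.representative_caller),
            stringent_support=str(row.stringent_support) in ("1", "True", "true"),
            n_probes=int(row.n_probes) if str(row.n_probes) != "" else None,
            stitched_from=int(row.stitched_from),
        ))
    return out


def write_verdicts(verdicts_by_trio: Dict[str, Sequence], path,
                   provenance: Optional[Dict] = None) -> None:
    """Inheritance verdict TSV: trio, child call coordinates, status, per-parent RO."""
    rows = []
    for trio_id in sorted(verdicts_by_trio):
        for v in verdicts_by_trio[trio_id]:
            iv = v.child_call.interval
            rows.append({
                "family": trio_id,
                "sample": v.child_call.sample_id,
                "chrom": iv.chrom,
                "start": iv.start + 1,
                "end": iv.end,
                "type": v.child_call.cnv_type,
                "status": v.status,
                "best_ro_father": f"{v.best_ro_father:.4f}",
                "best_ro_mother": f"{v.best_ro_mother:.4f}",
                "evidence_source": v.parental_evidence_source,
            })
    cols = ["family", "sample", "chrom", "start", "end", "type", "status",
            "best_ro_father", "best_ro_mother", "evidence_source"]
    _write_table(pd.DataFrame(rows, columns=cols), path, provenance,
                 extra=["# coordinates: 1-based inclusive"])


def write_gate_audit(audit, path, provenance: Optional[Dict] = None) -> None:
    """Rare-filter audit TSV: one row per (call, gate)."""
    rows = [{
        "sample": g.sample_id,
        "chrom": g.interval.chrom,
        "start": g.interval.start + 1,
        "end": g.interval.end,
        "type": g.cnv_type,
        "gate": g.gate,
        "value": g.value,
        "threshold": g.threshold,
        "passed": int(g.passed),
        "detail": g.detail,
    } for g in audit]
    cols = ["sample", "chrom", "start", "end", "type", "gate", "value",
            "threshold", "passed", "detail"]
    _write_table(pd.DataFrame(rows, columns=cols), path, provenance,
                 extra=["# coordinates: 1-based inclusive"])


def config_hash(obj) -> str:
    """Stable short hash of a config mapping, recorded in output headers."""
    text = repr(sorted(_flatten(obj))) if isinstance(obj, dict) else repr(obj)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _flatten(d: Dict, prefix: str = ""):
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            yield from _flatten(v, key + ".")
        else:
            yield key, repr(v)


def _write_table(df: pd.DataFrame, path, provenance: Optional[Dict],
                 extra: Optional[List[str]] = None) -> None:
    try:
        with open(path, "w") as fh:
            fh.write(f"# triocnv {PIPELINE_VERSION}\n")
            for line in extra or []:
                fh.write(line + "\n")
            if provenance:
                for k in sorted(provenance):
                    fh.write(f"# {k}: {provenance[k]}\n")
            df.to_csv(fh, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"cannot write output table {path}: {exc}") from exc
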