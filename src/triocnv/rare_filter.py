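"""Rare-variant filtering of consensus CNVs with a complete audit trail.

Four gates, all always evaluated so the audit is complete (no
short-circuit), in the fixed order size → probes → stable-region coverage →
control frequency:

* size strictly greater than 10 kb;
* at least 5 probes inside the call (callers emit runs of consecutive
  probes, so containment implies successiveness);
* strictly more than 75% of the call covered by copy-number-stable regions;
* carrier frequency strictly below 0.1% in EVERY control cohort, carriers
  matched at >= 50% reciprocal overlap and counted per control sample (a
  fragmented control event is not double-counted).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np

from .consensus import ConsensusCnv
from .intervals import GenomicInterval, ProbeMap, count_probes, coverage_fraction
from .io_model import CnvCall, Region

__all__ = ["ControlCohortIndex", "RareFilterConfig", "control_frequency",
           "apply_rare_filters", "GateRecord"]


class ControlCohortIndex:
    """Frequency-queryable index of one control cohort's CNV calls.

    ``n_samples`` is the cohort size (the frequency denominator), which may
    exceed the number of samples that actually carry calls.
    """

    def __init__(self, cohort_name: str, n_samples: int, calls: Iterable[CnvCall]):
        if n_samples < 1:
            raise ValueError("control cohort must contain >= 1 sample")
        self.cohort_name = cohort_name
        self.n_samples = n_samples
        # Columnar per-(chrom, type) index; reciprocal overlap against every
        # same-type control call is a single vectorized pass.  Robust to the
        # thousands of coordinate-identical calls a polymorphic locus stacks up.
        grouped: Dict[Tuple[str, str], List[CnvCall]] = defaultdict(list)
        for c in calls:
            grouped[(c.interval.chrom, c.cnv_type)].append(c)
        self._index: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for key, group in grouped.items():
            starts = np.array([c.interval.start for c in group], dtype=np.int64)
            ends = np.array([c.interval.end for c in group], dtype=np.int64)
            samples = np.array([c.sample_id for c in group], dtype=object)
            self._index[key] = (starts, ends, samples)

    def carriers(self, call: ConsensusCnv, min_ro: float = 0.5) -> Set[str]:
        """Distinct control samples with >= 1 same-type call at RO >= min_ro."""
        entry = self._index.get((call.interval.chrom, call.cnv_type))
        if entry is None:
            return set()
        starts, ends, samples = entry
        ov = np.minimum(ends, call.interval.end) - np.maximum(starts, call.interval.start)
        ro = np.maximum(ov, 0) / np.maximum(ends - starts, call.interval.length)
        return set(samples[ro >= min_ro])


@dataclass(frozen=True)
class RareFilterConfig:
    max_control_freq: float = 0.001
    min_ro_vs_controls: float = 0.5
    min_stable_coverage: float = 0.75
    min_probes: int = 5
    min_size_bp: int = 10_000

    def __post_init__(self) -> None:
        for name in ("max_control_freq", "min_ro_vs_controls", "min_stable_coverage"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0,1]")
        if self.min_probes < 1 or self.min_size_bp < 1:
            raise ValueError("min_probes and min_size_bp must be >= 1")


@dataclass(frozen=True)
class GateRecord:
    """One gate's evaluation for one call: value, threshold and verdict."""

    sample_id: str
    interval: GenomicInterval
    cnv_type: str
    gate: str
    value: float
    threshold: float
    passed: bool
    detail: str = ""


def control_frequency(
    call: ConsensusCnv, cohort: ControlCohortIndex, min_ro: float = 0.5
) -> Tuple[int, float]:
    """Carrier count and frequency of ``call`` in one control cohort."""
    carriers = cohort.carriers(call, min_ro)
    return len(carriers), len(carriers) / cohort.n_samples


def apply_rare_filters(
    calls: Sequence[ConsensusCnv],
    cohorts: Sequence[ControlCohortIndex],
    stable_regions: Sequence[Region],
    probes: ProbeMap,
    config: RareFilterConfig = RareFilterConfig(),
) -> Tuple[List[ConsensusCnv], List[GateRecord]]:
    """Reduce consensus calls to rare variants; audit every gate for every call."""
    if not cohorts:
        raise ValueError("rare filtering requires >= 1 control cohort "
                         "(frequency gate cannot be evaluated)")
    stable = [r.interval for r in stable_regions]
    survivors: List[ConsensusCnv] = []
    audit: List[GateRecord] = []
    for call in calls:
        base = dict(sample_id=call.sample_id, interval=call.interval,
                    cnv_type=call.cnv_type)
        size_ok = call.interval.length > config.min_size_bp
        audit.append(GateRecord(**base, gate="size", value=call.interval.length,
                                threshold=config.min_size_bp, passed=size_ok))
        n_probes = count_probes(call.interval, probes)
        probes_ok = n_probes >= config.min_probes
        audit.append(GateRecord(**base, gate="probes", value=n_probes,
                                threshold=config.min_probes, passed=probes_ok))
        cov = coverage_fraction(call.interval, stable)
        stable_ok = cov > config.min_stable_coverage
        audit.append(GateRecord(**base, gate="stable_coverage", value=cov,
                                threshold=config.min_stable_coverage, passed=stable_ok))
        freq_ok = True
        for cohort in cohorts:
            count, freq = control_frequency(call, cohort, config.min_ro_vs_controls)
            ok = freq < config.max_control_freq
            freq_ok = freq_ok and ok
            max_carriers = _max_carriers(config.max_control_freq, cohort.n_samples)
            audit.append(GateRecord(
                **base, gate=f"frequency:{cohort.cohort_name}", value=freq,
                threshold=config.max_control_freq, passed=ok,
                detail=f"carriers={count}/{cohort.n_samples} (rare means <= {max_carriers})",
            ))
        if size_ok and probes_ok and stable_ok and freq_ok:
            survivors.append(call)
    return survivors, audit


def _max_carriers(max_freq: float, n_samples: int) -> int:
    """Largest carrier count still strictly below max_freq (e.g. 2 of 2,988 at 0.1%)."""
    k = int(max_freq * n_samples)
    if k / n_samples >= max_freq:
        k -= 1
    return max(k, 0)
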