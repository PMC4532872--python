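"""Sample-level array quality control.

Two gates: a minimum genotyping call rate, and per-sample LRR/BAF standard
deviations required to sit within the cohort mean ± k·s.d. (sample s.d.,
n−1 denominator).  Bounds are computed once on the full cohort, including
samples that later fail the call-rate gate; values exactly at a bound pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .io_model import SampleQCMetrics

__all__ = ["QcThresholds", "cohort_metric_bounds", "filter_samples", "QcReport"]


@dataclass(frozen=True)
class QcThresholds:
    min_call_rate: float = 0.95
    sd_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 < self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must be in (0,1]")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be positive")


@dataclass
class QcReport:
    passing: List[str]
    excluded: Dict[str, str] = field(default_factory=dict)  # sample -> first failed gate
    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)


def cohort_metric_bounds(
    metrics: Sequence[SampleQCMetrics], sd_multiplier: float = 3.0
) -> Dict[str, Tuple[float, float]]:
    """Cohort mean ± multiplier·s.d. bounds for lrr_sd and baf_sd."""
    if len(metrics) < 2:
        raise ValueError("cohort bounds need >= 2 samples (s.d. undefined otherwise)")
    bounds: Dict[str, Tuple[float, float]] = {}
    for name in ("lrr_sd", "baf_sd"):
        values = np.array([getattr(m, name) for m in metrics], dtype=float)
        mean, sd = float(values.mean()), float(values.std(ddof=1))
        bounds[name] = (mean - sd_multiplier * sd, mean + sd_multiplier * sd)
    return bounds


def filter_samples(
    metrics: Sequence[SampleQCMetrics], thresholds: QcThresholds = QcThresholds()
) -> QcReport:
    """Partition samples into passing / excluded with the first failed gate.

    Gate order: call_rate, then lrr_sd, then baf_sd.  Bound checks are
    inclusive ("within" the range retains boundary values).
    """
    bounds = cohort_metric_bounds(metrics, thresholds.sd_multiplier)
    report = QcReport(passing=[], bounds=bounds)
    for m in metrics:
        if m.call_rate < thresholds.min_call_rate:
            report.excluded[m.sample_id] = "call_rate"
            continue
        lo, hi = bounds["lrr_sd"]
        if not lo <= m.lrr_sd <= hi:
            report.excluded[m.sample_id] = "lrr_sd"
            continue
        lo, hi = bounds["baf_sd"]
        if not lo <= m.baf_sd <= hi:
            report.excluded[m.sample_id] = "baf_sd"
            continue
        report.passing.append(m.sample_id)
    return report
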