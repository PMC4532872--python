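"""Genomic interval algebra underlying every pipeline stage.

All coordinates are internal 0-based half-open ``[start, end)``; input
dialects (1-based inclusive caller output, BED) are converted at the I/O
boundary.  The operations here — overlap, reciprocal overlap, coverage
against a region set, fragment stitching and probe counting — are the
substrate for consensus calling, frequency filtering and size/probe gates
downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import TYPE_CHECKING, Dict, Iterable, List, Sequence, Tuple

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .io_model import CnvCall

__all__ = [
    "GenomicInterval",
    "ProbeMap",
    "overlap_length",
    "reciprocal_overlap",
    "merge_intervals",
    "coverage_fraction",
    "stitch_fragments",
    "count_probes",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``chrom:[start, end)`` in base pairs.

    ``end > start`` always; length is ``end - start``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


class ProbeMap:
    """Array probe positions, per chromosome, 0-based and strictly increasing.

    CNV callers emit runs of consecutive probes, so the number of probes
    inside an interval equals the length of the longest successive-probe run
    supporting a call there.
    """

    def __init__(self, positions: Dict[str, Sequence[int]]):
        self._positions: Dict[str, np.ndarray] = {}
        for chrom, pos in positions.items():
            arr = np.asarray(sorted(pos), dtype=np.int64)
            if arr.size and np.any(np.diff(arr) <= 0):
                raise ValueError(f"duplicate probe positions on {chrom}")
            self._positions[chrom] = arr

    def chromosomes(self) -> List[str]:
        return list(self._positions)

    def positions(self, chrom: str) -> np.ndarray:
        return self._positions.get(chrom, np.empty(0, dtype=np.int64))

    def count_in(self, interval: GenomicInterval) -> int:
        pos = self.positions(interval.chrom)
        lo = int(np.searchsorted(pos, interval.start, side="left"))
        hi = int(np.searchsorted(pos, interval.end, side="left"))
        return hi - lo


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Shared bases between two intervals; 0 across chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Overlap divided by the longer interval.

    ``reciprocal_overlap(a, b) >= f`` means the shared segment covers at
    least fraction ``f`` of *both* intervals — the standard criterion for
    declaring two CNV calls the same event.
    """
    return overlap_length(a, b) / max(a.length, b.length)


def merge_intervals(regions: Iterable[GenomicInterval]) -> Dict[str, List[Tuple[int, int]]]:
    """Union of possibly-overlapping regions, as sorted disjoint spans per chromosome."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    merged: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out: List[Tuple[int, int]] = []
        for s, e in spans:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = out
    return merged


def coverage_fraction(a: GenomicInterval, regions: Iterable[GenomicInterval]) -> float:
    """Fraction of ``a``'s bases covered by the union of ``regions``.

    Regions may overlap each other; they are merged internally first.
    """
    merged = merge_intervals(regions).get(a.chrom, [])
    covered = 0
    for s, e in merged:
        covered += max(0, min(a.end, e) - max(a.start, s))
    return covered / a.length


def count_probes(a: GenomicInterval, probes: ProbeMap) -> int:
    """Probes ``p`` with ``a.start <= p < a.end`` on ``a.chrom``."""
    return probes.count_in(a)


def stitch_fragments(
    calls: Sequence["CnvCall"],
    max_gap_bp: int = 100_000,
    max_gap_fraction: float = 0.2,
) -> List["CnvCall"]:
    """Merge fragmented calls from one sample + caller back into whole events.

    Very large array CNVs are often emitted as several adjacent sub-calls.
    Same-chromosome, same-type calls separated by a gap no larger than
    ``max(max_gap_bp, max_gap_fraction * merged_span)`` are merged
    transitively into a single call spanning the outer boundaries.  Probe
    counts sum, confidence takes the minimum of the members, and the number
    of pre-merge fragments accumulates in ``stitched_from``.  Idempotent.
    """
    calls = list(calls)
    if not calls:
        return []
    sample_ids = {c.sample_id for c in calls}
    callers = {c.caller for c in calls}
    if len(sample_ids) > 1 or len(callers) > 1:
        offender = next(
            c for c in calls
            if c.sample_id != calls[0].sample_id or c.caller != calls[0].caller
        )
        raise ValueError(
            "stitch_fragments requires a single sample and caller; "
            f"offending call: sample={offender.sample_id} caller={offender.caller} "
            f"{offender.interval}"
        )

    def sort_key(c: "CnvCall"):
        return (c.interval.chrom, c.interval.start, c.interval.end, c.cnv_type)

    out: List[CnvCall] = []
    for key in sorted({(c.interval.chrom, c.cnv_type) for c in calls}):
        chrom, cnv_type = key
        group = sorted(
            (c for c in calls if c.interval.chrom == chrom and c.cnv_type == cnv_type),
            key=sort_key,
        )
        # Iterate to a fixpoint: a merge enlarges the span, which can raise
        # the fractional gap threshold enough to absorb a neighbour that a
        # single pass would have left out; idempotence requires convergence.
        while True:
            merged: List[CnvCall] = []
            current = group[0]
            for nxt in group[1:]:
                gap = nxt.interval.start - current.interval.end
                span = max(nxt.interval.end, current.interval.end) - current.interval.start
                if gap <= max(max_gap_bp, max_gap_fraction * span):
                    current = _merge_pair(current, nxt)
                else:
                    merged.append(current)
                    current = nxt
            merged.append(current)
            if len(merged) == len(group):
                break
            group = merged
        out.extend(merged)
    return sorted(out, key=sort_key)


def _merge_pair(a: "CnvCall", b: "CnvCall") -> "CnvCall":
    interval = GenomicInterval(
        a.interval.chrom, a.interval.start, max(a.interval.end, b.interval.end)
    )
    n_probes = None
    if a.n_probes is not None and b.n_probes is not None:
        n_probes = a.n_probes + b.n_probes
    confidence = None
    present = [c for c in (a.confidence, b.confidence) if c is not None]
    if present:
        confidence = min(present)
    copy_number = a.copy_number if a.copy_number == b.copy_number else None
    return dataclasses.replace(
        a,
        interval=interval,
        n_probes=n_probes,
        confidence=confidence,
        copy_number=copy_number,
        stringent=a.stringent and b.stringent,
        stitched_from=a.stitched_from + b.stitched_from,
    )
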