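"""Per-sample consensus CNV calling across multiple detection algorithms.

An autosomal event is retained when at least two distinct callers report it
(reciprocal overlap >= ``min_ro``, same type) and at least one of them is a
primary caller (iPattern or PennCNV).  On chromosome X only the two primary
callers are consulted, and both must report the event with a stringent
(caller-flagged high-confidence) call.  Consensus boundaries come from the
highest-priority supporting caller so probe counts stay coherent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Sequence, Tuple

from .intervals import GenomicInterval, reciprocal_overlap
from .io_model import PRIMARY_CALLERS, CnvCall

__all__ = ["ConsensusCnv", "match_calls_across_callers", "consensus_call_set",
           "CALLER_PRIORITY", "is_chrx"]

# Primary callers first; determines whose boundaries a consensus event adopts.
CALLER_PRIORITY = ("ipattern", "penncnv", "quantisnp", "cnvpartition")


def is_chrx(chrom: str) -> bool:
    return chrom.lower().lstrip("chr") == "x" or chrom.lower() == "chrx"


@dataclass(frozen=True)
class ConsensusCnv:
    """A per-sample consensus event with its supporting-caller evidence."""

    sample_id: str
    interval: GenomicInterval
    cnv_type: str
    supporting_callers: FrozenSet[str]
    representative_caller: str
    stringent_support: bool
    n_probes: int | None
    stitched_from: int = 1

    def __post_init__(self) -> None:
        if self.representative_caller not in self.supporting_callers:
            raise ValueError("representative caller must be a supporting caller")


def match_calls_across_callers(
    calls: Sequence[CnvCall], min_ro: float = 0.5
) -> List[List[CnvCall]]:
    """Group one sample's calls (fragments already stitched per caller).

    Calls of identical type on the same chromosome are grouped transitively
    when pairwise reciprocal overlap >= ``min_ro``; each call lands in
    exactly one group.
    """
    calls = list(calls)
    if not calls:
        return []
    samples = {c.sample_id for c in calls}
    if len(samples) > 1:
        raise ValueError(f"calls span multiple samples: {sorted(samples)}")

    groups: List[List[CnvCall]] = []
    by_key: Dict[Tuple[str, str], List[CnvCall]] = {}
    for c in calls:
        by_key.setdefault((c.interval.chrom, c.cnv_type), []).append(c)
    for key in sorted(by_key):
        members = sorted(by_key[key], key=lambda c: (c.interval.start, c.interval.end, c.caller))
        parent = list(range(len(members)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if members[j].interval.start >= members[i].interval.end:
                    break  # sorted by start; no further overlap with i
                if reciprocal_overlap(members[i].interval, members[j].interval) >= min_ro:
                    parent[find(i)] = find(j)
        clusters: Dict[int, List[CnvCall]] = {}
        for i, c in enumerate(members):
            clusters.setdefault(find(i), []).append(c)
        for root in sorted(clusters, key=lambda r: clusters[r][0].interval.start):
            groups.append(clusters[root])
    return groups


def consensus_call_set(
    groups: Sequence[Sequence[CnvCall]],
    child_sex: str = "unknown",
    primary_callers: Tuple[str, ...] = PRIMARY_CALLERS,
    caller_priority: Tuple[str, ...] = CALLER_PRIORITY,
) -> List[ConsensusCnv]:
    """Apply the autosome / chrX evidence rules to matched call groups.

    ``child_sex`` is carried for downstream stages; the chrX rule applies
    identically to both sexes at this stage.
    """
    out: List[ConsensusCnv] = []
    for group in groups:
        group = list(group)
        chrom = group[0].interval.chrom
        if is_chrx(chrom):
            # Only the primary callers are consulted on chrX.
            primary_calls = [c for c in group if c.caller in primary_callers]
            present = {c.caller for c in primary_calls}
            if set(primary_callers) - present:
                continue
            stringent_ok = all(
                any(c.stringent for c in primary_calls if c.caller == caller)
                for caller in primary_callers
            )
            if not stringent_ok:
                continue
            supporting = frozenset(present)
            candidates = primary_calls
            stringent_support = True
        else:
            supporting = frozenset(c.caller for c in group)
            if len(supporting) < 2 or not supporting & set(primary_callers):
                continue
            candidates = group
            stringent_support = any(c.stringent for c in group)

        rep_caller = min(
            supporting,
            key=lambda c: caller_priority.index(c) if c in caller_priority else len(caller_priority),
        )
        rep_call = max(
            (c for c in candidates if c.caller == rep_caller),
            key=lambda c: (c.interval.length, -c.interval.start),
        )
        out.append(ConsensusCnv(
            sample_id=rep_call.sample_id,
            interval=rep_call.interval,
            cnv_type=rep_call.cnv_type,
            supporting_callers=supporting,
            representative_caller=rep_caller,
            stringent_support=stringent_support,
            n_probes=rep_call.n_probes,
            stitched_from=rep_call.stitched_from,
        ))
    out.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end, c.cnv_type))
    return out
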