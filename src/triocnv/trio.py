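"""Inheritance classification of child CNVs against parental call sets.

Parental evidence uses the RAW UNION of all per-caller parental calls
(fragments stitched per caller), not the parental consensus set: a single
caller's false negative in a parent must not manufacture a de novo event.
A child call is de novo only when neither parent has any same-type call
reaching the reciprocal-overlap threshold; a missing parental call file
yields ``unresolved``, never de novo by absence of data.

On chrX in male children a hemizygous deletion (copy number 0) matches a
maternal heterozygous deletion (copy number 1): matching is by call type,
never by copy number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .consensus import ConsensusCnv
from .intervals import reciprocal_overlap
from .io_model import CnvCall

__all__ = ["InheritanceVerdict", "classify_inheritance", "de_novo_summary",
           "DeNovoSummary"]

STATUSES = ("de_novo", "maternal", "paternal", "biparental", "unresolved")


@dataclass(frozen=True)
class InheritanceVerdict:
    child_call: ConsensusCnv
    status: str
    best_ro_father: float
    best_ro_mother: float
    parental_evidence_source: str = "raw_union"

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown inheritance status {self.status!r}")


def _best_ro(child_call: ConsensusCnv, parent_calls: Sequence[CnvCall]) -> float:
    best = 0.0
    for c in parent_calls:
        if c.cnv_type != child_call.cnv_type:
            continue
        ro = reciprocal_overlap(child_call.interval, c.interval)
        if ro > best:
            best = ro
    return best


def classify_inheritance(
    child_call: ConsensusCnv,
    father_calls: Optional[Sequence[CnvCall]],
    mother_calls: Optional[Sequence[CnvCall]],
    min_ro: float = 0.5,
) -> InheritanceVerdict:
    """Classify one child consensus CNV against both parents' raw call unions.

    ``father_calls``/``mother_calls`` of ``None`` mean the parent's data is
    missing (→ unresolved); an empty sequence means the parent genuinely has
    no calls (→ counts toward de novo).
    """
    if father_calls is None or mother_calls is None:
        return InheritanceVerdict(
            child_call, "unresolved",
            best_ro_father=_best_ro(child_call, father_calls or []),
            best_ro_mother=_best_ro(child_call, mother_calls or []),
        )
    ro_f = _best_ro(child_call, father_calls)
    ro_m = _best_ro(child_call, mother_calls)
    in_father = ro_f >= min_ro
    in_mother = ro_m >= min_ro
    if in_father and in_mother:
        status = "biparental"
    elif in_father:
        status = "paternal"
    elif in_mother:
        status = "maternal"
    else:
        status = "de_novo"
    return InheritanceVerdict(child_call, status, best_ro_father=ro_f, best_ro_mother=ro_m)


@dataclass
class DeNovoSummary:
    n_trios_with_de_novo: int
    per_trio_counts: Dict[str, int]
    total_de_novo_events: int


def de_novo_summary(verdicts_by_trio: Dict[str, Sequence[InheritanceVerdict]]) -> DeNovoSummary:
    """Trio-level de novo counts: trios with >= 1 de novo verdict, plus totals."""
    per_trio = {
        trio: sum(1 for v in verdicts if v.status == "de_novo")
        for trio, verdicts in verdicts_by_trio.items()
    }
    return DeNovoSummary(
        n_trios_with_de_novo=sum(1 for n in per_trio.values() if n > 0),
        per_trio_counts=per_trio,
        total_de_novo_events=sum(per_trio.values()),
    )
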