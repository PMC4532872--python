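"""Gene annotation and rule-based clinical tiering of rare variants.

Expert curation against CNV databases is approximated by an explicit
decision table over size, de novo status, gene count and hits to a
user-supplied known-pathogenic-locus file.  First matching rule wins:

1. de novo AND size >= 5 Mb                      → pathogenic
2. known-locus hit at RO >= 0.5                  → likely_pathogenic
   (pathogenic instead if the locus is flagged syndromic-dominant)
3. de novo AND >= 20 genes                       → likely_pathogenic
4. de novo AND >= 1 gene                         → vus
5. otherwise                                     → likely_benign

Rule 2 deliberately fires for inherited variants too: known
variable-expressivity loci (1q21.1, 16p13.11, ...) remain reportable when
transmitted from a parent.  Unresolved inheritance is tiered as inherited
and flagged for review.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

from .consensus import ConsensusCnv
from .intervals import GenomicInterval, overlap_length, reciprocal_overlap
from .io_model import Region
from .trio import InheritanceVerdict

__all__ = ["TierRules", "ClassifiedVariant", "annotate_genes",
           "assign_clinical_tier", "build_classified_variants", "TIERS"]

TIERS = ("pathogenic", "likely_pathogenic", "vus", "likely_benign")


@dataclass(frozen=True)
class TierRules:
    large_cnv_bp: int = 5_000_000
    likely_path_min_genes: int = 20
    locus_ro: float = 0.5

    def __post_init__(self) -> None:
        if self.large_cnv_bp <= 0:
            raise ValueError("large_cnv_bp must be positive")


@dataclass(frozen=True)
class ClassifiedVariant:
    consensus: ConsensusCnv
    inheritance: InheritanceVerdict
    n_genes: int
    gene_names: Tuple[str, ...]
    known_locus_hits: Tuple[Tuple[str, float, bool], ...]  # (name, RO, dominant)
    tier: str
    rule_fired: str
    review_flag: bool = False
    filter_audit: str = ""


def annotate_genes(
    interval: GenomicInterval, genes: Sequence[Region]
) -> Tuple[int, List[str]]:
    """Distinct gene names overlapping the variant by >= 1 bp, sorted."""
    names = {
        g.name for g in genes
        if overlap_length(interval, g.interval) >= 1 and g.name
    }
    ordered = sorted(names)
    return len(ordered), ordered


def locus_hits(
    interval: GenomicInterval, known_loci: Sequence[Region], locus_ro: float = 0.5
) -> List[Tuple[str, float, bool]]:
    hits = []
    for locus in known_loci:
        ro = reciprocal_overlap(interval, locus.interval)
        if ro >= locus_ro:
            hits.append((locus.name, ro, "dominant" in locus.flags))
    hits.sort(key=lambda h: (-h[1], h[0]))
    return hits


def assign_clinical_tier(
    consensus: ConsensusCnv,
    inheritance_status: str,
    n_genes: int,
    hits: Sequence[Tuple[str, float, bool]],
    rules: TierRules = TierRules(),
) -> Tuple[str, str, bool]:
    """Returns (tier, rule fired, review flag). Total: exactly one rule fires."""
    review = inheritance_status == "unresolved"
    de_novo = inheritance_status == "de_novo"
    if de_novo and consensus.interval.length >= rules.large_cnv_bp:
        return "pathogenic", "rule1_large_de_novo", review
    if hits:
        if any(dominant for _, _, dominant in hits):
            return "pathogenic", "rule2_known_locus_dominant", review
        return "likely_pathogenic", "rule2_known_locus", review
    if de_novo and n_genes >= rules.likely_path_min_genes:
        return "likely_pathogenic", "rule3_de_novo_gene_rich", review
    if de_novo and n_genes >= 1:
        return "vus", "rule4_de_novo_genic", review
    return "likely_benign", "rule5_default", review


def build_classified_variants(
    verdicts: Sequence[InheritanceVerdict],
    genes: Sequence[Region],
    known_loci: Sequence[Region],
    rules: TierRules = TierRules(),
    audits: Sequence[str] = (),
) -> List[ClassifiedVariant]:
    """Annotate and tier every verdict-bearing rare variant."""
    out: List[ClassifiedVariant] = []
    for i, verdict in enumerate(verdicts):
        call = verdict.child_call
        n_genes, names = annotate_genes(call.interval, genes)
        hits = locus_hits(call.interval, known_loci, rules.locus_ro)
        tier, rule, review = assign_clinical_tier(
            call, verdict.status, n_genes, hits, rules
        )
        out.append(ClassifiedVariant(
            consensus=call,
            inheritance=verdict,
            n_genes=n_genes,
            gene_names=tuple(names),
            known_locus_hits=tuple(hits),
            tier=tier,
            rule_fired=rule,
            review_flag=review,
            filter_audit=audits[i] if i < len(audits) else "",
        ))
    out.sort(key=lambda v: (v.consensus.sample_id, v.consensus.interval.chrom,
                            v.consensus.interval.start, v.consensus.interval.end))
    return out
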