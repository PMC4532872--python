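"""Cohort-level statistics: severity association, burden comparison, rates.

The central test is a two-tailed Fisher's exact test on a 2×2 table of
motor-severity class (GMFCS I–III vs IV–V) against carriage of a large
(>=5 Mb) de novo CNV.  The two-sided p-value uses the probability-mass
convention of mainstream statistical software: the sum of hypergeometric
probabilities of all tables with the same margins that are no more probable
than the observed one, computed by full enumeration over the feasible range
of cell ``a`` with log-factorial terms (mid-p and doubling variants exist;
this package uses neither).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
from scipy.special import gammaln
from scipy.stats import t as t_dist

from .io_model import PhenotypeRecord

__all__ = ["ContingencyTable2x2", "dichotomize_gmfcs", "fisher_exact_two_sided",
           "burden_t_test", "rate_report", "build_severity_table"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a,b,c,d): rows are exposure (severe vs mild-moderate GMFCS),
    columns outcome (large de novo CNV carrier vs not)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def dichotomize_gmfcs(level: str) -> str:
    """GMFCS I–III → mild_moderate; IV–V → severe; unknown stays unknown."""
    if level in ("I", "II", "III"):
        return "mild_moderate"
    if level in ("IV", "V"):
        return "severe"
    if level == "unknown":
        return "unknown"
    raise ValueError(f"unrecognized GMFCS level {level!r}")


def _log_hypergeom(a: int, row1: int, row2: int, col1: int, n: int) -> float:
    """log P(table) under fixed margins, via log-factorials."""
    b, c = row1 - a, col1 - a
    d = row2 - c
    lf = lambda k: gammaln(k + 1)
    return (lf(row1) + lf(row2) + lf(col1) + lf(n - col1)
            - lf(n) - lf(a) - lf(b) - lf(c) - lf(d))


def fisher_exact_two_sided(t: ContingencyTable2x2, rel_tol: float = 1e-7) -> float:
    """Exact two-sided p by enumeration (probability-mass method).

    Sums P(table) over every table with the observed margins whose
    probability is <= that of the observed table, with relative tolerance
    ``rel_tol`` on the comparison to absorb floating-point noise.
    """
    if t.total == 0:
        raise ValueError("all-zero contingency table")
    row1, row2 = t.a + t.b, t.c + t.d
    col1 = t.a + t.c
    n = t.total
    a_min = max(0, col1 - row2)
    a_max = min(row1, col1)
    log_obs = _log_hypergeom(t.a, row1, row2, col1, n)
    p = 0.0
    for a in range(a_min, a_max + 1):
        lp = _log_hypergeom(a, row1, row2, col1, n)
        if lp <= log_obs + np.log1p(rel_tol):
            p += float(np.exp(lp))
    return min(p, 1.0)


def burden_t_test(
    group1: Sequence[float], group2: Sequence[float]
) -> Tuple[float, float]:
    """Unpaired pooled-variance Student's t-test (not Welch), two-sided.

    Degenerate inputs: zero pooled variance with equal means gives p=1;
    zero pooled variance with unequal means is undefined and raises.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 values")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t_stat = diff / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2.0 * float(t_dist.sf(abs(t_stat), df))
    return float(t_stat), min(p, 1.0)


def rate_report(numerator: int, denominator: int) -> str:
    """Percentage string, one decimal, half-up rounding — e.g. (8, 115) → '7.0%'."""
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be in [0, denominator]")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return f"{pct.quantize(Decimal('0.1'), rounding=ROUND_HALF_UP)}%"


def build_severity_table(
    carrier_sample_ids: Iterable[str],
    phenotypes: Sequence[PhenotypeRecord],
) -> ContingencyTable2x2:
    """2×2 severity table over probands with known GMFCS only.

    ``carrier_sample_ids``: probands carrying >= 1 de novo CNV at or above
    the large-CNV size cutoff (or a flagged large pathogenic/likely-
    pathogenic event).  a = severe carriers, b = severe non-carriers,
    c = mild-moderate carriers, d = mild-moderate non-carriers.
    """
    carriers: Set[str] = set(carrier_sample_ids)
    a = b = c = d = 0
    for ph in phenotypes:
        klass = dichotomize_gmfcs(ph.gmfcs)
        if klass == "unknown":
            continue
        carrier = ph.sample_id in carriers
        if klass == "severe":
            a, b = a + carrier, b + (not carrier)
        else:
            c, d = c + carrier, d + (not carrier)
    return ContingencyTable2x2(a, b, c, d)
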