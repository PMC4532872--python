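# Methods

## Coordinates and interval algebra

All internal coordinates are 0-based half-open, the convention that makes
length and gap arithmetic unambiguous and matches BED.  CNV call tables
default to the 1-based inclusive dialect array callers print (a row
`start=100001, end=250000` spans 150,000 bp); output tables are written
1-based inclusive; conversion happens only at the I/O boundary and every
file header states its convention.

Reciprocal overlap is `|a ∩ b| / max(|a|, |b|)` — equivalently, the largest
fraction f such that the shared segment covers ≥ f of both intervals.  The
0.5 threshold used for cross-caller matching, control-carrier matching and
parental matching is the prevailing convention in the CNV literature; all
three thresholds are independently configurable.

Probe support is counted as the number of array probes strictly inside the
call.  Callers emit runs of consecutive probes, so containment implies the
"successive probes" reading; the minimum is 5.

## Fragment stitching

Very large array CNVs are frequently emitted as several adjacent
sub-calls.  Same-sample, same-caller, same-type calls separated by a gap
≤ max(`max_gap_bp` = 100 kb, `max_gap_fraction` = 0.2 × merged span) are
merged, iterating to a fixpoint: a merge enlarges the span, which can
legitimately raise the fractional threshold enough to absorb the next
fragment, and idempotence (stitching twice equals stitching once) holds
only at the fixpoint.  Probe counts sum, confidence takes the minimum,
the stringent flag requires all members stringent, and the fragment count
is carried as provenance.  The thresholds are explicit stand-ins for what
is in practice a manual-review judgement, hence config-exposed.

## Consensus evidence rules

Autosomal events require ≥ 2 distinct callers, at least one primary
(iPattern or PennCNV).  chrX events consult only the primary callers and
require a stringent call from each; "stringent" is a caller-supplied
boolean because high-confidence criteria are caller-specific.  Consensus
boundaries are taken from the highest-priority supporting caller
(iPattern > PennCNV > QuantiSNP > CNVPartition) rather than a union or
intersection, keeping the reported probe count attributable to one real
call.  Grouping is transitive, so a chain of calls can connect extremes
below the pairwise threshold; this is accepted and bounded by the
same-chromosome same-type constraint.  The chrX rule applies identically
to both sexes.

## Sample QC

Samples need call rate ≥ 0.95 and per-sample LRR/BAF standard deviations
within cohort mean ± 3 s.d. (sample s.d., n−1).  Bounds are computed once
on the full cohort, including samples that fail the call-rate gate, and
boundary values pass ("within" read inclusively — conservative retention).
Trios losing any member are dropped from segregation analysis.

## Rare filtering

Gate strictness follows the filter's definition exactly: size strictly
> 10 kb, probes ≥ 5, stable-region coverage strictly > 0.75, control
frequency strictly < 0.001.  Frequency must hold in every cohort
("rare everywhere") rather than in a pooled denominator — the conservative
reading of a primary-plus-refinement cohort design.  Carriers are counted
per control sample, not per call, so a fragmented control event cannot be
double-counted; with a 2,988-sample cohort the 0.1 % threshold means at
most 2 carriers, a bound the audit trail states explicitly.  All four
gates are always evaluated (no short-circuit) so the audit is complete for
every call, survivor or not.

## Inheritance

Parental evidence is the raw union of all per-caller parental calls
(stitched per caller), not the parental consensus set: consensus demands
two concordant callers, and requiring that of a parent would let a single
parental false negative manufacture a de novo call.  The false-de-novo
probability for an inherited event is therefore roughly the product of the
per-caller miss rates across the carrier parent's callers — at sensitivity
0.9 and four callers, ~10⁻⁴, comfortably below the (1−s)² envelope the
tests assert.  Matching is by call type only; a hemizygous male chrX
deletion (copy number 0) matches a maternal heterozygous deletion (copy
number 1).  Missing parental data yields `unresolved`, never de novo.
Adjacent del+dup pairs are reported as two events, with no attempt to
infer unbalanced translocations.

## Clinical tiering

Expert curation against CNV databases is replaced by an explicit decision
table (first match wins): (1) de novo and ≥ 5 Mb → pathogenic; (2)
known-locus hit at RO ≥ 0.5 → likely pathogenic, or pathogenic when the
locus is flagged syndromic-dominant, regardless of inheritance; (3) de
novo and ≥ 20 genes → likely pathogenic; (4) de novo and genic → VUS;
(5) otherwise likely benign.  The 5 Mb size cutoff and the 20-gene
threshold encode the field's practice of treating very large or gene-rich
de novo events as reportable; known variable-expressivity loci (1q21.1,
16p13.11 and similar) stay reportable when inherited, which is why rule 2
fires for inherited variants.  Unresolved inheritance is tiered as
inherited and flagged for review.  The rule that fired is recorded per
variant.  No ACMG/ClinGen scoring, dosage-sensitivity lookup or literature
evidence is attempted.

## Statistics

The two-sided Fisher exact p-value uses the probability-mass method — the
sum of hypergeometric probabilities of all tables with the observed
margins no more probable than the observed table — computed by full
enumeration with log-factorial terms and a 10⁻⁷ relative tolerance on the
probability comparison (mid-p and doubling conventions exist; neither is
used).  Burden comparisons use the pooled-variance (Student, not Welch)
unpaired t-test; zero pooled variance with equal means returns p = 1,
with unequal means it is an error.  Percentages are rendered with half-up
rounding to one decimal.  The severity table is built over probands with
known GMFCS only: rows severe (IV–V) vs mild-moderate (I–III), columns
carrier vs non-carrier of a de novo event ≥ 5 Mb.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
the scale of the modelled study: 115 complete trios, one 2,988-sample
control cohort, polymorphic CNVs at population frequencies 0.10–0.40
transmitted with probability 0.5, a rare-inherited background of 2 events
per parent genome (20 kb–1 Mb, transmitted with probability 0.5), de novo
events planted in round(8/115 × n) trios (half 20–500 kb, half 5–75 Mb),
and known-locus inherited events in round(3/115 × n) further trios.
Severe GMFCS probability is 0.75 for large-de-novo carriers and 0.22
otherwise (the values implied by 3-of-4 carriers and 22-of-99 non-carriers
severe in a 103-proband severity subset); 12/115 of probands have unknown
GMFCS.  Four caller error models add sensitivity loss, boundary jitter
(truncated at 40 % of event length so intervals never invert),
fragmentation of events > 2 Mb, false positives and per-call stringency.
QC metrics are drawn from bounded uniforms (±2 reference s.d., so the
sample-relative ±3 s.d. gate excludes nobody at outlier rate 0) with
outliers pushed to 6–10 reference s.d. explicitly.

The genome is scaled — chr1 200 Mb, chr2 150 Mb, chr3 120 Mb, chrX 150 Mb,
probes every 1,200 bp, one gene per 150 kb — keeping coordinates realistic
in magnitude so the 10 kb and 5 Mb gates are meaningful while fixtures
stay small.  Two structural guarantees make zero-noise recovery exact
rather than merely likely: planted same-type events keep a gap strictly
above the stitching envelope (> max(100 kb, (len₁+len₂)/4)), so distinct
truth events can never merge into one call; and control background events
are placed below 50 % reciprocal overlap with every planted study event,
making "planted" and "rare" synonymous by construction (on a scaled genome
chance collisions would otherwise cross the ≤ 2-carrier bound regularly).
Polymorphic territory and known loci cluster near chromosome starts,
leaving corridors where 75 Mb events fit.  Opposite-type events may be
adjacent, mirroring real adjacent del+dup patterns.

What the generator does not model: raw LRR/BAF intensities, per-caller
probe subsets, genuinely common inherited pathogenic variants,
population stratification, and locus-specific mutation rates.  Passing
the recovery tests therefore demonstrates the pipeline's bookkeeping and
rule logic, not calibration against real array noise.

Identical config and seed give byte-identical bundles; all randomness
flows through one seeded generator per stage.

## Problem sizes and numerical choices

Tests and the acceptance script run the full 115-trio, 2,988-control
configuration (a few seconds per end-to-end run).  The brute-force oracle
equivalence checks use 10,000 random intervals ≤ 10 kb against per-base
bitmap oracles.  The false-de-novo property test raises the rare-inherited
rate to 5 events per parent genome to observe ≥ 500 inherited events in
one cohort, per the property's stated sample-size requirement.  Sorting
ties break by (chromosome, start, end, type); the provenance hash recorded
in every output covers analysis parameters (not input paths), so the same
analysis on relocated inputs is recognizably identical.

## Known limitations

The consensus matching rule, the stringency definition and the stitching
thresholds are declared stand-ins for judgements the original workflow
made manually or left caller-specific.  chrY is not handled; no liftover
between genome builds; relationship verification and parent-of-origin
inference are out of scope.  Raising the cross-caller `min_ro` usually
shrinks the consensus set, but transitive grouping means this is not a
theorem — splitting one mixed group can in principle yield two emitting
groups.
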