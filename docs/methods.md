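# Methods

## Coordinates and interval algebra

All internal coordinates are 0-based half-open; readers convert on input
(CNV tables and known-variant tables default to 1-based inclusive, the
clinical convention; GFF3 is 1-based inclusive; BED is native) and writers
convert back. "Overlap" always means at least one shared base, so
book-ended intervals (`a.end == b.start`) neither merge nor count a
feature. Strand is ignored everywhere: the analysis concerns copy number
of genomic spans, not transcripts.

CNVR merging computes connected components of the pairwise-overlap graph
with a single sweep over start-sorted calls. Merging is per subgroup only:
regions from different subgroups are never combined, because every
downstream statistic is a subgroup property.

## Classification rules

A CNV is **common** when the union of known variants overlapping it covers
the whole CNV (`common_overlap_floor = 1.0`) and the overlapping variants
carry at least `min_studies = 2` distinct study identifiers. "Union
coverage with a distinct-study count" is the weakest reading of
"reported in at least two studies" — the alternative (each study must
individually cover the CNV) is stricter; both are one configuration change
apart and the report records the covered fraction and study count per CNV
so the readings can be compared after the fact.

Coverage below `rare_overlap_ceiling = 0.50` makes the CNV **rare**; rare
CNVs split by inheritance into **de novo** (absent in both parents) or
**familial** (inherited). Coverage in [0.50, 1.0), or full coverage backed
by a single study, falls in a band the rules do not define; such CNVs are
classed **ambiguous** and excluded by default (`ambiguous_policy`,
alternative: treat as rare) rather than silently assigned. Curated
pathogenic (DECIPHER-style) CNVs bypass classification. Control-cohort
CNVs that classify rare belong to no standard subgroup and are reported
separately with a warning. Internal-control CNVs can be appended to the
known-variant list under the reserved study id `__internal_controls__`.

## Densities and the weighted median

Densities divide distinct feature counts by the exact base-pair span /
10⁶, never by a pre-rounded Mb figure. The subgroup statistic is the
**lower weighted median** of per-CNVR densities with CNVR sizes (Mb) as
weights: the smallest density whose cumulative weight reaches half the
total. No interpolation is done at exact half-weight ties; the lower value
wins, which keeps the statistic at 0 for subgroups where most weighted
mass lies on miRNA-free regions. The unweighted median is emitted
alongside, since "weighted by size" admits both readings. Report rounding
is half-away-from-zero — two decimals for densities, one for per-CNVR
averages — applied only at serialization; machine-readable outputs keep
full precision.

Subgroup pairs are compared with the two-sided Wilcoxon rank-sum
(Mann–Whitney) test: the groups are unpaired samples, so a signed-rank
(paired) test is not applicable. The exact distribution is enumerated when
both samples have ≤ 10 observations without ties; otherwise the
tie-corrected normal approximation runs without continuity correction (so
identical samples give p = 1 exactly). The method note field of every
comparison records which path ran.

## Coverage null

The observed statistic is the fraction of all genome features (miRNA or
protein-coding-gene track) overlapped by at least one region of the
subgroup. The null resamples the subgroup's length multiset: each region
independently draws a chromosome with probability proportional to its
valid start count (`chromosome length − region length + 1`), then a
uniform valid start. Sampled regions may overlap each other and are not
re-merged — re-merging would shrink total coverage below the observed
set's. Rejection sampling handles the optional exclusion mask and the
optional non-overlap mode; no mask is applied by default (no assembly-gap
model). Replicates run on substreams spawned deterministically from the
configured seed, so results are independent of execution order.

The empirical two-tailed p doubles the smaller tail with an add-one
correction, `p = min(1, 2·(1 + min(#null ≥ obs, #null ≤ obs))/(R + 1))`,
so finite replication never reports zero. Because ties count in both
tails, the test is conservative when the null statistic takes few distinct
values — with sparse tracks or few replicates the realized type-I rate
falls below nominal. The calibration check therefore uses a dense track
(20,000 features, 30 regions of 100 kb on a 20 Mb toy genome) and 499
replicates, where the discretization is mild; the measured rejection rate
at α = 0.05 sits near 0.04–0.055.

## Enrichment

A gene is "targeted" if it appears in any miRNA's target set; the target
map is an input (no target prediction is performed). Gene identity is the
upper-cased symbol. Over-representation of a set in a query is the
hypergeometric upper tail `P(X ≥ k)` over a configurable universe —
default the whole protein-coding track, alternatively the union of set
members. Raw p-values are BH-adjusted across all tested sets, filtered at
adjP < 0.05, ranked ascending by adjP (ties by raw p, then name) and cut
to the top 10. The two-stage procedure mirrors the original web-tool
pipeline: miRNA-target sets are tested against the subgroup's CNV genes
first, and pathway sets are then tested over the genes of the stage-1
passers.

The brain-related miRNA percentage follows the curated-annotation
convention: the denominator is miRNAs **with expression data**, not all
miRNAs in the subgroup; miRNAs absent from the annotation file count as
"no data" with a logged count. The annotation itself is an input file —
it originated from manual literature curation, which cannot be automated
faithfully.

## Synthetic cohorts

The generator emulates the study design, not array data: five subgroups
with configurable counts (defaults 24 / 46 / 216 / 67 / 35 CNVs), per-group
log-normal sizes (multi-Mb de novo and pathogenic regions, ~0.5 Mb common
variants), an hg18-scale 24-chromosome genome, a miRNA track with a
clustered hotspot fraction (default 30% of 2042 loci in 60 clusters), a
uniform 19,905-gene track, and a known-variant database whose loci anchor
the common CNVs. Construction makes the planted truth exact: common CNVs
coincide with ≥ 2-study loci (covered fraction 1.0), rare CNVs are placed
off every known-variant locus (fraction 0.0), so classification recovery
is exact by design and the recovery test checks bookkeeping, not
statistical luck. Subgroups with miRNA bias > 1 centre a CNV on a random
miRNA locus with probability `1 − 1/bias` (defaults: 5× for the de novo
and pathogenic groups, per the observed density contrast; 1× elsewhere).

What the generator does **not** model: probe-level segmentation and its
breakpoint noise, trio genotypes behind the inheritance labels, realistic
gene length/density structure, linkage between gene positions and miRNA
positions, and database ascertainment bias. Passing tests therefore show
the pipeline's statistics behave correctly under their own assumptions,
not that those assumptions hold for any particular array platform.

## Problem sizes and numerical choices

Tests and analysis drivers run scaled-down instances (cohorts of 56–95
CNVs, 300–510 miRNAs, 1000–5000 genes; 199–499 null replicates; the
calibration uses 200 runs, the power check 50 runs at 5× bias) — full-scale
defaults run in seconds but the repeated-run simulations multiply that.
Empirical-p granularity at R replicates is 2/(R + 1); 499 replicates
resolve p = 0.004, ample for an α = 0.05 decision. Degenerate inputs are
errors, not silent results: empty samples for the weighted median, empty
null lists, zero-feature totals, region lengths exceeding every
chromosome, and rare CNVs with unknown inheritance in cohorts where the
split is required.

## Known limitations

- The published absolute counts (84 miRNAs in de novo CNVRs, exact
  rank-sum p-values, coverage bar heights, named pathways) are not
  reproducible from the printed tables alone; they require the original
  supplementary coordinates, an hg18 miRBase v19 track, the 2013 DGV
  freeze, and the era's web-tool versions. The package reproduces the
  printed ratios and the method's behavior, which is what is testable.
- One published density cell rounds inconsistently (84 miRNAs / 70.5 Mb =
  1.19 at two decimals against a printed 1.20); the computed value is
  reported. One published targeted-gene percentage shows the same issue
  (84/737 = 11.4% against a printed 11.5%). The published "average CNVR
  size" column is inconsistent with its own totals; the package computes
  totals/count and makes no attempt to match it.
- The empirical p is conservative under heavy ties (see above); this is a
  property of the chosen formula, preferred over anti-conservative
  alternatives.
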