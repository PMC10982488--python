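# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open; `length = end - start`.
PennCNV rawcnv files are 1-based inclusive and BED is 0-based half-open;
conversion happens only at the I/O boundary, so the internal length of a
parsed call equals the `length=` field PennCNV prints. Chromosome labels
are normalised by stripping a leading `chr`; only autosomes 1–22 are
accepted, since the calls derive from autosomal SNP probes. The GRCh37
assembly is assumed throughout and never verified against a sequence.
Thousands separators in `length=` are tolerated; when a declared length
disagrees with the coordinates, the parser warns and trusts coordinates.

## Quality control

Sample filters (all strict inequalities): LRR_SD < 0.3, BAF_drift < 0.01,
|WF| < 0.05, and NumCNVs ≤ 50, where NumCNVs is the raw calling-stage call
count — metric filters are applied first, then the call-count filter on
raw counts, matching the order in which a caller reports these statistics.
Call filters: length > 50,000 bp AND ≥ 6 probes ("more than 5").

Blacklist exclusion removes a call iff ≥ 50% of the *call's* length lies
in the union of blacklist regions (immunoglobulin, telomeric, centromeric).
This is the only per-call reading that makes a "50% overlap with these
regions" rule well defined, and it is configurable
(`QcThresholds.max_blacklist_fraction`). HLA retention is an overriding
retain-list: a call touching the retain interval by ≥ 1 bp is never
blacklist-removed, so users can supply standard blacklist BEDs unmodified.

The 50 kb / 6-probe filter runs **after** fragment merging by default
(fragments of a large variant may individually fall under 50 kb); a config
switch (`basic_filter_before_merge`) reverses the order.

## Fragment merging

Two same-sample, same-chromosome, same-type calls with gap
`g = b.start − a.end` and prospective merged span `s = b.end − a.start`
have gap fraction `g/s` (identical to the 1-based inclusive arithmetic).
Merging runs in two passes with thresholds < 0.50 then < 0.40; the second
pass can only act on gaps created by first-pass merges, and the two-pass
structure is kept deliberately rather than collapsed into one 0.40 pass.
Within a pass the pair with the smallest gap fraction merges first, ties
broken leftmost — the published procedure specifies no order, and this
choice makes the algorithm deterministic (verified against a naive rescan
oracle). Calls of the same type that outright overlap are union-merged
unconditionally first, because the gap fraction is undefined for overlaps.
A merged call takes the copy number of its longer constituent and the sum
of probe counts; deletions never merge with duplications, and merging
across copy-number states of the same sign (cn 0 with cn 1) is allowed by
default (`MergePolicy.same_type_only` controls the grouping key).

## Rare-variant filtering

The reference panel draws size/4 controls per country × sex stratum
without replacement (default 200, i.e. 50 per stratum), deterministically
from the seed. Panel calls are clustered per CNV type into CNV regions by
single-linkage with linkage criterion *reciprocal* overlap ≥ 0.5 — the
overlap must be ≥ 50% of **both** calls' lengths, computed as
overlap / max(len_a, len_b). The delineation of a population "variant"
before frequency estimation is a genuinely open design point; reciprocal
50% single-linkage CNVRs are standard practice and consistent with the
50% removal criterion. Carrier frequency counts distinct samples, so two
overlapping calls in one panel member count once; the ≥ 2% rule is
computed on frequency (≥ 4 carriers of 200) so other panel sizes work.
Removal covers a call with the union of same-type common regions and drops
it when coverage ≥ 50% of the call's length. Panel members are excluded
from all later analysis, so frequency estimation is leakage-free.

## Burden statistics

Frequencies divide *call counts* by the number of individuals, so a
"frequency" can exceed 1 — a deliberate convention (it reproduces the
published arithmetic exactly) despite its epidemiological quirk. The OR
treats (count, n − count) as a 2×2 table; when a count exceeds n the OR,
CI and p are reported as NaN rather than raising (this arises in small
strata). The Wald CI is `exp(ln OR ± z·SE)` with
`SE = √(1/a + 1/(n₁−a) + 1/b + 1/(n₂−b))`; any empty cell suppresses the
CI. The two-proportion test is the pooled z-test, two-sided, identical to
the Pearson χ² test on the table; the default has **no** continuity
correction, the choice that reproduces the published headline p = 0.0002
(with Yates it would print 0.0005); a flag enables Yates.

Bin membership is `lo < length ≤ hi` (a 100,000 bp call is "50–100 kb");
the boundary side is not dictated by the published bin labels, so this
deterministic convention is documented here. Bonferroni uses m = 10
(5 bins × 2 types) at α = 0.05, threshold 0.005; the overall per-type rows
are unadjusted. Singletons are calls with no same-type call in any *other*
sample at reciprocal overlap ≥ 0.5 (two identical calls in one sample
remain singletons).

## Enrichment test

The enrichment model is authored here, not shelled out: maximum-likelihood
logistic regression of case status on the per-sample count of distinct
genes hit (≥ 1 bp transcript overlap, no flanking border), with total CNV
kb and segment count as covariates — the published basis of the
size/rate-robust CNV enrichment test. Subset mode makes the candidate-list
gene count the predictor and adds the all-gene count as a covariate,
testing pathway genes *relative to* all genes. Deletions and duplications
are tested separately; with two candidate lists plus all genes that gives
6 tests and a Bonferroni threshold of 0.008. p is one-sided for a positive
coefficient (Wald z). Constant covariate columns are dropped before
fitting; separation or non-convergence returns a flagged result with
diagnostics instead of crashing. Coefficient *magnitudes* depend on
covariate scaling (kb here) and are implementation-defined; only the sign
and the p-value semantics are guaranteed.

## PRS comparison

Carriers are samples with ≥ 1 rare deletion strictly longer than 1,000 kb
(post rare-filter). The Wilcoxon rank-sum test uses the exact null
distribution when both groups are ≤ 25 and tie-free (so it agrees with
exhaustive enumeration), and otherwise the normal approximation with tie
correction and (by default) continuity correction. All six pairwise group
comparisons are computed and labelled, since only two of the possible
contrasts are conventionally reported; carrier placement within the
control distribution is summarised as the fraction of carrier-case scores
above the control 75th percentile. PRS values are inputs, never computed;
the generator emits Z-scores standardised to the control distribution.

## Synthetic cohorts

The generator's defaults are the study conditions: 1,200 cases / 3,800
controls split evenly by country and sex; per-individual Poisson rare-CNV
rates per (type, bin) matched to the observed control frequencies
(e.g. 0.34 for deletions of 50–100 kb, 0.003 for deletions > 1 Mb); a
planted case rate ratio of 4.0 for > 1 Mb deletions and 1.0 elsewhere;
30 common polymorphic regions with carrier frequencies uniform on
[0.02, 0.20]; QC-outlier injection at ~1% per metric; fragmentation of 20%
of calls > 150 kb into 2–3 adjacent pieces whose pairwise gap fractions
stay below ~0.40 so the merge pass reassembles them; and PRS Z-scores
N(0,1) in controls with a +0.8 SD case shift, a shift large enough for the
qualitative carrier-group pattern (carrier cases ≈ non-carrier cases ≫
controls) to emerge at realistic carrier counts. Call lengths are
log-uniform within each bin (> 1 Mb capped at 3 Mb), positions uniform on
GRCh37 autosome lengths weighted by size, rejection-sampled off the
blacklist except for a 2% contamination fraction placed inside it, and
probe counts are length/3 kb with a floor of 6.

What the generator does **not** emulate: probe-level LRR/BAF signal,
linkage disequilibrium, realistic gene structure (exons), relatedness, and
locus-specific mutation hotspots. Passing tests therefore demonstrate the
correctness of the *post-calling* analysis under a homogeneous Poisson
background, not the behaviour of any CNV caller on real intensity data.

`make_table_fixture` is the bridge from printed contingency counts to
end-to-end exact tests: it lays the exact count grid out as degenerate
calls at distinct non-overlapping loci (bin-representative lengths,
clean QC metrics, round-robin sample assignment so no two same-sample
calls are adjacent), so the full pipeline returns precisely the input grid.

## Problem sizes and numerical checks

The test suite exercises oracle equivalence on ≥ 1,000 random toy
instances per algorithm (base-pair set oracle for coverage, graph closure
for clustering, quadratic scan for singletons, naive rescan for merging);
parameter recovery over 200 simulated cohorts at the full 1,200/3,800
size using the generator's count layer (the per-sample Poisson draw that
`simulate_cohort` itself uses) feeding the burden statistics, with the
file-level pipeline exercised end-to-end separately; and enrichment
calibration over 500 null fits at n = 600. Acceptance-script replicates
mirror these sizes. Seeds derive from a single master seed; identical
seeds give byte-identical cohorts.

## Known limitations

- Relatedness filtering (π̂) is out of scope: it requires genotypes, which
  the pipeline never sees; the sample table is assumed unrelated.
- Carrier frequency is not an allele frequency; no diploid CNV genotyping
  is attempted.
- ACMG pathogenicity classification is manual curation; the deletion
  report emits the evidence table a curator would use, nothing more.
- The Wald CI is poorly behaved at very small counts (the headline cell's
  13/10 is near the edge of its comfort zone); no exact or profile CI is
  offered because the reproduced tables use Wald intervals.
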