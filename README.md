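# cnvburden

Rare copy-number-variant (CNV) burden analysis for case/control cohorts
genotyped on SNP arrays, built around the question of whether rare
deletions and duplications contribute to a complex disease — here motivated
by autoimmune Addison's disease (AAD), a rare autoimmune destruction of the
adrenal cortex, but applicable to any two-group cohort with PennCNV-style
call lists.

The package is for statistical geneticists who have per-sample CNV calls
(plus array QC metrics) and want a reproducible, tested path from raw call
lists to burden tables, gene-set enrichment and polygenic-score follow-up.

## What it computes

The pipeline post-processes hidden-Markov-model CNV calls and tests for a
case excess of rare variants:

1. **Quality control** — samples are kept iff LRR_SD < 0.3,
   BAF_drift < 0.01, |WF| < 0.05 and NumCNVs ≤ 50; calls are kept iff
   length > 50 kb with > 5 probes; calls with ≥ 50% of their length in
   immunoglobulin/telomeric/centromeric blacklist regions are removed
   (the HLA region is retained).
2. **Fragment merging** — adjacent same-sample calls are merged when
   gap/(merged span) < 0.50, then again at < 0.40 (two passes).
3. **Rare-variant filtering** — a stratified reference panel of 200
   controls (25% per country × sex stratum) defines common CNV regions
   (50% reciprocal-overlap clusters with carrier frequency ≥ 2%); calls
   ≥ 50% covered by a common region of the same type are removed, and the
   panel is excluded from analysis.
4. **Burden statistics** — per CNV type and length bin
   (50–100, 100–200, 200–500, 500–1000, >1000 kb), the call frequency
   `f = count / n` in each group, the odds ratio of the 2×2 table
   `OR = a(n₂−b) / ((n₁−a)b)` with Wald 95% CI
   `exp(ln OR ± z·√(1/a + 1/(n₁−a) + 1/b + 1/(n₂−b)))`, and a pooled
   two-proportion z-test (χ²₁-equivalent, no continuity correction by
   default). Bonferroni threshold 0.005 for the 10 binned tests.
   Singleton-only and per-country stratified tables are included.
5. **Gene-set enrichment** — logistic regression of case status on the
   number of distinct genes hit by a sample's rare CNVs, adjusted for total
   CNV kb and segment count (robust to case/control differences in CNV
   size and rate); candidate gene lists are tested relative to all genes
   by adding the all-gene count as a covariate. One-sided p, threshold
   0.008 (6 tests).
6. **Large-deletion follow-up** — annotation of >1 Mb deletions against a
   locus catalog, report rows merging majority-overlapping deletions with
   affected/unaffected tallies, and Wilcoxon rank-sum comparison of
   polygenic risk score (PRS) Z-scores across carrier × phenotype groups.

A synthetic-cohort generator (`cnvburden.synthetic_data`) emulates all
inputs — QC outliers, common polymorphic regions, per-bin Poisson rare-CNV
rates, caller fragmentation, a planted case excess of large deletions, and
group-shifted PRS scores — so the whole pipeline is testable without access
to any cohort data.

## Worked example

```python
import cnvburden as cb

# simulate a cohort of 1,200 cases / 3,800 controls with a planted
# rate ratio of 4 for >1 Mb deletions (control rate 0.003/person)
bundle = cb.simulate_cohort(cb.SyntheticCohortSpec(seed=1))
cfg = cb.PipelineConfig(panel_size=200, seed=1)
res = cb.run_stages(bundle.samples, bundle.calls, cfg,
                    bundle.blacklist, bundle.retain, prs=bundle.prs)
print(res.flow.to_string(index=False))
print(res.burden[res.burden.cnv_type == "DEL"].round(3).to_string(index=False))
```

prints the stage-by-stage flow report

```
                 stage  n_samples  n_calls
                 input       5000    25196
             sample_qc       4907    24729
        merge_adjacent       4907    24001
call_size_probe_filter       4907    24001
   blacklist_exclusion       4907    23893
           rare_filter       4707     6380
```

and the deletion burden table

```
cnv_type        bin  case_count  control_count  case_freq  control_freq    OR  ci_low  ci_high     p
     DEL   50-100kb         402           1234      0.343         0.349 0.972   0.846    1.117 0.687
     DEL  100-200kb         296            847      0.252         0.240 1.071   0.919    1.247 0.380
     DEL  200-500kb          88            300      0.075         0.085 0.874   0.683    1.120 0.287
     DEL 500-1000kb          24             55      0.020         0.016 1.321   0.814    2.144 0.258
     DEL    >1000kb          11             13      0.009         0.004 2.564   1.146    5.739 0.018
     DEL        all         821           2449      0.700         0.693 1.033   0.895    1.193 0.655
```

Reading the `>1000kb` row: 11 case deletions among 1,173 analysed cases
versus 13 among 3,534 analysed controls — an estimated odds ratio of 2.6
(95% CI 1.1–5.7) for this replicate of the planted fourfold excess, not
crossing the Bonferroni threshold of 0.005. The overall deletion burden
(`all` row) is null, as simulated.

The same analysis is available from the shell
(`cnvburden simulate`, `cnvburden run-all --config cfg.yaml --out-dir out/`,
plus per-stage subcommands `qc`, `merge`, `filter-common`, `burden`,
`enrich`, `annotate`, `prs-compare`).

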