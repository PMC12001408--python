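# urostab

Temporal-stability analysis of the human urinary microbiota from paired
16S rRNA OTU count tables.

## The problem

Whether a single urine sample is representative of a person's urinary
microbial community over months to years is an open question with direct
consequences for microbiome-based diagnostics in urology.  The natural study
design collects **two samples per subject** separated by a known interval
(months apart) and asks how much of the community persists: how many OTUs
are detected at both timepoints, how much relative abundance those
overlapping OTUs carry, and how that shared abundance decays with the
interval between collections.

`urostab` implements that analysis as a reusable, tested pipeline for
researchers working with paired amplicon count data:

1. **Cohort I/O** — dense or sparse-triplet OTU count tables plus
   sample/subject metadata (timepoint, collection method MSU/catheter, sex,
   age, cancer/stone status, interval), validated into a paired cohort.
2. **QC and normalization** — Good's coverage gate
   (C = 100·(1 − F₁/N), pairs excluded when either sample is below the
   threshold, default 85%), removal of global-singleton OTUs, per-sample
   relative-abundance normalization.
3. **Alpha diversity** — iterated rarefaction (default 1,000 reads ×
   1,000 iterations) with bias-corrected Chao1,
   S_obs + F₁(F₁−1)/(2(F₂+1)), and Shannon entropy H = −Σ pᵢ ln pᵢ.
4. **Overlap statistics** — per subject: shared OTU count n_shared, overlap
   fraction, and the *shared relative abundance*
   (abundance₁ + abundance₂)/2 of OTUs detected at both timepoints; cohort
   aggregates stratified by sex, cancer status and collection-method
   combination; a sex-stratified prevalence table of persistent taxa; a
   diagnostic for dominant-but-discordant OTUs.
5. **Beta diversity** — Bray–Curtis dissimilarity Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) and a
   from-scratch sequential PERMANOVA (Gower centering, per-term pseudo-F and
   R², permutation p-values with optional within-subject strata, exact
   enumeration for small n).
6. **Temporal models** — Pearson correlation, exact/approximate Wilcoxon
   signed-rank and rank-sum tests, Kruskal–Wallis, and the decay model

   shared abundance (%) = β₀ + β₁·months + β₂·age + β₃·sex + β₄·cancer + ε

   fitted by OLS with Wald-t confidence intervals (one response row per
   subject makes a per-subject random intercept unidentifiable; see
   `docs/methods.md`).
7. **Synthetic cohorts** — a generator with known ground truth (persistent
   vs transient community components, interval-dependent mixture weight) so
   every stage, including the decay-slope estimator, is testable without any
   external data.

## Worked example

Simulate a default 63-subject cohort and run the core analysis:

```python
import numpy as np
from urostab import (
    generate_cohort, run_qc, cohort_overlap, decay_model,
    interval_subgroup_analysis,
)

cohort, truth = generate_cohort(seed=7)
filtered, report, rel = run_qc(cohort)          # coverage gate + singleton filter
summary, agg = cohort_overlap(filtered, rel)    # per-subject overlap table
fit = decay_model(summary)                      # shared abundance ~ months + ...
sub = interval_subgroup_analysis(summary)       # short vs long intervals
```

Output for seed 7:

```
subjects retained : 63 (0 excluded)
mean OTUs/sample  : 71.6
mean overlapping  : 28.8 +/- 21.6
shared abundance  : 85.8% +/- 19.7%
decay slope       : -0.552 %/month (95% CI [-0.99, -0.11], p = 0.0151)
intercept         : 104.47%
3-15 months group : 92.3% +/- 21.0%
>15-40 months     : 80.6% +/- 17.1%
```

Reading: paired collections from this synthetic cohort share on average
~29 OTUs carrying ~86% of the community's relative abundance, and each
additional month between collections lowers the shared abundance by about
0.55 percentage points (a single-cohort estimate of the generator's true
−0.66 %/month drift; the 95% CI covers it).

The same analysis is available from the shell:

```bash
urostab simulate --seed 7 --out sim/
urostab overlap --table sim/otu_table.tsv --metadata sim/metadata.tsv --out results/
urostab model   --table sim/otu_table.tsv --metadata sim/metadata.tsv --out results/
urostab run     --config pipeline.yaml      # full qc→alpha→overlap→beta→model run
```

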