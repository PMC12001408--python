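# Methods

This note documents the statistical procedures implemented in `urostab`,
the assumptions behind them, the design choices made where the design was
genuinely open, and what the synthetic-data validation does and does not
demonstrate about real data.

## Data model and quality control

The unit of analysis is a *paired cohort*: each subject contributes exactly
two urine samples (timepoint 1 and 2) separated by a known interval in
months, summarized as an integer OTU count table (samples × OTUs).  Tables
are kept in lexicographic id order internally, which makes every downstream
statistic invariant to input row ordering by construction.  Zero-count OTUs
and samples are preserved at I/O time so that filtering is always an
explicit, auditable operation.

QC runs in a fixed, logged order:

1. **Good's coverage gate.**  Per sample, C = 100·(1 − F₁/N), where F₁ is
   the number of OTUs observed exactly once *in that sample* and N the
   sample's reads.  C estimates the percentage of reads drawn from taxa that
   would be seen again on resequencing, i.e. sequencing-depth adequacy.  A
   subject is excluded — both samples — when any of its samples has
   C strictly below the threshold (default 85, percent scale).  Coverage is
   computed on raw counts, before any OTU filtering, because the gate judges
   the sequencing effort of the original library.
2. **Global-singleton removal.**  OTUs whose *summed* count across the whole
   dataset equals exactly 1 are likely sequencing artifacts and are dropped.
   Sample-level singletons (used by the coverage gate) and global singletons
   are distinct concepts and named apart in the code.
3. **Relative-abundance normalization.**  Each sample's counts are divided
   by its total so proportions sum to 1.  Proportions are stored in [0, 1]
   throughout; reporting layers multiply by 100.  Normalization is
   scale-invariant: multiplying a sample's counts by k > 0 leaves its
   proportions unchanged.

## Alpha diversity

Richness and evenness are compared across unequal sequencing depths by
iterated rarefaction: each sample is subsampled *without replacement*
(multivariate hypergeometric) to a common depth (default 1,000 reads),
the index is computed, and the draw is repeated (default 1,000 iterations);
per-sample means and SDs over iterations are reported.  Subjects with any
sample below the depth are excluded as a pair to keep paired comparisons
balanced.

* **Chao1** (richness): the bias-corrected form
  S_obs + F₁(F₁−1)/(2(F₂+1)) is the default because it stays finite when no
  doubletons are present; the classic F₁²/(2F₂) variant is available for
  sensitivity runs.  Chao1 ≥ S_obs always, with equality iff F₁ ≤ 1.
* **Shannon** (evenness): H = −Σ pᵢ ln pᵢ over detected taxa, natural log by
  default (the convention of the R ecosystem this analysis style comes
  from); the base is configurable.

Each sample's RNG stream is derived from (seed, SHA-256(sample id)), so
results are bit-reproducible under a fixed seed and unchanged when the
cohort is reordered or subset.

## Overlap statistics

For one subject with relative-abundance vectors p⁽¹⁾, p⁽²⁾ on a common OTU
index, with presence defined strictly as abundance > 0:

* n_shared = #{i : pᵢ⁽¹⁾ > 0 and pᵢ⁽²⁾ > 0};
* frac_shared = n_shared / denominator.  The denominator is the **mean of
  the two per-sample richness values** by default.  This choice is the one
  consistent with reporting an overlap percentage alongside mean overlap
  and richness counts (41/152 ≈ 27%), but it is not canonical, so `union`
  and `min` denominators are available as options.
* shared_abund_t = Σ_{i shared} pᵢ⁽ᵗ⁾, and
  shared_abund_mean = (shared_abund_1 + shared_abund_2)/2 — the statistic
  whose temporal decline quantifies community drift.  It is symmetric in
  timepoint order, and moving mass from a shared OTU onto a one-sided OTU
  can only decrease it.

No minimum-abundance detection threshold is applied beyond global-singleton
removal.  The prevalence table counts an OTU as present for a subject only
when detected in *both* of the subject's samples, tallies by sex, and keeps
rows reaching the prevalence threshold (default 50%) in at least one sex.
The dominant-discordant diagnostic flags OTUs with relative abundance
strictly above a threshold (default 0.5) in one sample and exactly 0 in the
other; such taxa explain the lowest-overlap pairs.

## Beta diversity and PERMANOVA

Bray–Curtis dissimilarity d(x, y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) on relative
abundances.  PERMANOVA is implemented from first principles:

* A = −D²/2 is double-centered (Gower) to G; SS_total = tr(G), which equals
  Σ_{i<j} d²ᵢⱼ / n (verified to 1e−9 in tests).
* Terms enter sequentially (Type I).  An orthonormal basis of the
  accumulated design columns (intercept first; categorical terms dummy-coded)
  is built by Gram–Schmidt; SS of term k is the increment in Σⱼ qⱼᵀG qⱼ over
  its basis vectors, and df is the rank gain.  Confounded (zero rank gain)
  and constant terms raise errors.
* pseudo-F = (SS_term/df_term)/(SS_res/df_res).  For Euclidean-embeddable
  distances and a single two-level factor this reduces to the classical
  one-way ANOVA F, which the tests exploit as an oracle.
* p-values come from permuting sample labels, free by default, or restricted
  within strata (e.g. within subject for paired designs) when requested.
  The add-one estimator p = (1 + #{F* ≥ F})/(1 + n_perm) is used so p is
  never exactly 0.  Tie comparison uses a relative tolerance of 1e−8 so
  permutations reproducing the observed grouping always count as ties.
  For n ≤ 8, `n_permutations="all"` enumerates all n! permutations and
  reports the exact proportion.
* Single-variable models fitted one term at a time (`single_term_permanova`)
  mirror per-variable R² reporting; the sequential multi-term mode logs its
  term order.  Whether a paired design should use free or within-subject
  restricted permutations is a judgment call; both are exposed.

## Hypothesis tests

Test selection (parametric vs rank-based) is an explicit caller switch, not
an automatic normality gate.  The Wilcoxon signed-rank test drops zero
differences, uses the exact sign-enumeration null for ≤ 25 nonzero tie-free
differences and otherwise a normal approximation with tie and continuity
corrections; the rank-sum (Mann–Whitney), Kruskal–Wallis and (Welch) t
tests follow standard definitions.  Exactness boundaries are validated
against independent dynamic-programming enumerations of the null
distributions; approximations agree with enumeration to within 0.01 at the
switchover.

## The decay model

The temporal drift of the community is modeled on the per-subject summary:

shared_abund_mean (%) = β₀ + β₁·months + β₂·age + β₃·sex + β₄·cancer (+ β₅·method) + ε

A design with exactly one response row per subject cannot identify a
per-subject random intercept — it is completely confounded with the
residual, and an REML fit would return the same fixed-effect point
estimates with an arbitrary variance split.  The model is therefore fitted
by OLS with Wald-t confidence intervals (df = n − p).  A MixedLM profile
(`mixed_decay_model`) is provided for genuinely replicated designs and
refuses to run when every group has a single row.

Conventions: the response is on the percent scale (so β₁ reads as
percentage points of shared abundance per month); sex is coded F = 0
reference, cancer and catheterized-first-collection as 0/1 indicators;
marginal R² = Var(fitted)/Var(response).  Standardized betas z-score the
continuous predictors (months, age) only and leave the response
unstandardized — the convention is recorded in the fit object because no
single standard exists.  The interval-subgroup analysis splits subjects at
15 months (boundary to the short group), reports group means ± SD and a
months-only within-group fit; a months-only simple model over the full
range is available by passing `terms=("months",)`.

## The synthetic cohort generator

The generator exists so that every stage, and especially the decay-slope
estimator, can be validated against known truth without external data.  It
emulates a 63-subject paired urine cohort: per-subject taxon pools drawn
log-normally with mean 152 and SD 128 (truncated at ≥ 5, and at half the
global pool of 2,000 when an extreme draw is infeasible), long-tailed
within-subject compositions (Dirichlet, concentration 0.3), sequencing
depths log-normal with mean 11,524 and SD 8,669 truncated at ≥ 1,000 (so
default rarefaction is always feasible — lower the truncation to exercise
the exclusion rule), intervals uniform on 3–40 months, and covariates
matching the cohort's demographics (age ~ N(61.1, 14.8) truncated at 18,
P(male) = 43/63, P(cancer) = 28/63, P(stones) = 22/63,
P(catheterized first sample) = 26/63).  Log-normal forms for richness and
depth are pragmatic defaults — only means and SDs are constrained by the
emulated design — and every parameter is overridable.

**Drift mechanism.**  Each subject has a persistent component (a
Binomial(S, 0.27) subset of its S taxa, with its own Dirichlet profile) and
a timepoint-specific transient component drawn from previously unused taxa.
Both timepoints are mixtures

composition_t = w·persistent + (1−w)·transient_t,

so the measured shared relative abundance at either timepoint equals w up
to multinomial detection loss, and the averaged statistic the pipeline
computes is a direct probe of w.  Drift is modeled on this
shared-abundance scale directly — not through per-taxon dynamics — because
that is the scale on which the phenomenon is quantified, and it makes the
generative slope the estimand of the pipeline's own estimator.

**Noise on a bounded scale.**  w has mean exactly
(99.78 − 0.66·months)/100 and is drawn from a Beta distribution with that
mean and an SD of 0.15, capped at 95% of the feasibility bound
√(μ(1−μ)) near the boundaries.  A Beta variate is used deliberately
instead of a clamped Gaussian: with an intercept near 100%, clamping a
Gaussian at 1 would bend the regression function downward at short
intervals and bias any linear fit toward zero (the derivative of
E[min(a+ε, 1)] is Φ((1−a)/σ) times the latent slope, as low as ~0.56 here),
making the configured slope unrecoverable in principle.  The Beta
construction keeps E[w | months] exactly linear while respecting the [0, 1]
support, so unbiased recovery is a property of the estimator, not an
accident of the noise model.  Near the short-interval boundary the capped
SD makes the Beta strongly skewed, producing occasional very low weights —
qualitatively matching pairs whose shared abundance collapses despite a
short interval.

**What passing the synthetic suite shows — and what it does not.**  The
recovery experiment (200 cohorts at defaults; mean fitted slope within
2 Monte-Carlo SEs of −0.66 %/month, ≥ 93% CI coverage) demonstrates that
the pipeline's estimator is unbiased with correct uncertainty under the
generator's assumptions: linear mean drift, independent subjects,
interval-independent persistence counts, multinomial sequencing noise.
Real urine data may violate any of these — age/interval confounding,
taxon-specific dynamics, compositional correlations between persistent and
transient taxa, batch effects — so the suite validates the *software and
estimator*, not the biological model.  Detected per-sample richness in
synthetic cohorts is below the latent pool size (rare taxa fall under the
detection limit at realistic depth), which mirrors real data only
qualitatively.

## Numerical choices

* Rarefaction identity: when a sample's total equals the depth the original
  vector is returned (SD 0 across iterations).
* Empty inputs: all-zero vectors raise `UndefinedStatisticError` for
  coverage/Shannon/Bray–Curtis; Chao1 of an empty sample warns and returns 0.
* Relative-abundance rows must sum to 1 within 1e−9; zero-read samples are
  rejected by name.
* Rank-deficient decay-model designs raise a collinearity error naming the
  aliased columns rather than silently dropping terms.
* The pipeline's JSON summary rounds floats to 10 decimals so fixed-seed
  runs are byte-identical.

## Validation problem sizes

The automated suite uses problem sizes chosen to give tight oracle
comparisons at interactive runtimes: oracle agreement on ≥ 100 random
instances per statistic; rarefaction versus the hypergeometric closed form
E[S] = Σᵢ(1 − C(N−nᵢ, d)/C(N, d)) on 20 samples × 1,000 iterations (judged
by a combined 3-SE z-score with a 5-SE per-sample guard, so twenty
comparisons do not inflate the false-alarm rate); PERMANOVA exact-p
enumeration and null-uniformity on n = 6 two-group designs (500
replicates); rank-test enumeration up to n = 20–26; and the 200-cohort
recovery experiment at full default scale (63 subjects each).
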