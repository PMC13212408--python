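# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the places where the design was genuinely open.

## The vulnerability index

Each task contributes one continuous summary metric.  Standardization
pools **all rows passed in** — the combined exposed/comparison sample —
using the sample SD (n−1 denominator).  Classification is per task:
`both_tails` (|z| > 1 atypical), `high_tail` (z > 1) or `low_tail`
(z < −1).  Two conventions are fixed here and matter at the margins:

* the boundary |z| = 1 exactly counts as **normative** ("within 1 SD"
  read inclusively) — a measure-zero choice for continuous metrics but a
  real one for discretised inputs;
* a task whose observed values have zero variance is an error
  (`DegenerateScaleError`), not a silently all-normative task.

Aggregation: low = 0 atypical tasks, medium = 1, high = ≥ 2, over the
participant's *available* tasks; fewer than two available tasks means the
participant is `excluded` (a value, not an error — exclusions are logged
by the pipeline).  Callers analysing a subsample (the longitudinal stage)
reuse the full baseline sample's task means/SDs via the
`means=`/`sds=` arguments of `standardize`/`build_index`, because the
index is built once at baseline and carried forward.

When a task has no configured directionality, `both_tails` is the
fallback.  The *default study rule set* used by the generator and the
analysis scripts is deliberately one-tailed per task (threat bias and
emotion-intensity high-tail; trust, reward-learning and effort low-tail).
The reason is structural: with approximately normal metrics and pooled
standardization, a two-sided 1-SD cut fixes each task's atypicality rate
near 32 %, and five such tasks make a predominantly-low category
distribution impossible (P(all normative) ≈ 0.68⁵ ≈ 0.15).  One-tailed
cuts put the per-task rate near 10–21 % and reproduce the intended
low-heavy distribution with a visible exposed-group excess in medium and
high.  Substantively, each task also has a theoretically expected
direction of maltreatment-related deviation, which is what the one-tailed
defaults encode.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with defaults anchored to the study's group summaries:

| parameter | MT (n = 85) | NMT (n = 90) |
|---|---|---|
| age, years | 12.8 (2.4) | 12.9 (2.1) |
| pubertal status (PDS) | 2.4 (0.8) | 2.4 (0.8) |
| IQ | 98.5 (11.4) | 104.4 (11.0) |
| SES (0–5 ordinal) | 3.3 (1.0) | 2.9 (1.0) |
| baseline SDQ (0–40) | 12.4 (6.4) | 7.3 (5.6) |
| % female / % Caucasian | 48.2 / 38.8 | 52.2 / 44.4 |
| follow-up available | 57/85 | 47/90 |

Task metrics are per-group normals (unit SD; exposed group shifted
0.45 SD in each task's atypical direction), each missing completely at
random with probability 0.10.  SDQ and SES are latent normals rounded and
clamped to their ordinal ranges.  Follow-up availability is MCAR per
group (the study reported no systematic baseline differences between
followed and unfollowed participants; one source paragraph gives the
comparison-group follow-up n as 47 and another as 41 — the generator
takes 47/90 and exposes the rate as a parameter).

The follow-up SDQ is generated **conditionally on the vulnerability
category the index module itself assigns** to the participant's generated
metrics: a Bernoulli increase indicator at the configured probability for
the (group × category) cell — defaults: exposed low/medium/high =
0.35/0.45/0.90, comparison flat 0.40 — then an integer score equal to
baseline ± (1 +) a Poisson(2.5) jump, clamped to [0, 40].  Because the
outcome is wired to the computed category rather than a latent copy, the
generator supports honest parameter-recovery experiments on the
downstream regression.  A baseline already at the ceiling (probability
≈ 0 under the defaults) cannot increase and is recorded as stable.
Participants in the `excluded` category use the group's low-category
probability.  Randomness: one integer seed; each variable draws from a
sub-stream keyed by (seed, variable name), so identical seeds give
byte-identical tables.

What the generator does **not** emulate: trial-level task behaviour,
non-normal or heteroskedastic metric distributions, correlated task
metrics, informative missingness/attrition, and measurement error in the
SDQ.  Passing tests therefore demonstrate correctness of the machinery
and recoverability of effects under the stated conditions, not robustness
of the index on real data.

## Resampling inference

* **Logistic regression**: IRLS, convergence when the max absolute
  coefficient change < 1e−8 within 100 iterations; working weights
  clipped at 1e−10.  Separation does not raise: the fit is returned
  flagged (non-convergence, a singular weighted normal system, a constant
  outcome, or any |coefficient| > 100), so bootstrap callers can apply
  their exclusion policy.
* **Case-resampling bootstrap**: n rows drawn with replacement per
  replicate (optionally within strata); replicates with separation or a
  collapsed (constant) outcome/predictor column are dropped and counted;
  if more than half fail, an `InferenceInstabilityError` is raised rather
  than reporting numbers from the surviving minority.  Per coefficient:
  bias (mean of replicates minus original fit), SE (replicate SD), 95 %
  percentile interval (2.5th/97.5th percentiles, linear interpolation),
  OR = exp(B).  Percentile rather than BCa intervals: the reporting style
  being mirrored (B, bias, SE, CI) is that of standard statistical-package
  bootstrap output, and significance is declared by the interval
  excluding 0 — no parametric p-value is computed.
* **Chi-square**: Pearson, no continuity correction; empty margins are
  errors.  The Monte-Carlo p-value conditions on both margins (sequential
  multivariate-hypergeometric row construction; the two-row case is
  vectorised) and uses the (1 + k)/(n_sims + 1) estimator so p is never
  exactly 0.  The participant-level bootstrap of χ² reports bias, SE and
  a percentile interval of the statistic; on the published baseline
  counts it reproduces the reported bias (≈ 1.9 vs 1.8) and SE (≈ 5.1).

## Screening diagnostics

Symptom increase is strict (follow-up > baseline; stable counts as no
increase); missing either score propagates missingness.  Sensitivity,
specificity and PPV treat the high category as the positive screen; each
is reported with its numerator and denominator and an exact
Clopper–Pearson interval via the beta-quantile characterisation (lower
bound 0 at k = 0, upper bound 1 at k = n, by definition).  A zero
denominator flags the metric undefined instead of raising.  Per-category
increase probabilities are available raw or adjusted — predicted from the
logistic model at the subgroup's **mean** baseline SDQ (evaluating at
observed covariates and averaging is the other defensible reading; the
mean-covariate mode is the one implemented because it matches
"adjusted for baseline symptom levels" with a single displayed value per
category, and the raw mode is always available alongside).

## Propensity-score full matching

The propensity score is a statsmodels binomial GLM of exposed-group
membership on the six covariates (categoricals one-hot encoded, first
level reference; missing covariates mean/mode-imputed with a warning).
Perfect separation raises a `MatchingError` advising covariate reduction.

Full matching partitions all participants into subclasses with at least
one member of each group.  As in any optimal full match, subclasses are
stars (1 treated with k controls, or k treated with 1 control) and the
objective is the total |propensity distance| from members to their
subclass singleton.  Minimising this over all star partitions is a
minimum-cost bipartite edge cover (minimal edge covers are exactly star
forests); on a scalar score an optimal cover can be taken non-crossing,
giving the exact O(n_t·n_c) recurrence over the two sorted score lists

    dp[i, j] = |t_i − c_j| + min(dp[i−1, j−1], dp[i−1, j], dp[i, j−1]).

An earlier design — a single DP over *consecutive intervals* of the
merged sort order — was rejected after enumeration showed optimal
subclasses need not be consecutive (counterexample: scores ordered
T, T, C, C).  The implemented matcher agrees exactly with exhaustive
star-partition enumeration on hundreds of random instances of ≤ 8
participants (re-verified in the test suite).  Distances default to the
probability scale; the logit scale is an option.  Weights: treated
weight 1; a control in a subclass with a treated and b controls gets
(a/b)·(N_c/N_t), so each group's weights sum to its size.

Balance is summarised as (weighted mean difference) / (unweighted pooled
SD, √((s_T² + s_C²)/2)) for numeric covariates — the unweighted
denominator keeps before/after comparable — and as weighted proportion
differences per level for categoricals.  The post-match association test
treats weighted counts as effective counts in the Pearson statistic
(χ² therefore scales linearly with a global weight rescaling), bootstraps
participants carrying their weights, and simulates the p-value from the
rounded weighted margins; the mechanics of the original post-match test
are not documented, so this is the package's own explicit construction.

## Pipeline and problem sizes

`run_study` executes: index on the full baseline sample → group ×
category bootstrap χ² → follow-up restriction → symptom-increase outcome
→ bootstrapped logistic regression within each exposure group (low as
reference) → screening metrics in the exposed group → optional full
matching with weighted re-test → optional re-fit excluding baseline
SDQ ≥ 20 (the study's high-baseline sensitivity analysis, implemented as
a ≥ threshold flag).  Every dropped participant appears in the exclusion
log with a reason, and the report serialises to JSON losslessly.

Default analyses use R = 5000 bootstrap replicates and 5000 Monte-Carlo
simulations, matching the study.  The test suite and the acceptance
script use smaller, stated sizes chosen for tight statistical checks at
interactive runtimes: calibration experiments use 1000 null tables ×
2000 simulations; parameter recovery uses 100 generated cohorts of
n = 2000 exposed participants with 500 bootstrap replicates each;
matcher-optimality checks use hundreds of exhaustively enumerable
instances of ≤ 8 participants.

## Known limitations

* Per-category odds ratios for the baseline association are not computed:
  the originally reported values (1.24 / 1.67 / 0.65) do not follow from
  the published counts by any standard category-vs-rest formula, so no
  comparable quantity is defined here.
* The weighted post-match χ² uses effective counts; alternatives (Rao–
  Scott corrections, design-based variance) are out of scope.
* The generator's MCAR missingness and independent normal metrics are
  simplifications; see the generator section for the full list.
* With a single scalar propensity score, matching quality degrades when
  the score model is misspecified; no doubly-robust correction is
  provided.
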