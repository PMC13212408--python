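# neurovuln

Cumulative neurocognitive vulnerability analysis for maltreatment-exposure
cohorts: index construction, resampling-based inference, screening
diagnostics and propensity-score full matching, with a synthetic cohort
generator so every stage is testable without restricted participant data.

## The scientific problem

Children exposed to maltreatment are at elevated risk of later
psychopathology, but risk is not deterministic: identifying *which*
children are on a worsening trajectory — before symptoms become
entrenched — is the central problem of preventative child mental health.
One proposed screening approach aggregates performance across several
neurocognitive tasks (threat-related attention bias, trust attribution,
emotion-intensity perception, volatility-adapted reward learning,
effort-based reward sensitivity) into a single **cumulative neurocognitive
vulnerability index**, and asks whether that index predicts symptom
increases over a ~1.5-year follow-up.

This package implements that analysis pipeline for anyone who wants to
apply it to a cohort table, probe its statistical behaviour, or power
future studies against a synthetic cohort with the same structure.

## The index and the inference

For each of up to five tasks, a participant's summary metric `x` is
standardized against the *combined* sample (both exposure groups pooled):

    z = (x − x̄) / s        (s with the n−1 denominator)

A score is **atypical** when it falls more than 1 SD in the task's
atypical direction (`both_tails`: |z| > 1; `high_tail`: z > 1;
`low_tail`: z < −1; the boundary |z| = 1 is normative).  Participants with
at least two available tasks are classified

* **low** — no atypical score, **medium** — exactly one, **high** — two or
  more; fewer than two available tasks ⇒ **excluded**.

Inference mirrors the resampling style of the original analysis:

* group × category association: Pearson χ² with a case-resampling
  bootstrap (bias, SE, 95 % percentile CI of χ²) and a Monte-Carlo
  p-value simulated with both margins fixed, p = (1 + k)/(n_sims + 1);
* symptom change (follow-up SDQ > baseline SDQ) regressed on category
  dummies (reference: low) plus baseline SDQ, by maximum-likelihood
  logistic regression (IRLS) with a case-resampling bootstrap — per
  coefficient: B, bias, SE, 95 % percentile CI, OR; significance = CI
  excluding 0;
* screening metrics for the high category (sensitivity, specificity, PPV)
  with exact Clopper–Pearson intervals;
* propensity-score **full matching** on age, pubertal status, gender, SES,
  IQ and ethnicity: an exact dynamic programme over the sorted scores
  (optimal full matching = minimum-cost bipartite edge cover, solved in
  O(n_t·n_c) on a scalar score), with standardized-mean-difference balance
  diagnostics and a weighted re-test of the association.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort (85 exposed "MT" / 90 comparison "NMT" participants):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_build_index.py
python analysis/03_group_association.py
python analysis/04_predict_symptom_change.py
python analysis/05_propensity_matching.py
```

With seed 1 this prints, among other things:

```
group x vulnerability category counts:
category  low  medium  high
NMT        48      35     7
MT         34      29    22

published counts: chi2 = 5.88, bias = 1.88, SE = 5.11, MC p = 0.0400

MT (n=56):
  high          B=+3.57* bias=-0.29 SE=0.78 CI=[1.86, 4.91] OR=35.64
NMT (n=44):
  high          B=-0.36  bias=+0.42 SE=0.90 CI=[-1.64, 1.84] OR=0.69

MT sensitivity: 12/27 = 44.4% (95% CI 25.5-64.7%)
MT ppv: 12/13 = 92.3% (95% CI 64.0-99.8%)
```

Read: exposed participants pile up in the medium/high categories; on the
*published* baseline counts the bootstrapped χ² machinery reproduces the
reported statistic (χ² 5.88) with bootstrap bias ≈ 1.9 and SE ≈ 5.1; in
the synthetic follow-up subsample, high vulnerability strongly predicts
symptom increase in the exposed group (CI excludes 0) but not in the
comparison group; and a high-vulnerability flag is a highly specific,
high-PPV but only moderately sensitive screen — the qualitative pattern
the index is designed to exhibit.

The same operations are available as a CLI
(`neurovuln simulate|analyze|diagnostics|match|run`) and as plain library
functions (`neurovuln.build_index`, `neurovuln.bootstrap_logistic`, …).

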