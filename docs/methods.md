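# Methods

## Problem and data model

The package predicts whether, and how often, a person will generate
low-back-pain (LBP) billing codes in the year after a cohort examination,
from two linked sources: statutory-health-insurance claims (diagnoses and
fee-schedule entries per billing quarter) and cohort covariates
(demographics, pain scales, medication, social variables). Time is indexed
in billing quarters relative to the examination quarter `Q0`:

| window    | quarters  | use                                        |
|-----------|-----------|--------------------------------------------|
| history   | Q−7..Q−4  | "history of back pain" indicator           |
| baseline  | Q−3..Q0   | baseline code counts, specialties, imaging |
| follow-up | Q1..Q4    | the outcome `y`; never enters predictors   |

An LBP code is any ICD-10 dorsopathy M40–M54 that survives an exclusion
list for cervical/thoracic diagnoses. The default list removes the
cervical-disc category (M50), cervicocranial/cervicobrachial syndromes
(M53.0, M53.1), cervicalgia (M54.2), and any site-coded M-chapter entry
whose site digit marks occipito-atlanto-axial (1), cervical (2),
cervicothoracic (3) or thoracic (4) involvement (e.g. M54.02). The list is
a plain-text, prefix-matched configuration input because the authoritative
catalogue for a given billing system is a deployment detail; enlarging it
can only shrink the outcome (a tested invariant).

The Charlson comorbidity index uses the Quan 2005 ICD-10 prefix mapping
with the original weights; each condition category counts once and the
severe form (complicated diabetes, moderate/severe liver disease,
metastatic cancer) supersedes its milder counterpart.

Record linkage between cohort and claims identifiers is deterministic:
names are upper-cased, candidate pairs are blocked on exact birth date, and
the total Levenshtein distance over surname + given name (plus 1 for a sex
mismatch) classifies pairs as `exact_match` (0), `possible_match_review`
(≤ 2 by default) or `non_match`. Review candidates are flagged, never
auto-decided, because in practice they go to manual review.

## Hurdle model

`y` is zero-inflated — most people generate no LBP code at all, and the
positive counts are not Poisson-thin — so the count law is factorised into
a logistic "any code" part and a zero-truncated count part:

* zero part: `logit P(y>0) = x'β_zero`, fitted by Newton–Raphson with step
  halving on all rows;
* count part: zero-truncated Poisson or negative binomial on the positive
  rows, `log λ = x'β_count`, maximised by L-BFGS-B with analytic gradients;
  the negative binomial uses the mean–dispersion parameterisation
  (variance `λ + λ²/θ`), `θ` optimised on the log scale and bounded in
  `[e^−10, e^15]` because the likelihood is flat in `log θ` at the Poisson
  limit. Starting values: intercept at the log positive mean, slopes zero.

The likelihood separates, so the joint optimum is the pair of part-wise
optima (asserted to 1e-8 in tests). Standard errors come from the observed
information — analytic for the logit part, finite differences of the
analytic gradient for the count part — and ratio CIs are Wald,
`exp(β̂ ± 1.96·se)`. AIC is `−2ℓ + 2k` with `k` counting both parts plus
`θ` when present. Family choice takes the smaller AIC; ties (|ΔAIC| <
1e-6) go to the Poisson, which has one parameter fewer. On equidispersed
data `θ̂` runs to its upper bound, the two log-likelihoods coincide, and
the AIC tie-break therefore also picks Poisson.

Numerics: `log(1 − f(0))` is computed as `log(−expm1(·))`, stable from
λ ≈ 1e-10 up to λ ≈ 1e3; linear predictors are clipped at ±30 before
exponentiation; truncated sampling in the generator uses the inverse-cdf
map `F^{-1}(f0 + U(1−f0))`, which is exact.

Predictive distributions report `π`, the pmf over `0..k_max` (default 50;
tail mass beyond `k_max` is ≤ 1e-3 for λ ≤ 20), and exact first/second
moments computed in closed form rather than from the truncated grid.

## Scoring rules and diagnostics

Four negatively oriented strictly proper rules for count forecasts:
logarithmic `−log P(y)`; quadratic/Brier `−2P(y) + Σ_k P(k)²` (bounded in
[−1, 1], −1 only for a correct point mass); Dawid–Sebastiani
`((y−μ)/σ)² + 2 log σ`; ranked probability `Σ_k (F(k) − 1{y≤k})²` with the
summation limit set by the pmf truncation. Empirical propriety (the true
forecast minimises the expected score) is verified on a grid of Poisson
truth/forecast pairs.

Zero inflation is tested with the score test against a fitted Poisson
model (van den Broek form): with `p0_i = e^{−λ̂_i}`,

```
S = [Σ_i (1{y_i=0} − p0_i)/p0_i]² / (Σ_i (1−p0_i)/p0_i − n·ȳ)  ~  χ²(1).
```

The default covariate set is intercept-only (a test of the marginal
outcome distribution); at the intercept-only MLE the denominator equals
`Σ(e^{λ̂} − 1 − λ̂) > 0`, so the degenerate-denominator error can only be
triggered by an all-zero outcome or ill-fitting covariate models.

Rootograms compare `√observed` with `√expected` frequencies per count;
hanging style places the bar base at `√ê_k − √o_k`, so a base below zero
at `k = 0` reads as zero under-fitting (the classic Poisson-on-overdispersed
signature, exercised in tests).

## Best-subset search

Candidates are declared per model part (`zero`, `count`, `both`). Because
the likelihood separates and the published presentation reports different
predictors per part, the search is part-wise rather than fully crossed
(which would cost `2^p × 2^p`): the zero-part subset is chosen by the mean
out-of-bag binary Brier score over `b` bootstrap resamples of the outer
training data, the count-part subset by the mean Dawid–Sebastiani score of
the truncated count forecast on the out-of-bag positives. Both rules are
configurable. For every subset and bootstrap the count part is fitted with
both families and the AIC winner is scored; the per-bootstrap family
choices are retained in the result so the family decision is auditable.

All `2^p − 1` non-empty subsets per part are visited (counter-asserted);
`p > 25` without a size cap is refused. The same bootstrap index sets are
shared by all subsets (paired comparison), work is partitioned by subset
under joblib, and results are reduced in subset-id order, so the result is
deterministic for a fixed seed regardless of worker count. A subset whose
fit fails in a bootstrap (separation in a small OOB cell, rank deficiency)
loses that bootstrap from its mean and the failure is counted; more than
50% failures disqualifies the subset. The winner is refitted on the full
outer training data. An intercept-only reference score is always computed;
the selected subset never scores worse (tested).

The outer 3:1 split takes `round(0.75·n)` training rows. A published
split of 2869/968 at n = 3837 is not reproducible from any simple rounding
of 3:1 (0.75·3837 = 2877.75) and is consistent with a per-row Bernoulli
split; `outer_split` therefore accepts an explicit `n_validation` to pin
published sizes exactly.

**Selection-consistency limit.** Mean-OOB-score minimisation is not a
consistent selector: a noise predictor that is spuriously associated with
the outcome *within the given outer sample* genuinely improves out-of-bag
prediction in that sample, so it enters the winning subset with
probability ≈ 5–7% per noise variable at n = 2000 (measured; stable under
reseeding of the bootstrap stream, i.e. not curable by increasing `b`).
Exact recovery of a 3-predictor active set against 3 nulls at n = 2000,
b = 50 is therefore ≈ 80–85%, while recovery in the "all actives
contained" sense is essentially 100%. Users who need sparser selections
should pass a `max_subset_size` cap or post-filter by Wald CIs.

## Two-stage workflow

Claims-side and cohort-side searches run independently; the union of the
two winning subsets (with per-predictor provenance labels) forms the
candidate pool of a final joint search. When cohort candidates are noise,
the joint winner usually collapses back to the claims subset (tested at
the ≈ 80% rate implied by the inclusion probabilities above).

## Missing data

Chained-equation multiple imputation with per-variable conditional models:
predictive mean matching (k = 5 donors) for numeric variables, logistic
draws for binaries, multinomial-logit draws for categoricals; 10 sweeps by
default, all other variables predicting each target. Observed cells are
identical across the m completed datasets (asserted byte-wise). Rubin's
relative increase in variance of a variable's mean, `(1 + 1/m)·B/W̄`, is
reported in percent; it is exactly 0 for variables without gaps. The
published workflow's compromise — m = 1 for model training, m = 20 for
validation — is the default configuration at the call sites, not a
constraint. Evaluating one trained model on each completed validation set
yields one ROC per imputation; the pooled AUC is their mean, and the
spread (max − min) is reported, undefined at m = 1.

## Classification evaluation

The zero-part probability is the classifier score. AUC is computed as the
Mann–Whitney concordance (ties ½) — asserted equal to brute-force pairwise
concordance — with a DeLong 95% CI from placement values. Discrimination
bands follow the usual convention: < 0.7 non-acceptable, [0.7, 0.8)
acceptable, [0.8, 0.9) excellent, ≥ 0.9 outstanding (lower edges
inclusive). No probability cutoff is fixed anywhere; confusion-matrix
outputs exist only for a user-supplied threshold.

Seek-of-care strata cross-classify subjects by LBP evidence before/at
baseline versus during follow-up (`0|0`, `0|1`, `1|0`, `1|1`, a partition)
with per-stratum summaries of predicted probabilities, optionally crossed
with pain-severity bands (default NRS 0 / 1–3 / 4–6 / 7–10, configurable —
the exact banding used in published figures is not recoverable). On
generator output the `1|0` stratum (past care, no follow-up code) receives
markedly higher predictions than `0|0`: with predictors dominated by past
utilisation, that misclassification is structural, and the package
reproduces it qualitatively.

## Synthetic-data generator

The generator is the package's ground truth. Covariates are drawn from
simple parametric families moment-matched to the published cohort
description: age ~ truncated normal (52.6, 15.6) on [20, 84]; sex 51.5%
female; family status (10.7/77.5/6.3/5.5% single/married/separated/
widowed); household income log-normal matched to median 1100 €/mean
1300 € (in 100-€ units); pain NRS ~ negative binomial matched to mean
2.69/variance ≈ 6.9, capped at 10; radiating pain mildly associated with
NRS through a logistic link (configurable knob, default +0.15 log-odds per
NRS point); disc prolapse 8%; competing diseases 65/28/7% for 0/1/>1;
physical activity 40/35/25%; benzodiazepine 1.5% and opioid 1.7% use;
linkage consent 94.1%. Where only a published mean/median was available
the remaining shape choices (e.g. the income log-sd 0.578) follow from
moment matching; where nothing was published (competing diseases,
radiating-pain split) values are fixed once at levels typical for a
middle-aged general-population cohort.

Claims history is driven by a standard-normal latent care-seeking
propensity `u_i`: the per-quarter baseline LBP code rate is
`exp(a + 0.8·u_i)`, with `a` solved by root-finding on the realised sample
so that `P(≥1 baseline code) = 0.30` exactly in expectation. History
(Q−7..Q−4) uses the same rate, which makes "history of back pain" and the
baseline-code candidates genuinely correlated predictors, as in real
claims data. Comorbidity diagnosis codes are planted to match the drawn
competing-diseases level, so the Charlson index is derived, not drawn.
ICD codes come from a small pool of genuine lumbar rubrics (70% M54.XX);
provider groups, imaging and intervention fee entries are sampled at
plausible ambulatory-care shares.

The outcome is then drawn from the hurdle law whose linear predictors use
the *derived* candidate matrix — the same feature-engine code path the
analysis uses — with default coefficients equal to the natural logs of the
published joined-data odds/rate ratios (zero part: age 40–69 1.73, age >69
0.74, female 1.34, income/100 € 1.03, disc prolapse 1.32, competing 1
0.74, competing >1 0.37, 2Q codes 2.43, acute codes 0.44, history 6.91;
count part: married 1.44, separated 1.27, widowed 1.60, activity 1–2 h
1.19, >2 h 1.04, NRS 1.01, radiating gluteal/knee/lower-leg 1.20/1.44/
1.34, benzodiazepine 0.79, 2Q codes 1.56, female 1.00). Osteoarthritis,
part of the published joined count model, is not a generator covariate and
is omitted. The intercepts (−3.0 zero part, −0.55 count part) set the
marginal outcome level at ≈ 22% consulters with ≈ 1.7–2 codes each, the
level implied by the published stratum sizes. The age × M54-only
interaction defaults to coefficient 0 (no published estimate) and is
configurable. Follow-up claims rows are laid out so that re-counting them
through the feature engine reproduces `y` exactly (tested).

Because the fitted model is exactly the generating law given the derived
design, maximum-likelihood fits recover every planted coefficient within
Monte-Carlo error; the acceptance suite asserts agreement within 3 Wald
SEs at n = 50,000, and `scripts/acceptance.py` reports the recovered
ratios. Item non-response defaults to the published rates (income 3.5%,
NRS 0.4%, family status 0.3%), MCAR, never touching the outcome; a MAR
mechanism with a calibrated marginal rate is available.

What the generator does **not** emulate: survey design and response
behaviour, private-insurance exclusion logic, seasonal or secular claims
trends, code-position/laterality detail, correlated multi-morbidity
patterns beyond the single latent propensity, and measurement error in
identifiers beyond single-character surname typos. Passing tests therefore
demonstrate correctness of the estimators and the search machinery under
the assumed data-generating law, not predictive performance on real
claims.

## Problem sizes used in the test and acceptance runs

Parameter recovery runs one generation + one fit at n = 50,000. Generator
calibration and distributional checks use n = 20,000. Search behaviour is
exercised at n = 2000 with b = 50 bootstraps and 6 candidates (63 subsets
per part), and the planted-subset recovery study repeats that 20 times.
These sizes keep a full run on a single CPU in minutes while leaving
Monte-Carlo error well below the tolerances asserted.

## Known limitations

* The part-wise search cannot represent a criterion that trades zero-part
  complexity against count-part complexity; the capped fully crossed
  search is the escape hatch for small `p`.
* Wald CIs can misbehave for rare binary predictors (benzodiazepine use at
  1.5% prevalence yields wide intervals at cohort-scale n).
* The imputation model is linear/logistic; strongly non-linear
  relationships between covariates are imputed at their linear projection.
* DeLong CIs assume independent subjects; clustered claims data would need
  a cluster-aware variance.
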