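# Methods

This note documents the models, conventions, and design choices behind
`panelqc`: what the synthetic cohorts emulate, how each quality metric is
defined at its boundaries, and where genuinely open decisions were resolved.

## The synthetic instrument

The packaged codebook defines a general-health survey of 39 ordinal items
(categories 1–5): seven 4-item domain scales (physical function, anxiety,
depressive symptoms, fatigue, sleep disturbance, ability to participate,
pain interference), a 2-item cognitive scale, and nine auxiliary items that
extend the physical-function battery to six items, form two 3-item
mixed-direction sleep sets, and supply five similar-topic partner items for
the kappa consistency pairs. Two sleep items (`sd1`, `sd4`) are asked in the
positive direction and stored as the respondent saw them; they are inverted
(r → 6 − r) only at scoring time. A 24-condition health checklist carries two
fake conditions ("syndomitis", "chekalism"). Each respondent is assigned 72
items in total (39 ordinal + 26 checklist + 6 demographics + 1 open text);
this full count is the denominator of the speed screen, while the
completeness screen uses the 39-item ordinal matrix, since checklist and
demographic answers are never item-missing in the generator.

## Cohort generator

**Attentive response model.** Each respondent carries eight latent domain
traits θ with an exchangeable correlation of 0.4 by default (any symmetric
PSD matrix is accepted). An item response is generated as
y = √0.7·θ_domain + √0.3·ε with ε ~ N(0,1), cut at the equal-spaced
thresholds (−1.5, −0.5, 0.5, 1.5) into categories 1–5. The loading of 0.7
yields inter-item correlations near 0.7 before categorization and Cronbach α
around 0.85–0.89 for 4-item scales after categorization — the range typical
of short health-profile scales. This is deliberately the simplest model with
tunable inter-item correlation; graded-response calibration is out of scope.

**Demographic structure.** Six weighting variables (age group, gender,
race/ethnicity, education, income, census region) are sampled independently
from stated population margins, distorted by multiplicative per-variable
selection weights (realized share of a category with marginal p and bias b
is bp/Σbp). A shared health factor h — a sum of per-category effects of age,
income, and education — shifts every trait by ±0.5·h with a per-domain sign
(+ for functioning domains, − for symptom domains), so demographic selection
bias propagates into health estimates and raking has something real to
correct. The packaged convenience-panel bias skews young, highly educated,
and lower-income; the probability-panel config applies no bias.

**Personas** (mutually exclusive labels, recorded as ground truth):

* *attentive* — latent-trait responses; skips each item independently with
  probability 0.02; endorses checklist conditions according to true status,
  generated from base prevalences tilted by the health factor
  (p = expit(logit(prev) − 0.8h)); never endorses a fake condition.
* *straightliner* — one constant response per consecutive
  same-response-category block, drawn avoiding each block's allowed category
  (5 for physical function, 3 for the sleep sets) so plants violate all three
  straight-lining rules by construction; answers every item.
* *speeder* — attentive responses but total duration forced below 1 s per
  assigned item (uniform 0.3–0.95 s/item); other personas draw lognormal
  seconds-per-item (median 12 s convenience / 7 s probability, σ = 0.5/0.4).
* *misrepresenter* — endorses each fake condition with probability 0.95 and
  each real condition with probability 0.6. The real-condition rate is a free
  parameter (no published generative value exists); 0.6 encodes the observed
  tendency to endorse "all or essentially all" conditions. An optional
  secondary flag (`misrepresenter_straightline_frac`, 0.10 in the packaged
  convenience config, 0 by default in the API) makes a share of
  misrepresenters also straight-line, reproducing the observed drop in
  straight-lining when fake endorsers are excluded while keeping one
  unambiguous persona label per respondent.
* *copier* — open-text answer pasted from a shared template sentence
  (14 words); copiers are paired so every copier shares a verbatim run with
  at least one other (an odd trailing copier joins the previous pair; a
  persona draw with exactly one copier is folded back into the attentive
  pool). All other personas answer with seeded word salad of 12–25 distinct
  words from a 1200-word synthetic vocabulary, which makes the
  10-word/75%-coverage rule exactly decidable and false positives
  practically impossible.

Planted incompletes (answering fewer than half of the ordinal items) are an
explicit toggle applied to attentive respondents. Determinism: every
component draws from a named substream keyed by CRC32 of
(seed, stage, component), so identical configs produce byte-identical tables
and toggling one pipeline stage never shifts another's randomness.

**What the generator does not emulate:** platform mechanics (batch release,
payment), longitudinal attrition beyond a single retention probability,
item-level response styles (acquiescence), differential item functioning, or
any link between misrepresentation and demographics. Passing detector tests
on these cohorts therefore demonstrates correctness of the rules and
estimators on their stated definitions — plants are constructed to be
unambiguous — not field sensitivity on real respondents, where careless
behavior is heterogeneous and partial.

## Screening conventions

Both screens use strict inequalities, so exactly 1 s/item and answering
exactly half are retained — the rules' wording is "less than" and "at
least". Out-of-range response values are coerced to missing and counted, not
grounds for exclusion. A respondent failing both screens is tallied once, in
the too-fast row, so the accounting identity
final = analytic + too_fast + incomplete always holds. Fake-condition
endorsement is evaluated on the analytic set only and does not remove
respondents; it defines the "no fake conditions" sensitivity subset used by
every downstream metric.

## Metric definitions at the edges

* **Weighted kappa** uses pairwise-complete cases and disagreement weights
  (i−j)² over the full declared category range. When chance disagreement is
  zero (both marginals degenerate on one category) kappa is undefined and
  reported as NaN, never 0. Interpretation bands round kappa half-up to two
  decimals first (0.205 → 0.21 → "fair"), matching reporting precision.
* **Straight-lining.** The all-sets rule evaluates answered items within
  each consecutive set and does not flag respondents with a fully unanswered
  set; the targeted battery rules require complete batteries (conservative —
  a missing item makes constancy unverifiable). The constants may differ
  across sets.
* **Mean root of pairs** rp = 1 − mean over item pairs of √|r_i − r_j|,
  divided by √(max − min); respondents with fewer than two answered battery
  items are undefined and excluded from battery means. The rescaling by
  √range is this package's reading of "rescaled to range from 0 to 1" (the
  originating formula is not reprinted anywhere authoritative); it is exact
  for the extreme pair (1,5) and exposed as the only supported convention.
* **Winsorized burden** caps durations at the 97.5th percentile under
  linear interpolation between order statistics (numpy's default). The cap
  is an exact fixed point when 0.975·(n−1) is integral and idempotent to
  within adjacent-order-statistic interpolation otherwise.
* **Cronbach alpha** recodes reverse-keyed items, deletes listwise within
  scale (pairwise covariance estimation is intentionally not offered — with
  2% independent missingness listwise costs ~8% of cases and keeps the
  estimator's textbook form), requires ≥3 complete cases, and is undefined
  when the total score has zero variance.

## Comparing alpha coefficients

The independent-samples comparison uses the Feldt ratio
W = (1−α₁)/(1−α₂). Under a compound-symmetric Gaussian model,
(1−α̂)/(1−α) in one sample follows F(n−1, (n−1)(k−1)); the common shortcut
of referring W to F(n₁−1, n₂−1) ignores the (n−1)(k−1) denominators and is
measurably liberal — Monte-Carlo here gave 7–10% rejections at nominal 5%
(n = 500/arm, worst at k = 4). Each arm's degrees of freedom are therefore
variance-matched to the exact single-sample distribution:
d = (n−1)(k−1)/k, which equates var(ln W) with its delta-method value
2/(n−1) + 2/((n−1)(k−1)) per arm. Measured type-I error is 4.4–6.1% across
k ∈ {4, 8, 10}. The p value is two-sided (2·min of the F tail areas), and a
χ²₁ statistic (ln W)²/(2/d₁ + 2/d₂) is reported alongside for conventions
that label this a chi-square test. Both forms agree at large n. The test
treats the all/no-fake columns as if independent when used for that contrast
in the pipeline report — a reporting convention, flagged as such in the
bundle key.

## Raking

Weights start at 1 (or supplied base weights, normalized), cycle through the
raking variables in config order multiplying by target/current weighted
share, then are trimmed to the cap and rescaled to mean 1 — repeatedly, so
the cap still holds after rescaling. Convergence is declared when the total
absolute imbalance, Σ over variables and categories of
|weighted share − target|, reaches the tolerance (default 10⁻⁶; the
diagnostic is also judged against the conventional 0.01 reporting
threshold). Targets must be strictly positive and sum to 1 per variable
(files may hold percentages; they are normalized at load); a nonzero target
for an empty sample category is an immediate error (no solution exists).
Missing demographic values become an explicit "(missing)" category raked to
its own sample share — weight-neutral — with stated targets scaled to the
remainder. Variable order does not affect the converged solution (a tested
property, not an assumption). The packaged targets reproduce national adult
margins for the six weighting variables; the published source collapses the
top two education rows into one 34.8% figure, which is split 19.1/15.7 in
proportion to the weighted probability-panel sample.

## T-scores, benchmarks, and correlations

Scale scores are means of recoded items, prorated when at least half of a
scale's items are answered. T = 50 + 10(x − mean_ref)/sd_ref against a
*synthetic* reference cohort (attentive-only, unbiased demographics,
generated from the same seed fan-out) — this reproduces the construction of
the T metric but is **not** an official item-calibration lookup for any
published instrument. Differences above 2 T-score points (strictly) are
flagged as at least "small" effects. Benchmark tables preserve the
all / no-fake / weighted stage order. Correlation matrices are Pearson by
default (Spearman available), pairwise-complete, with undefined cells (for
constant columns or < 3 complete pairs) reported as NaN; 95% CIs use Fisher's
z ± 1.96/√(n−3). Matrix comparison summarizes the lower triangle: mean and
max |Δr|, exceedance shares at 0.05/0.10/0.15/0.20, sign flips (r₁r₂ < 0),
and the share of pairs where the second sample's coefficient is larger in
magnitude. Demographic variables enter correlations as age-group midpoints
and ordinal education/income codes.

## Problem sizes

Packaged pipeline defaults: 3000 convenience + 2000 probability respondents
with a 2000-respondent reference cohort — large enough for stable
correlation and reliability estimates while a full two-panel run completes
in seconds. The reproduction script uses n = 6750 for misrepresenter-rate
recovery (the convenience analytic size it emulates), n = 6000 for raking,
~2000 texts for false-positive screening, and 1000 replicates for each
calibration experiment. Mixture-recovery and calibration tests use 3-σ
binomial bands at these sizes.

## Known limitations

* The copied-text detector measures exact token runs after casefolding and
  punctuation stripping; paraphrase or near-duplicate detection is out of
  scope, as is human-judgment classification of nonsensical answers.
* Raking provides no variance estimation (no replicate weights or GREG
  calibration); the effective sample size is the only dispersion diagnostic.
* The alpha comparison assumes compound symmetry; congeneric (unequal
  loading) scales make both W and its reference distribution approximate.
* T-score standardization against the synthetic reference is suitable for
  within-package comparisons only.
* Regions are modeled at 4-census-region granularity; no metro/nonmetro
  subdivision.
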