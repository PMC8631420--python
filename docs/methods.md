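# Methods

This note records the models, calibration choices and numerical
conventions behind `vigitext`, and what the synthetic-data experiments do
and do not demonstrate about real self-report channels.

## Synthetic corpus generator

### Generative model

Each report carries latent covariates and 12 binary symptom indicators.

* **Gender** is disclosed with probability 0.587; disclosed reporters are
  female with probability 0.591.  **Age** is disclosed with probability
  0.587, drawn uniformly on [18, 90].  **Dose phase** is disclosed with
  probability 0.736 and is then first/second/both with probabilities
  0.493/0.148/0.360.  These rates mirror the disclosure pattern of a real
  crowd-reporting channel of ~11,500 messages.
* Symptom *c* is Bernoulli with probability
  `p_c = clip(base_c · g · d · a, 0, 1)`, where `base_c` are the default
  per-class prevalences (fever 0.4743, pain 0.4657, fatigue 0.3354,
  headache 0.2479, chills 0.2302, insomnia 0.0521, lymph-node enlargement
  0.0162, erythema 0.0277, swelling 0.0179, pruritus 0.0173,
  nausea/vomiting 0.0305, diarrhea 0.0057),
  `g = 2.5/2.1` for disclosed women (1 otherwise), and `d = 2.2/1.9` for
  reports covering a first dose — category *first* or *both*; a both-dose
  report includes the first-dose reaction (1 otherwise).  Undisclosed
  covariates act neutrally.
* The **age factor** is
  `a = max(0, 1 − β·(age − age_ref) / (E0·g·d))` with `β = 0.0457` and
  `E0 = Σ_c base_c ≈ 1.921`.  Normalising by the report's own expected
  count `E0·g·d` makes the age effect *additive*: every report's expected
  AE count declines by exactly β per year, so an OLS fit of count on age
  over the whole mixed-covariate corpus recovers β without attenuation.
  Normalising by `E0` alone would make the marginal slope `β·E[g·d] ≈
  1.17·β` — a mis-calibration the package deliberately avoids.
* `age_ref = 54`, the mean of the default age range.  Anchoring the
  multipliers at the mean age keeps the female/male and first/second
  ratios of mean counts equal to the configured multipliers corpus-wide
  (an additive age term cancels from a ratio only when its mean
  contribution is zero), and it removes age-factor clamping entirely on
  [18, 90] (min expected count 1.921 > 0.0457·36 = 1.645).  The only
  residual nonlinearity is the per-class clip at 1 for fever/pain among
  the youngest women with a first dose (~1.6% of reports), which shifts
  the marginal slope by < 0.4%.
* **Optional correlation factors.**  By default the 12 indicators are
  independent given covariates (covariate mixing alone induces mild
  positive correlation ≈ 0.05–0.12 between prevalent classes).  A latent
  factor `(classes, strength s)` multiplies the member classes'
  probabilities by `(1 ± s)` with a fair coin, preserving marginals while
  inducing positive within-group correlation.
  `SyntheticConfig.with_systemic_factor(s)` switches on the shared
  systemic-reaction factor (fever/chills/fatigue/headache); arbitrary
  block structures (e.g. systemic/local/gastric) can be planted for
  community-detection tests.

Calibration consequences of the defaults: disclosed-female mean count
`E0·(2.5/2.1)·E[d] ≈ 2.51` (matching the emulated channel's published
2.5), male ≈ 2.11, and population marginals about 17% above `base_c`
(the multipliers act on top of reference covariates, so `base_c` is the
prevalence at reference conditions, not the population marginal).

### Rendering and parsing

Messages follow the channel's header convention — gender letter (М/Ж),
"NN лет/года/год" with correct Russian numeral agreement, dose marker V1/V2
with a dd.mm.yy date (both-dose reports render two segments) — followed by
exactly one lexicon phrase per true symptom and 0–2 non-symptom decoys.
The default lexicon is Cyrillic with a transliterated variant; phrases are
unique to their class, which makes rendered corpora linearly separable.
The parser is total (never raises), accepts Cyrillic and Latin variants,
bounds ages to [10, 110] (analyses filter further to ≥ 18), treats
conflicting gender letters as undisclosed, and reports dose *both* iff
both markers match.  Renderer → parser round-trip is exact on all
disclosed fields and is enforced by tests on 1,000 rendered messages.

### What the generator does not emulate

Real messages paraphrase symptoms in open vocabulary, misspell, mix
scripts, and mention negated or historical symptoms; the generator's
closed lexicon has none of this, so classifier scores here are an upper
bound.  There is no moderation/deletion process, no adversarial or
duplicate reporting, no seasonal or batch structure in symptoms, and
timestamps follow a smooth rise-then-decay (gamma-shaped, peak near day
66 of a 130-day window) rather than news-driven bursts.  Passing tests
demonstrate the *protocol* (splitting, up-sampling, thresholding,
metrics) and the *estimators*, not real-world extraction accuracy.

## Classifier protocol

* **Up-sampling** duplicates positives of minority classes (sampling with
  replacement) until each class matches the largest class's positive
  count (configurable cap); duplicates' side-effects on their other
  labels are accounted for during balancing.  Applied to training
  partitions only.
* **Stratified k-fold** uses greedy iterative multilabel stratification
  followed by a swap-repair pass that brings every (fold, class) positive
  count within one example of its size-proportional target.
* The default backend is one-vs-rest logistic regression (C = 10) over
  word 1–2-gram TF-IDF features — the sigmoid/binary-cross-entropy
  decision layer without a neural encoder.  Degenerate classes
  (single-valued in training) emit a constant score and are flagged.
* **Metrics**: micro metrics pool all 12×n decisions; macro metrics
  average per-class values, excluding classes without positives
  (precision/F1) or without both outcomes (AUC), with exclusion counts
  reported.  Pooled micro-AUC is primary; the per-class mean is reported
  alongside.  Ties at the 0.5 threshold count as positive (≥).
* Under a label-permutation null the **macro** AUC sits at 0.5; pooled
  micro-AUC does not, because pooling mixes class base rates and
  prevalent classes keep systematically higher scores.  Chance-level
  checks therefore use the class-wise average.

## Statistics

* All tests are two-sided; p-values are displayed to 3 decimals, floored
  at "<.001"; no multiple-testing correction is applied.
* **Fisher exact** delegates to the standard hypergeometric routine and
  is verified against exhaustive margin-preserving enumeration for all
  small tables.  All-zero tables give p = 1 by convention.
* **Mann–Whitney** uses the exact tie-aware permutation distribution of U
  (full enumeration over group assignments) whenever
  C(n_a+n_b, n_a) ≤ 2·10⁵, and the tie-corrected normal approximation
  with continuity correction otherwise.  Exhaustive enumeration at the
  textbook "n ≤ 20 per group" boundary is combinatorially infeasible
  (C(40,20) ≈ 1.4·10¹¹), hence the enumeration-count cutoff.
* **Prevalence ratio** (count_a/n_a)/(count_b/n_b) is the primary
  two-sample effect measure for frequency tables; the classical
  cross-product odds ratio is computed alongside.  Published comparison
  columns labelled "OR" reproduce exactly as prevalence ratios, not as
  cross-product odds ratios, which is why the ratio column of the
  shipped over-60 comparison is checked under this convention.  A zero
  reference rate yields an infinity flag, not an exception.
* **Age regression** is OLS of per-report AE count on age, restricted to
  ages ≥ 18; the slope is reported as magnitude plus direction flag.
  Fixed-seed Monte-Carlo recovery checks use 3-SE bands in unit tests (a
  2-SE band falsely rejects a correct generator on ~5% of seeds); the
  dedicated calibration check at the prescribed full-disclosure settings
  uses the strict 2-SE band.

## Co-occurrence network

Spearman rank correlation of binary indicators equals the phi
coefficient, so the matrix is computed as the Pearson correlation of the
0/1 columns.  Constant columns yield NaN rows that are flagged, never
silently zeroed.  Edges are kept on strict `r > 0.09`.  Community
detection is weighted Louvain (seedable); hierarchical clustering of the
matrix uses average linkage on distance 1 − r (linkage configurable).
Correlations are computed per message; per-user aggregation is out of
scope.

## Harmonization and profiles

Rules are shipped as declarative text (`category = rule`): lines with
AND/OR/NOT parse as boolean expressions over the canonical classes,
everything else as frequency sums over source-table categories.  Boolean
categories are evaluated per report, and derived-category frequencies are
*not* determined by the 12 marginals (enforced by a counterexample test).
The registry-category denominator is the set of reports with at least one
AE, matching passive registries' sentinel-free intake.  The trial
source-vocabulary fixture is a synthetic split whose sums match the
published aggregated counts (the split itself is not published).  The
published registry comparison table's counts and percentages are mutually
inconsistent; its printed percentages are used for correlation and its
ratio column is treated as approximate.

Vaccine profiles are six-symptom percentage vectors (pain, headache,
fatigue, fever, chills, nausea); profiles with missing entries are
rejected at load.  Distances are Euclidean on the percent scale.  The
platform-group aggregate is reported as both the sum and the mean of
pairwise distances; the sum is the headline convention (the self-report
profile sits at 131.8 ≈ 132 percentage points summed over the three
vector-vaccine profiles, versus 275.6 over the four mRNA profiles —
closer to vector platforms under either aggregate).  The self-report
nausea frequency is taken as 3.00 from the profile table (its frequency
table prints 3.05); the profile value is primary.

## Problem sizes and determinism

Calibration experiments use 10,000-message corpora (Monte-Carlo error:
slope SE ≈ 0.0007, female-mean SE ≈ 0.03); classifier-protocol
experiments use 5,000 messages with 5-fold CV; co-occurrence experiments
use 4,000–20,000 depending on the effect size under test.  Every random
stage draws from a single seeded NumPy generator; identical configuration
(including seed) reproduces corpora, models and pipeline outputs
bit-identically, which the end-to-end manifest test verifies via content
hashes.

## Known limitations

* The linear backend cannot capture negation, coreference or
  morphological variation; it exists to exercise the protocol at desk
  scale, and real deployments should plug a stronger encoder into the
  same backend contract.
* The generator's independence-given-covariates assumption understates
  real symptom correlation; the factor knob is a coarse remedy.
* Parsing rules are a reconstruction of loose community conventions and
  are configuration-exposed rather than canonical.
* Published aggregate values that cannot be reproduced from their own
  printed components (the mRNA group aggregate "241", the registry
  comparison's ratio column) are documented as such and excluded from
  exact checks rather than approximated.
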