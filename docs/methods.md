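# Methods

This note documents the models, scoring rules, numerical conventions and
design choices behind `vigimem`, and what the synthetic-data tests do and do
not establish about real data.

## Task model and scoring

**Vigilance task.**  A digit appears every second; the participant presses a
key for the rare target (digit 0, probability 0.25) and withholds otherwise.
Each one-minute block of 60 trials is scored by the four signal-detection
outcomes and the F1 score `2·TP/(2·TP+FP+FN)`.  F1 ignores correct
rejections, which dominate a 75%-non-target stream and would otherwise mask
sensitivity changes.  A keypress is attributed to the stimulus whose
one-second window it falls in; multiple presses in one window count once —
with a one-second cadence this is the only unambiguous attribution rule.
Blocks with no targets and no false alarms carry no signal and score NaN;
such blocks propagate as missing and the participant drops out of any
aggregate that needs them (listwise), matching how complete-case t-tests
behave downstream.

**Reaction times.**  Only true-positive RTs count.  Within each block, RTs
farther than two *sample* standard deviations (ddof = 1) from the block mean
are excluded in a single pass (the rule is not iterated; iterating would
trim indefinitely on heavy-tailed data).  With fewer than three RTs the
spread estimate is meaningless and trimming is skipped.

**Decrement statistics.**  Baseline = mean F1 over blocks 1–3; final = mean
over blocks 7–9; the vigilance decrement is `100·(final−baseline)/baseline`.
The practice block (index 0) is scored — it is the t = 0 point of trajectory
plots — but never enters baseline or final.  A zero or undefined baseline
flags the participant (`decrement_defined = False`) and excludes them from
normalized-decrement endpoints.  Accuracies are unit fractions internally
and become percent only in reporting, to avoid double-scaling.

**Memory probes.**  The object task is an 8-alternative forced choice over
20 items, probed immediately after encoding and again ~30 min later.
Outcomes are `correct`, `same_object_wrong_orientation` (right object, wrong
orientation — an identity/orientation binding failure) and `other_error`.
Accuracy and the orientation false-alarm rate are simple proportions; the
memory decrement mirrors the vigilance decrement
(`100·(delayed−immediate)/immediate`, NaN when immediate accuracy is 0, and
invariant to whether accuracies arrive as fractions or percent).  Word
recognition (24 probes, half non-targets) is scored
`(hits + correct rejections)/24`; the source studies leave the exact word
scoring rule unstated, so this choice is explicit and configurable via
`n_probes`.  An optional least-squares residualization of the decrement on
the maintenance interval is available (`adjust_maintenance_interval`) as a
robustness check when groups differ in how long memory had to be held.

## Resampling inference

Both procedures resample **participants** (rows), never individual cells:
the participant is the exchangeable unit, and trajectories are redrawn
jointly across timepoints.  Per iteration, N rows are drawn with replacement
from *each* group — N defaulting to the smaller group size — and the
difference of group means is recorded; default 10 000 iterations.

* *Timeseries mask*: a timepoint is flagged when more than 95% of iteration
  differences share a sign.  Taken literally this criterion is a two-sided
  rule of size ≈ 10%, so the scalar group test also reports the conventional
  two-sided bootstrap p-value `2·min(P(d≤0), P(d≥0))`; results label which
  number is the literal sign criterion.  Ties at exactly zero count toward
  neither sign, so the two proportions sum to ≤ 1 without bias.
* Because only N = min(n₁,n₂) rows are drawn from the *larger* group, the
  resampled difference over-disperses relative to the sampling distribution
  of the observed difference when groups are unbalanced; the test is then
  conservative (measured type-I ≈ 2–4% at nominal 5% for 13 vs 73).  This
  is a property of the procedure itself, reproduced faithfully.
* Reproducibility: every call takes an integer seed; identical inputs and
  seed give identical masks and p-values.

## Parametric endpoints

* **t-tests** are pooled-variance Student by default (`df = n₁+n₂−2`);
  every recomputable published statistic in this family of study tables
  matches the pooled form, so Welch sits behind a flag.
  `pooled_t_from_summary` computes the identical statistic from printed
  (mean, sd, n) pairs — it agrees exactly with the raw-data path for any
  samples having those summaries.  Zero pooled variance yields t = 0 for
  equal means and signed infinity (flagged) otherwise.  Table reproduction
  rounds t to one decimal, half away from zero.
* **Bayes factors** are Jeffreys–Zellner–Siow: Cauchy(0, r) prior on the
  standardized effect with r = √2/2, evaluated through the inverse-gamma
  mixture as a one-dimensional integral over g (scipy adaptive quadrature,
  relative tolerance 1e-10; non-convergence raises with diagnostics).
  Effective N is n for one sample and n₁n₂/(n₁+n₂) for two.  Published BF
  values in this literature are directionally ambiguous, so the package
  always reports bf10 *and* bf01 = 1/bf10, never a bare "BF".
* **Chi-square** is Pearson's without continuity correction (the form that
  reproduces published 2×2 values); a zero marginal leaves the statistic
  undefined (NaN) rather than raising.
* **Correlations** are Spearman with average ranks; partial correlations
  rank-transform all variables, residualize x and y on the covariate ranks
  by least squares, and Pearson-correlate the residuals (p via the
  t-approximation with df = n−2−k).  With no covariates the partial form
  reduces exactly to plain Spearman.
* **PCA composites** z-score each measure (ddof = 1), drop zero-variance
  columns with a warning, and take the first eigenvector of the correlation
  matrix; the sign is oriented so the composite correlates positively with
  the row-mean of the z-scored inputs, making "higher = better on average"
  stable across runs.
* **Bonferroni** is `min(1, p·m)` with the battery family size fixed at
  m = 29 by default (the number of tests in the full battery ledger),
  configurable per fit.

## Synthetic cohort generator

The generator emulates the data-generating structure the analysis assumes:
two groups (defaults 53 exposed vs 83 control), a practice block plus nine
60-trial blocks at 25% target probability, per-minute fatigue/motivation
ratings on a 0–100 scale, object-memory probes at both phases and word
probes, plus participant covariates (age, gender, days since diagnosis,
questionnaire scale scores including grit).

* **Hit-probability drift** is linear per block on the probability scale,
  clipped to [0.01, 0.99] — the simplest model consistent with a roughly
  linear group-mean decline.  Baseline hit rates are Gaussian across
  participants (sd 0.20).
* **Recovery**: for the exposed group the drift (and the memory misbinding
  inflation) is scaled by `max(0, 1 − days/τ)` with τ = 270 d for vigilance
  and τ = 180 d for memory — the deficits fade by roughly nine and six
  months respectively.  Days since diagnosis are uniform over a
  configurable range (default 10–400 d).
* **Calibrated defaults.**  The exposed/control baseline hit rates (0.764 /
  0.779) and drifts (−0.053 / −0.0017 per block) were chosen, via the
  closed-form expectation of the drift model
  (`expected_group_decrement`), so that the *cohort-mean* endpoints match
  the study conditions being emulated: baseline accuracies ≈ 75.5% / 78.5%
  and normalized decrements ≈ −12.3% / −0.9%.  Because recovery attenuates
  most exposed participants, the per-block drift of a recently diagnosed
  participant is necessarily steeper than the cohort-average slope.  The
  misbinding inflation default (0.20 of probability mass, exposed group
  only) likewise yields a cohort-mean orientation-false-alarm increase of a
  few points at delay once recovery is averaged in.
* **Misbinding** is modelled purely as mass transfer from `correct` to
  `same_object_wrong_orientation`; the `other_error` mass is fixed across
  phases, localizing the delayed deficit to orientation errors.
* **RTs** are log-normal truncated to (0, 1 s] by inverse-CDF sampling,
  respecting the one-second trial cadence (log-mean −0.80 ≈ 0.45 s).
* **Streams**: each participant owns an RNG stream seeded by
  `(seed, crc32(participant_id))`, so cohorts are extensible without
  perturbing existing participants, and identical config+seed reproduces
  byte-identical tables.
* An optional shared latent factor can couple a participant's vigilance and
  memory decrements; real studies do not characterize this coupling, so its
  scale is a free parameter defaulting to 0 (uncoupled).

**What the generator does not emulate**: stimulus rendering, response-window
jitter and lapses in rating compliance, item-level questionnaire structure,
"look-alike" distractor similarity gradients, practice/learning effects, or
any vaccination/socio-economic covariates.  Passing calibration and
recovery tests on this generator therefore establishes that the *pipeline*
is correct and calibrated under its assumed structure — not that real
cohorts satisfy that structure.

## Problem sizes used in the verification suites

The type-I-error calibration runs 500 replicate cohorts (300 in the
acceptance script) at the default 53/83 group sizes with all generating
parameters equal and recovery disabled, asserting rejection rates within
binomial 99% bounds of nominal for both the bootstrap group test and the
pooled-t battery endpoints.  Parameter recovery uses one cohort of 200
participants per group and requires the scored group-decrement difference
to land within 3 Monte-Carlo standard errors of the configured difference.
Oracle-equivalence suites compare F1, RT trimming, chi-square, PCA loadings
and the JZS Bayes factor against independently coded brute-force
implementations on ≥ 1000 random small instances.

## Known limitations

* The JZS quadrature targets two-sample and one-sample designs; paired
  designs enter through the one-sample path on difference scores.
* The unbalanced bootstrap test's conservatism (above) means its power is
  below that of a permutation test at the same nominal level; it is kept
  because it is the procedure under study.
* `expected_group_decrement` is the infinite-trial limit; finite-trial F1
  noise adds a small Jensen-type bias to the normalized decrement (well
  inside the 3-SE recovery tolerance at the sizes used).
* Degrees of freedom are always conventional (`n−1`, `n₁+n₂−2`); published
  tables in this literature occasionally print internally inconsistent df,
  which the package does not imitate.
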