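# Methods

`peersent` analyzes within-session emotional change in anonymous digital
peer-support (DPS) chat sessions. The unit of analysis is one user's
participation in one session; sessions are never linked across a user's
returns. Each message of the focal user carries intensity scores on a 1–10
scale for up to eight sentiments — loneliness, sadness, stress, anxiety,
depression, despair, helplessness (negative) and optimism (positive) —
produced upstream by an automated rater and treated here as input data.

## Inclusion filtering

A session enters the analysis of a sentiment only if

1. the user sent at least 3 messages (`MIN_USER_MESSAGES = 3`),
2. an *initial state* exists: the maximum of that sentiment's scores over
   the user's first 3 messages (users often open with brief exchanges
   before expressing their struggle, so the maximum is used rather than the
   first score), and
3. the initial state clears the threshold of 5 in the direction that leaves
   room for improvement: strictly above 5 for negative sentiments, strictly
   below 5 for optimism. An initial state of exactly 5 is excluded for both
   polarities.

Both the message minimum and the first-3 window count primary-user messages
only; moderator and peer messages carry no scores and the rule describes the
user's opening emotional state. The threshold is a parameter
(`threshold=5.0`) so that monotonicity — raising it can only shrink the
included set for negative sentiments, and only grow it for optimism — is a
testable property.

## Trajectory binning and the trend fit

Sessions differ in length, so each is mapped to a relative clock: a message
at time offset `u` in a session of duration `D` lands at `t = u/D ∈ [0, 1]`,
binned into 100 bins of width 0.01. `t = 1.0` (the final message) is clamped
into bin 99, keeping 100 half-open bins. Multiple scored messages in one bin
are averaged; unscored messages contribute nothing; empty bins stay missing.

Across sessions, each bin's mean, contributor count `n`, and SEM
(sample SD / √n; defined as 0 when `n = 1`, where the sample SD does not
exist) are computed over the non-missing values. An ordinary least-squares
line is fitted to the per-bin means against the bin centers
`(i + 0.5)/100`, unweighted: the aggregate curve is the estimand, and every
populated bin is one observation of it. A variant weighting bins by `n` is
available behind `weight_by_n=True` but is not the default. Bins with no
contributors are excluded from the fit, which requires at least two
populated bins. Goodness of fit is the ordinary R²; a constant response is
returned as slope 0 with R² = 0 by convention. The p-value is the
two-tailed t-test on the slope.

The session-level change is summarized as the **improvement percentage**

    improvement% = |ŷ(1) − ŷ(0)| / ŷ(0) × 100 = |slope| / intercept × 100,

the fitted relative change over one full session. It requires a positive
fitted intercept (scores live on a positive scale); "improvement" means a
decline for negative sentiments and a rise for optimism, tracked by the
slope's sign.

## Propensity matching

Cohorts (within vs outside business hours, resource received vs not) differ
systematically in engagement covariates, so slope comparisons between them
are run on propensity-matched subsets. Membership is modeled by unpenalized
logistic regression on: primary struggle topic (14 levels), device (3),
country (levels with fewer than `min_country_count = 10` sessions collapsed
to "other"), participant count, conversation duration binned into
{0-5, 5-10, 10-20, 20-45, 45-60, >60} minutes, engagement rate (primary-user
characters per minute of conversation) binned into
{0-10, 10-20, 20-30, 30-40, 40-50, >50}, and the initial sentiment score.
All bins are half-open `[lo, hi)`. One reference level per one-hot block is
dropped before the fit (the full blocks plus an intercept are singular; the
fitted probabilities are invariant to the choice). Constant columns are
dropped with a warning and near-perfect separation is flagged. The solver is
deterministic (lbfgs, tolerance 1e-8, no regularization — expressed as an
infinite inverse-regularization constant).

Matching is greedy 1-nearest-neighbor without replacement within a caliper
of `0.25 ×` the SD of all propensity scores, both cohorts pooled. The
smaller cohort drives the loop in ascending session-id order; each of its
sessions takes the nearest unused score in the other cohort if the gap is
within the caliper, ties broken toward the lower session id. The scheme is
deliberately deterministic so results are exactly reproducible; optimal
(non-greedy) matching and matching with replacement are out of scope.

Balance is diagnosed per feature column with the standardized mean
difference SMD = (mean_A − mean_B) / pooled SD, pooled SD =
√((s²_A + s²_B)/2), defined as 0 when the pooled SD is 0, before and after
matching.

## Cohort comparisons

Scalar metrics are compared with the two-sample **Welch** t-test,
two-tailed. The pooled-variance test is deliberately not used: the cohorts'
variances differ by large factors (typing-speed SDs differ by ~4× in the
reference deployment). A Mann-Whitney alternative sits behind
`method="mannwhitney"`. The effect size is classical Cohen's d on the
pooled SD; when both samples have zero variance the test is degenerate and
p = 1, d = 0 by convention. Percent difference is
(mean_A − mean_B)/mean_B × 100.

Fitted slopes are compared by stacking the two cohorts' per-bin means with a
cohort indicator `g` and fitting `y ~ 1 + t + g + t·g`; the interaction
coefficient estimates slope_A − slope_B exactly (for noiseless inputs on a
common bin domain the equality is exact), and its two-tailed t-test is
reported. When the stacked fit has (near-)zero residual variance the t
statistic is pure round-off; p is then reported as 1 for a zero interaction
and 0 otherwise. A label-shuffling permutation test (session trajectories
reassigned to cohorts, seeded, 1,000 reps by default) is available as an
alternative. The improvement-percent gap is reported in percentage points.

## Descriptive tables

Topic-keyed tables (topic distribution, EAP inflow/outflow, resource type ×
topic) count a session once per topic it carries, so column totals may
exceed the session count. EAP flow percentages are flagged/total × 100 per
topic with a grand-total row. The resources-per-session average divides all
shared resources by all sessions. Demographic percentages are computed over
disclosing sessions only, with the disclosure rate reported separately.
Business hours are Monday–Friday 08:00–17:00 local time, half-open at 17:00,
classified by session start only. Displayed percentages are rounded half-up
to 2 decimals to match table conventions.

## The synthetic generator

`peersent.synthetic` draws corpora with a known truth ledger. Per session:

* **Start time** from a 7×24 weekday × hour mixture whose default is a
  diurnal profile rescaled so ~32.2% of sessions start within business
  hours; the start time fixes the cohort.
* **Engagement covariates per cohort**: duration lognormal (means
  33.63 / 40.03 min within/outside, SDs 32.72 / 36.59), primary-user message
  count negative-binomial (20.36 / 26.35, SDs 25.55 / 30.95; at least 1),
  characters per message lognormal, topic count rounded normal clipped to
  [1, 14] (6.21 / 7.01). The cohort mixture reproduces the corpus-level
  means (≈38 min, ≈24 messages). These cohort differences double as the
  known confounder for matching tests.
* **Topics**: a primary struggle drawn from the deployment's topic shares,
  plus uniformly drawn extras up to the topic count.
* **Resources**: with probability 0.68 the session receives 1 + Poisson(1)
  resources (mean 1.36 per session over the corpus), typed by the observed
  resource-type mix; receipt defines the arm.
* **Scores**: for each sentiment, a per-session latent intercept
  `b ~ N(baseline(cohort), SD)` and the configured true slope for that
  sentiment × cohort × arm give the latent line `b + slope·t`; each
  message observes `round(clip(b + slope·t + ε, 1, 10))` with
  `ε ~ N(0, noise_sd)`, `noise_sd = 1.5` by default — integer scale points,
  matching a rater that emits whole anchors. The first message sits at
  t = 0; remaining message times are uniform over the session and sorted
  (the analysis consumes only normalized time, so no richer inter-arrival
  model is warranted).
* Default baselines are the reference deployment's cohort baseline table;
  default slopes encode its matched-cohort improvement percentages per arm
  (with the published cohort gaps split evenly around each sentiment's arm
  values). EAP flags, device, country, participant count and demographics
  (age from the published 3-year bins, gender and race from the published
  disclosure mix, disclosure probability 34.84%) follow the deployment's
  marginals.

One `numpy` PCG64 stream seeded from `config.seed` drives everything in a
fixed order (documented in the module docstring), so a config reproduces a
byte-identical corpus. `generate_sessions(cfg, with_truth=True)` returns the
per-session latent intercepts, cohort and arm; `ground_truth(cfg)` returns
the slope/intercept/implied-improvement table.

### What the generator does and does not emulate

It reproduces the deployment's marginal structure (cohort split, engagement
distributions, topic/resource/EAP/demographic mixes) and a linear latent
trajectory with i.i.d. Gaussian message noise. It does not model free text,
moderator behavior, serial correlation within a session, rater error
structure, or user identity across sessions. Passing recovery tests
therefore shows the *pipeline* is correct under the linear model, not that
real transcripts follow it.

Two calibration caveats are deliberate. First, the observable initial state
(the max of the first three noisy, rounded scores) is upward-biased relative
to the latent baseline — a corpus generated at latent stress 6.96 shows
initial-state means near 8.3 — so latent-baseline recovery is checked on the
truth ledger, not on the max statistic, and small latent cohort gaps are
attenuated in the observable. Second, inclusion truncation (initial > 5)
selects high-intercept sessions; with the default baseline SDs (~2) the
fitted intercept of an included subset exceeds the configured latent mean by
a few tenths. Recovery scenarios therefore use a moderate baseline SD (0.8),
where the selection bias is negligible against the 3-SE / 3-point recovery
bands.

## Numerical choices and problem sizes

* Score validation accepts [1, 10] reals; the generator emits integers.
* `t = 1.0` clamps to bin 99; within-bin collisions average.
* SEM(n=1) = 0; empty bins excluded from fits; fits need ≥2 populated bins.
* Caliper base is the pooled (both cohorts) score SD, `ddof = 1`.
* Half-up decimal rounding for displayed percentages.
* Recovery and matching studies run at 2,000–5,000 sessions with fixed
  seeds, where fitted slopes sit well within 3 SE of truth, improvement
  percentages within 3 points, i.i.d.-cohort match retention above 90%, and
  the Welch type-I rate inside the 99% binomial band of 0.05 at 2,000
  simulations. These sizes are the package's chosen study scale for its own
  verification runs.

## Known limitations

* The improvement percentage divides by the fitted intercept; it is
  undefined for nonpositive intercepts and unstable when the intercept is
  near zero (not reachable on the 1–10 scale).
* Greedy matching is order-dependent by design; a different (documented)
  order could produce a slightly different pairing of equal quality.
* The interaction OLS treats per-bin means as homoskedastic observations;
  with very unequal per-bin contributor counts the weighted fit or the
  permutation test is the safer alternative.
* No multiple-testing correction is applied across sentiments, matching the
  reporting convention the pipeline reproduces.
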