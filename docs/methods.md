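# Methods

## The estimation problem

In paediatric HIV registries, antiretroviral therapy (HAART) is started
preferentially in children whose CD4 class has fallen below threshold;
low CD4 also marks a worse underlying disease course, and therapy in
turn improves CD4.  CD4 is therefore a *time-dependent confounder
affected by prior exposure*: a regression that ignores it is confounded,
and a regression that conditions on it blocks part of the treatment
effect and opens a collider path between treatment and the unmeasured
disease severity.  The estimator implemented here is the standard
solution — a marginal structural Cox model fitted by stabilized inverse
probability of treatment and censoring (IPTC) weighting of a pooled
logistic regression.

## Person-period expansion

Follow-up is discretized into one-month intervals `[t, t+1)` on the
time-on-study scale.  Each child contributes one row per month from
enrollment to the month containing the TB event or the end of
observation.  Exposure `A_t` is "on HAART for at least 2 months at the
start of the interval" and is absorbing; the raw carried-forward
treatment status (`on_haart`) is kept separately, because the *weight*
models describe the initiation process while the *outcome* model uses
the lagged exposure.  Time-varying covariates (CD4 class, WHO stage,
adherence, cotrimoxazole prophylaxis) are last-observation-carried-
forward, falling back to the baseline value at `t=0` and to an explicit
`missing` level otherwise.  When a final visit records both a TB event
and a terminal status, the event wins (conservative for incidence).
Losses, deaths and transfers out are pooled into one censoring
indicator; a child's administrative end of follow-up at the study
horizon is not modelled as censoring (in the simulated design it occurs
only at the horizon, where no later risk sets exist).

## Weight construction

The monthly initiation hazard `P(start HAART at t | untreated, history)`
is fitted twice by pooled logistic regression: a *numerator* model on
baseline covariates (age, sex, baseline WHO stage, baseline CD4 class)
plus a flexible function of time, and a *denominator* model adding the
time-varying covariates.  The stabilized treatment weight at month `t`
is the cumulative product of numerator/denominator probabilities of the
child's observed actions, with factors equal to 1 after initiation.
Censoring weights are built the same way from models of remaining
uncensored (both models include current exposure; the denominator adds
the time-varying covariates), and each row's weight includes its own
interval's uncensored probability because dropout within a month
precludes observing that month's event.  Terminally censored rows are
excluded from the outcome fit; the weighting re-represents them.

Time enters all models as a restricted natural cubic spline with 4
degrees of freedom (interval dummies are available but 60 dummies are
unstable at a few hundred children).  Weight truncation at chosen
percentiles, e.g. (1, 99), is available behind a flag and off by
default, matching the motivating analysis, which reported none.

Complete separation in a weight model raises an error naming the
covariate; quasi-separation on a rare covariate level (a small group
with no events) is tolerated, because the runaway coefficient appears in
numerator and denominator alike and cancels from the weights.

## Outcome models and the estimation ladder

The outcome model is a pooled logistic regression of the monthly TB
indicator on current exposure and the spline in time, maximizing the
weight-multiplied likelihood; with monthly event probabilities below
1%, its exposure odds ratio approximates the marginal structural Cox
hazard ratio (verified against a Cox fit in the rare-event regime to
within 5%).  Variance is by subject-clustered sandwich with the weights
treated as fixed; a subject-level bootstrap that refits the weights per
replicate is available as a cross-check.  statsmodels warns that
`cov_type` with `var_weights` is "not fully supported"; the clustered
sandwich it produces was verified against a hand computation of the
fixed-weight MSM sandwich (they agree to four decimals), so the warning
is suppressed at the call site.

The five-model ladder mirrors the usual presentation:

1. unweighted, unadjusted (crude);
2. unweighted, adjusted for baseline covariates;
3. weighted by a baseline-covariates-only propensity model, stabilized
   by the marginal (time-only) initiation hazard, outcome unadjusted;
4. stabilized time-varying **treatment** weights, outcome adjusted for
   the baseline covariates (required because they stabilize the
   numerator);
5. total weights = (4) x stabilized censoring weights.

Row 3's construction, and the choice that row 4 carries treatment-only
weights, are declared interpretations of an under-specified published
table.  The reported contrast is current exposure, not cumulative
duration.

## The synthetic data-generating process

Each child carries a latent frailty `U ~ Uniform(0,1)` drawn once.  Per
month: CD4 class evolves as a two-state chain (worsening logit
`-3.4 + 2.5(U-0.5) - 1.5*on_haart`, recovery logit `-3.2 + 1.8*on_haart
- 2.5(U-0.5)`); an untreated child initiates HAART with probability
`logit^-1(-4.6 + 2.2*[CD4 low])`; censoring occurs with probability
`logit^-1(-5.6 + 0.7*[CD4 low] - 0.3*A_t)`; TB occurs with probability
`logit^-1(-4.9 + psi*A_t + 1.2*(U-0.5))` with `psi = log 0.64`.  The
exposure `A_t` switches on two months after initiation, mirroring the
analysis definition.  Baseline age, sex and WHO stage, and the
time-varying WHO stage / adherence / CPT decorations, are correlated
with CD4 but causally inert, so the full covariate lists of the
motivating analysis are exercisable without changing the estimand.

Design rationale: treatment decisions depend only on *measured* CD4, so
sequential exchangeability holds given the recorded history and the
IPTC estimator's identification conditions are exactly satisfied, while
any unweighted regression is biased through `U`.  Because the marginal
hazard ratio under this mechanism has no closed form, the estimand is
defined operationally: the same mechanism is re-run with treatment
forced to *always* (exposed from enrollment) and *never*, censoring
disabled, and the same pooled logistic working model is fitted to the
two intervened populations (`counterfactual_truth`).  The Monte-Carlo SE
comes from disjoint subject splits.  Seed-matched runs share all
uniforms, so intervening on treatment provably changes nothing but
treatment and its descendants.

Defaults were calibrated once to the motivating cohort's regime: 800
children, up to 60 months, overall TB incidence ≈7.5 per 100
child-years (published: 7.9), ≈60% ever initiating therapy, ≈20%
informative dropout, baseline WHO-stage mix and 35% low baseline CD4 as
published.  Age is a band mixture matching the published band sizes.
Under these defaults the crude estimator is biased upward by ≈0.16 on
the log-HR scale while the total-weighted estimator is unbiased to
within 0.01 (200-replicate study against the oracle).

What the generator does **not** emulate: continuous CD4 counts and
age-specific thresholds, regimen composition and interruptions (exposure
is absorbing), competing-risk death, clinic-level clustering, and
calendar-time effects.  Passing tests therefore demonstrate correctness
of the estimator under its identification conditions, not robustness to
violations real registries may harbour.

## Numerical choices

- Byar's cube-root approximation for person-time rate CIs (reproduces
  the published OpenEpi-style limits to 3 decimals); exact mid-P limits
  behind a flag.  The lower limit is 0 at zero events.
- Pearson chi-square without continuity correction by default (counts
  in the motivating tables are large); Yates behind a flag.
- Mann-Whitney uses the exact null distribution for small tie-free
  samples and the tie-corrected normal approximation otherwise.
- Kaplan-Meier, log-rank and Cox (Efron ties) are delegated to
  lifelines; survival times are "intervals survived", so an event in
  interval `t` has time `t+1`.
- Logistic fits use IRLS with up to 100 (weight models) / 200 (outcome
  models) iterations; the spline basis drops one column of patsy's
  `cr()` basis so it is full rank next to an explicit intercept.
- Bootstrap replicates that fail for want of events are dropped and
  counted; more than 20% dropped is an error.

## Known limitations

- At the default cohort size (n=800) the total-weighted fit's 95%
  sandwich CI attains nominal coverage under the null (95.0% measured
  over 200 replicates).  At half that size (n=400) it undercovers
  (≈90% over 500 replicates): the cumulative-product weights are
  heavy-tailed over 60 intervals and the replicate SD exceeds the mean
  sandwich SE by ≈13%, which neither small-sample cluster corrections
  (CR2/Mancl-DeRouen were evaluated), weight truncation at (1,99), nor
  a parsimonious weight model repairs.  For small cohorts the bootstrap
  CI is the recommended alternative.
- The ladder on a *single* cohort of 800 children is noisy (log-HR SE
  ≈0.19); qualitative conclusions about confounding should rest on
  replicate studies, as in the tests.
- Percentile bootstrap, not BCa; subject-level resampling only.
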