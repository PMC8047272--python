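# tbmsm

Marginal structural modelling of the effect of antiretroviral therapy
(HAART) on tuberculosis incidence in paediatric HIV cohorts.

In observational ART registries, a child's CD4 state both drives the
decision to start therapy and predicts tuberculosis — and is itself
improved by therapy already received.  Such *time-dependent confounders
affected by prior exposure* bias every standard regression, whether or
not CD4 is adjusted for.  The estimator implemented here handles them
the canonical way:

1. expand the cohort into **person-month** rows, with exposure defined
   as being on HAART for at least 2 months (absorbing);
2. model the monthly **treatment-initiation** hazard and the
   **censoring** hazard with pooled logistic regressions, and form
   per-child **stabilized inverse-probability-of-treatment-and-censoring
   (IPTC) weights**

   `SW(t) = prod_{k<=t} [ P(A_k | baseline, k) / P(A_k | baseline, L_k, k) ] x [ P(C_k=0 | ...) / P(C_k=0 | ..., L_k) ]`;

3. fit a **weighted pooled logistic model** of the TB event on current
   exposure and a spline in time, whose exponentiated exposure
   coefficient approximates the hazard ratio of a **marginal structural
   Cox model** when events are rare, with subject-clustered sandwich
   standard errors.

The motivating cohort (≈800 HIV-infected children under 15 followed up
to five years in Southwest Ethiopian ART clinics) was never deposited,
so the causal machinery is validated on **synthetic cohorts** from a
generator with a latent-frailty mechanism and a counterfactual oracle:
the same mechanism re-run under *always treat* / *never treat* with
censoring disabled defines the true marginal hazard ratio.  The
descriptive layer (person-time incidence with Byar confidence limits,
Kaplan–Meier/log-rank, chi-square, Mann–Whitney, a Table-1-style cohort
summary) is validated directly against the motivating study's printed
figures.

## Worked example

```python
import numpy as np
from tbmsm import (SimulationConfig, simulate_cohort, build_person_period,
                   counterfactual_truth, model_ladder, ladder_table,
                   incidence_rate)

est = incidence_rate(233, 2942.99)          # published inputs: events, child-years
print(f"{est.rate_per_100cy:.3f} ({est.ci_low:.3f}-{est.ci_high:.3f})")
# 7.917 (6.933-9.002)  per 100 child-years, Byar 95% CI

cfg = SimulationConfig()                    # n=800, 60 months, psi = log 0.64
subjects, visits = simulate_cohort(cfg)
pp = build_person_period(subjects, visits)  # person-month expansion

truth = counterfactual_truth(cfg, n_replicate_subjects=100_000)
print(f"oracle marginal HR {truth.hr_marginal:.3f}")
# oracle marginal HR 0.646   (close to exp(psi)=0.640; frailty makes them differ)

print(ladder_table(model_ladder(pp)).round(3).to_string(index=False))
#                 model    hr  ci_low  ci_high  p_value  n_events
# unweighted_unadjusted 0.570   0.423    0.769    0.000       217
#   unweighted_adjusted 0.576   0.422    0.785    0.000       217
#     baseline_weighted 0.555   0.398    0.774    0.001       217
# time_varying_weighted 0.560   0.386    0.812    0.002       217
#        total_weighted 0.573   0.394    0.833    0.004       217
```

A single cohort is noisy (the hazard-ratio SE at 800 children is ≈0.19
on the log scale); averaged over 200 replicate cohorts the total-weighted
estimator is unbiased for the oracle while the crude one is biased
upward by ≈0.16 on the log scale — the qualitative pattern of the
motivating analysis, where the crude model showed no effect (HR 1.019)
and the fully weighted model showed a protective HR of 0.642.

Short narrative scripts, one per capability, live in `examples/`.

A thin CLI wraps the pipeline for shell use:

```bash
tbmsm simulate --n 800 --months 60 --seed 1 --out-dir cohort/
tbmsm analyze --baseline cohort/baseline.csv --visits cohort/visits.csv --out run/
```

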