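"""Stabilized IPTC weights and the five-model estimation ladder.

Fits the treatment-initiation and censoring models, builds the
stabilized weights, checks their diagnostics, and prints the ladder:
crude, baseline-adjusted, and three increasingly rigorous weighted fits.
"""

from tbmsm import (SimulationConfig, build_person_period, ladder_table,
                   model_ladder, simulate_cohort, weight_diagnostics)
from tbmsm.msm import ladder_weight_sets

cfg = SimulationConfig(seed=20200905)          # n=800, 60 months, psi=log 0.64
subjects, visits = simulate_cohort(cfg)
pp = build_person_period(subjects, visits)

weight_sets = ladder_weight_sets(pp)
diag = weight_diagnostics(weight_sets["total"])
print(f"total stabilized weights: mean {diag['mean']:.3f} (should be ~1), "
      f"sd {diag['sd']:.2f}, max {diag['max']:.1f}")

fits = model_ladder(pp, weight_sets)
print("\nestimation ladder (HR for current >=2-months-on-HAART exposure):")
print(ladder_table(fits).round(3).to_string(index=False))
print("\nOne cohort of 800 children carries ~0.19 log-HR noise; the ladder's"
      "\nordering stabilizes over replicates (see examples/04 and the tests).")
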