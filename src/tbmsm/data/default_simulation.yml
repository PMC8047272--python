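n_subjects: 800
n_intervals: 60
psi: -0.4462871026284195
beta0: -4.9
beta_u: 1.2
alpha0: -4.6
alpha_l: 2.2
gamma0: -3.4
gamma_u: 2.5
gamma_a: 1.5
rho0: -3.2
rho_a: 1.8
kappa0: -5.6
kappa_l: 0.7
kappa_a: -0.3
exposure_lag_months: 2
sex_male_p: 0.54
who_stage_probs:
- 0.5
- 0.35
- 0.13
- 0.02
cd4_low_baseline_p: 0.35
seed: 20200905
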