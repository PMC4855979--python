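# Scenario 6 "Continuous phenotype": standard-normal phenotype with a
# smaller per-unit compositional shift.
name: scenario6_continuous_phenotype
s: 500
mu_k: [-0.05, 0.25]
sigma_k: [0.05, 0.15]
sigma_jk: 0.1
rho: 100
alpha0: [0.57, 0.43]
delta_alpha: [0.03, -0.03]
phenotype: continuous
n_replications: 1
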