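# Scenario 7 "Few associated sites": only 50 DMSs with moderate-to-
# strong positive effects in both cell types; ten replications.
name: scenario7_few_dms
s: 50
mu_k: [1.0, 0.95]
sigma_k: [0.05, 0.05]
sigma_jk: [0.1, 2.0]
rho: 100
alpha0: [0.57, 0.43]
delta_alpha: [0.08, -0.08]
phenotype: binary
n_replications: 10
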