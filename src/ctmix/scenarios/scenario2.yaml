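# Scenario 2 "No confounding": identical DMS effect distributions in
# both cell types, so mixing carries no differential signal.
name: scenario2_no_confounding
s: 500
mu_k: [0.25, 0.25]
sigma_k: [0.5, 0.5]
sigma_jk: 0.1
rho: 100
alpha0: [0.57, 0.43]
delta_alpha: [0.08, -0.08]
phenotype: binary
n_replications: 1
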