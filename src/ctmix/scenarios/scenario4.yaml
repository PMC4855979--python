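# Scenario 4 "High precision": rho = 200, sharply separated mixture
# distributions between cases and controls.
name: scenario4_high_precision
s: 500
mu_k: [0.3, 0.1]
sigma_k: [0.1, 0.1]
sigma_jk: 0.1
rho: 200
alpha0: [0.57, 0.43]
delta_alpha: [0.08, -0.08]
phenotype: binary
n_replications: 1
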