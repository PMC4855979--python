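# Scenario 5 "Low precision": rho = 10, highly variable mixture
# proportions blur the case/control separation.
name: scenario5_low_precision
s: 500
mu_k: [0.3, 0.1]
sigma_k: [0.1, 0.1]
sigma_jk: 0.1
rho: 10
alpha0: [0.57, 0.43]
delta_alpha: [0.08, -0.08]
phenotype: binary
n_replications: 1
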