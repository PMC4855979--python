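# Scenario 1 "Distinct differences": DMS effect distributions differ
# strongly between cell types; binary phenotype; confounded mixing.
name: scenario1_distinct_differences
s: 500
mu_k: [-0.05, 0.5]
sigma_k: [0.05, 0.75]
sigma_jk: [0.1, 2.0]
rho: 100
alpha0: [0.57, 0.43]
delta_alpha: [0.08, -0.08]
phenotype: binary
n_replications: 1
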