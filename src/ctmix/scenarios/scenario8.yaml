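# Scenario 8 "Many associated sites": 10,000 DMSs in two equicorrelated
# blocks of 5,000 (background correlations 0.4 and 0.5); effects are
# correlated within a block, independent across blocks; ten replications.
name: scenario8_many_dms_blocks
s: 10000
mu_k: [0.15, 0.55]   # overall location; per-block values below govern draws
sigma_k: [0.01, 0.01]
sigma_jk: [0.1, 2.0]
rho: 100
alpha0: [0.57, 0.43]
delta_alpha: [0.08, -0.08]
phenotype: binary
n_replications: 10
blocks:
  - size: 5000
    background_correlation: 0.4
    mu_k: [0.1, 0.4]
    sigma_k: [0.01, 0.01]
  - size: 5000
    background_correlation: 0.5
    mu_k: [0.2, 0.7]
    sigma_k: [0.01, 0.01]
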