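# Methods

## Scope and design

`ctmix` simulates cell-type-mixture confounding in Illumina-450K-style
methylation data and evaluates adjustment methods against known truth.
It has five layers: synthetic cell-separated base data, the mixture
simulator, adjustment methods, probe-wise association testing, and
evaluation metrics; `ctmix.pipeline.run_pipeline` composes them.

## Synthetic cell-separated base data

Real evaluations of this kind are built on cell-sorted methylation
profiles; here the base data are generated, which makes the truth
(which probes differ between cell types, how many latent factors
exist) available to tests. `generate_base_profiles` draws, on the
logit scale,

```
logit(beta_ijk) = m_j + d_j * 1[k = 2] + (Lambda_k f_i)_j + eps_ijk
```

* `m_j`: probe means from a three-component Beta mixture — weights
  0.40/0.35/0.25 on Beta(2,18), Beta(18,2), Beta(2,2) — reproducing
  the unmethylated/methylated peaks and intermediate shoulder of 450K
  beta distributions.
* `d_j`: a cell-type-2 shift on a Bernoulli(0.2) subset of probes,
  magnitude Unif(1, 3) on the logit scale with random sign. Roughly a
  fifth of probes strongly differential between monocytes and CD4+ T
  cells is consistent with sorted-blood comparisons.
* `Lambda_k f_i`: ten latent per-subject factors shared across cell
  types with cell-type-specific N(0, 0.05²) loadings, emulating batch
  effects and residual lineage heterogeneity. Random-matrix-theory
  estimates on either cell type's matrix then give a latent dimension
  near ten — matching what dimension estimators report on real
  separated cells — rather than the nominal two cell types.
* `eps_ijk ~ N(0, 0.15²)`: independent inter-individual noise, in the
  range of observed M-value dispersion for sorted cells.

The defaults were fixed in a design-phase calibration so that (a) a
scenario-1-style confounded mixture elevates the unadjusted genomic
inflation factor into the 1.4–2.4 range seen on real data, (b) the
cell-composition axis and the latent factors have comparable strength,
as in real mixed tissue, and (c) latent structure is detectable at the
desk scale of 20,000 probes. Betas are clipped to
[1e-6, 1 − 1e-6] so downstream logit transforms stay finite.

The probe-level population (means, differential mask, shifts) depends
only on the seed; individual-level draws additionally mix in a cohort
label. `generate_base_profiles(cfg, cohort="reference")` therefore
yields a held-out panel with the same probe universe and population
means but new subjects — the correct analogue of an external
cell-sorted reference data set.

What the generator does **not** model: Infinium type-I/type-II probe
chemistry, normalization artifacts, SNP-affected or sex-chromosome
probes, more than two cell types, or mean-variance coupling beyond
what the logit transform induces. Passing tests therefore demonstrate
behavior under idealized mixture confounding, not robustness to array
technical artifacts.

## Mixture simulation

The simulator follows the five-step scheme described in the README:
random DMS selection; Bernoulli(0.5) or standard-normal phenotype;
hierarchical DMS effects (probe-level means `mu_jk ~ N(mu_k,
sigma_k^2)`, individual effects `e_ijk ~ N(mu_jk, sigma_jk^2)`)
injected on the logit scale scaled by the phenotype; Dirichlet mixing
with `p_i ~ Dirichlet(rho * (alpha0 + z_i * delta_alpha))`. Design
choices where the scheme is underdetermined:

* `sigma_jk` ranges (e.g. Unif(0.1, 2)) are realized once per
  (probe, cell type) per replication, fixed across individuals.
* In the blocked scenario the per-cell-type effect means within a
  block are equicorrelated (shared-factor construction) at the block's
  background correlation; blocks, and the two cell types, are mutually
  independent.
* For continuous phenotypes `alpha0 + z * delta_alpha` can leave the
  simplex at extreme z; components are floored at 1e-6 and
  renormalized. With the shipped parameters this needs |z| > 14, so it
  has no practical effect on the scenarios.
* The binary phenotype is drawn per replication, not balanced by
  design.
* Every stage draws from an independently spawned child seed; the
  truth record stores all of them, so any replication is exactly
  reproducible from the manifest.

## Adjustment methods

All methods emit per-sample covariates that enter the probe-wise
linear model. Input scale: reference-based and reference-free operate
on beta values, SVA and RUV on logit(beta) (M-values); both are
configurable.

**Reference-based.** Markers are the 100 probes with the largest
absolute between-cell-type difference in the held-out reference
panel. Each sample's marker vector is regressed on the two reference
profiles under p ≥ 0, Σp = 1, solved by non-negative least squares
with a heavily weighted appended constraint row (exact on noiseless
mixtures). With two cell types summing to one, only p̂₁ enters the
design. The sum constraint can be relaxed to Σp ≤ 1 for real-data use
with incomplete references.

**Reference-free.** Probe-wise OLS on [intercept, phenotype] gives
coefficient matrix B and residual matrix E; the top K left-singular
vectors of [B | E] are probe-space loadings of latent structure, and
the covariates are projections of the row-centered data onto them. K
comes from random matrix theory. Standard errors for this method's
association scan come from resampling subjects (100 bootstrap
replicates) with normal reference p-values.

**SVA.** The surrogate count K̂ is chosen by a permutation test: each
probe's values are permuted independently, the permuted matrix is
re-residualized against the design, and eigenvalue variance fractions
are compared (100 permutations, monotone p-values, level 0.05).
Permuting the residual matrix itself would compare a rank-deficient
spectrum against full-rank ones and overcount — re-residualization is
essential. Surrogates are the top right-singular vectors of the
weighted row-centered data matrix, iterated five times with probe
weights

```
w_j = (1 - p_sv,j) * min(1, p_pheno|sv,j / 1e-3)
```

where `p_sv` tests the surrogate block and `p_pheno|sv` tests the
phenotype given the current surrogates. Two structural points, both
found the hard way on this package's own simulations:

1. *Surrogates must come from the data matrix, not the
   phenotype-residualized matrix.* Residual-derived directions are
   orthogonal to the phenotype by construction; adjusting for them
   removes variance but cannot remove the phenotype-aligned component
   of a confounder, which makes inflation worse, not better.
2. *The phenotype weight needs an empirical-null character and the
   iteration must start from the residual directions.* A
   theoretical-null weight (1 − p, or the p-value rank) down-weights
   the entire confounded probe stratum — exactly the probes that carry
   the confounder — while a soft floor at p ≈ 10⁻³ only excises probes
   clearly beyond the bulk, playing the role of the local-FDR
   posterior probabilities in the original formulation. Starting the
   iteration from the raw data SVD instead of the residual SVD has a
   degenerate fixed point in which one surrogate collapses onto the
   phenotype itself (the true-signal axis), destroying power when
   there is no confounding to remove.

**RUV-4.** Negative-control probes are cell-type-differential probes
that are not DMSs and not correlated with the phenotype beyond |r| =
0.5 in the mixed data; the 500 with the largest cell-type contrast
are used. The control submatrix is residualized against the design
*without* the phenotype column — controls are assumed phenotype-null,
so phenotype-aligned variation they exhibit is unwanted and must be
retained — and its top K = 3 right-singular vectors are the factors.
K = 3 is the fixed convention used throughout the evaluation; the
permissive 0.5 correlation screen reflects that under confounding,
control probes legitimately correlate with the phenotype through
composition.

**Latent dimension (RMT).** Probes are standardized; eigenvalues of
the n×n correlation matrix (1/J)XᵀX are counted above the
Marchenko–Pastur upper edge (1 + √(n/J))². The edge is a fluctuating
(Tracy–Widom) quantity, so on iid noise the estimate is 0 in ~95% of
seeds rather than always.

**External tools.** ISVA, EWASher and similar programs are not
reimplemented; `ExternalAdjustment` adapts any command reading a
values TSV on stdin and writing a samples × K covariate TSV on
stdout. Failures are isolated per method: the pipeline emits a
warning and an all-NaN metrics row.

## Association testing and moderation

Each probe is fit by OLS on [1, z, covariates]; the phenotype
coefficient is tested with a moderated t statistic. The prior
(d₀, s₀²) is fit by the method of moments on log residual variances
(digamma/trigamma matching, Newton inversion of the trigamma), the
posterior variance is s̃² = (d₀s₀² + d·s²)/(d₀ + d), and p-values use
t on d₀ + d degrees of freedom (normal when d₀ = ∞). If all variances
are identical the code falls back to unmoderated statistics with a
warning. Significance is declared at p < 10⁻⁴, strict inequality.
Tests default to the beta scale (the simulator's output scale); an
M-value option exists. Two-sided p-values throughout.

## Metrics

NFP and power count non-DMS and DMS probes below 10⁻⁴. The KS
statistic is the plain sup-distance from Uniform(0,1), reported as a
calibration measure, not a test. The GIF is the least-squares-through-
the-origin slope of sorted observed −log₁₀ p against expected
quantiles −log₁₀((i − 0.5)/m), computed after removing the true DMSs;
KS uses the same exclusion set so the two calibration measures are
comparable (a flag includes all probes). A median-χ²/0.456 lambda is
available as a cross-check. Zero p-values are clipped at 1e-300 with a
warning.

## Numerical and testing notes

* Desk scale is 20,000 probes × 46 subjects (analysis scripts) and
  4,000–5,000 probes in the test suite; the full-array scale of
  375,639 probes is supported but not exercised routinely.
* Probes in a simulated data set are *dependent*: they share the
  mixture-proportion draws and latent factors. Single-run GIF and KS
  values therefore fluctuate far more than iid theory suggests
  (null-scenario GIF ranges ~0.7–1.3 at n = 46), which is why
  directional and calibration checks use medians over five seeds, and
  why the p-value-uniformity check uses a base configuration without
  shared structure.
* Power in the distinct-differences scenario is low in absolute terms
  for all methods: many simulated effects are small against the
  individual-effect noise (σ_jk up to 2 on the logit scale), and
  adjustment covariates absorb part of the phenotype-aligned DMS
  variation. Rankings, not absolute power, are the informative output.
* Seeds: a master seed fans out to named per-stage seeds via
  SeedSequence with a CRC-32 of the stage name, so method order never
  affects results and all derived seeds stay below 2³¹.

## Known limitations

The reference panel is drawn from the same statistical population as
the study cohort, so reference-based deconvolution faces no
reference-mismatch bias — real references are often from different
labs and protocols. The SVA weighting uses a fixed soft threshold
rather than a fitted local-FDR model. Only two cell types are mixed.
The bootstrap for the reference-free method resamples subjects
identically across probes, preserving cross-probe dependence but
ignoring uncertainty in the latent loadings themselves.
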