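"""Cell-type adjustment methods.

Each method consumes the mixed methylation matrix (probes x samples)
plus the study design and emits an ``AdjustmentResult`` whose
``covariates`` (samples x K) enter the downstream probe-wise linear
model:

* reference-based — constrained least squares of each sample on mean
  cell-type reference profiles at marker probes, yielding estimated
  mixture proportions;
* reference-free — probe-space loadings from the SVD of the
  concatenated coefficient and residual matrices of an unadjusted
  probe-wise fit, dimension from random matrix theory, standard errors
  downstream by bootstrap;
* SVA — surrogate variables from the iteratively re-weighted data
  matrix, with a residual-permutation test for their number;
* RUV-4 — factor analysis (SVD) of negative-control probes (phenotype
  deliberately not regressed out), with K conventionally fixed at 3.

A shared subtlety: covariates meant to absorb a *confounded*
composition axis must retain its phenotype-aligned component, so the
decompositions here operate on (weighted/centered) data rather than on
phenotype-residualized matrices.

Latent dimension estimation compares standardized correlation-matrix
eigenvalues to the Marchenko-Pastur bulk edge.

External adjustment tools (ISVA, EWASher, and similar) are not
reimplemented; ``ExternalAdjustment`` adapts any command that reads a
values TSV on stdin and writes a samples x K covariate TSV on stdout.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logit

from ctmix.base_data import BETA_FLOOR, CellProfilePair
from ctmix.errors import ConfigurationError


@dataclass
class ReferenceProfileSet:
    """Mean beta per cell type from a held-out cell-separated data set."""

    probe_ids: np.ndarray
    mean_beta: np.ndarray  # (n_probes, 2)

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids)
        self.mean_beta = np.asarray(self.mean_beta, dtype=float)
        if self.mean_beta.ndim != 2 or self.mean_beta.shape[1] != 2:
            raise ValueError("mean_beta must be (n_probes, 2)")
        if len(self.probe_ids) != self.mean_beta.shape[0]:
            raise ValueError("probe_ids length does not match mean_beta")
        if (self.mean_beta <= 0).any() or (self.mean_beta >= 1).any():
            raise ValueError("reference means must lie strictly in (0, 1)")


@dataclass
class AdjustmentResult:
    """Covariates produced by one adjustment method."""

    method: str
    covariates: np.ndarray  # (n, K_hat)
    k_hat: int
    proportions: np.ndarray | None = None  # (n, 2), reference-based only
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim != 2:
            raise ValueError("covariates must be 2-D (samples x K)")
        k = self.covariates.shape[1]
        if k and np.linalg.matrix_rank(self.covariates) < k:
            raise ValueError("covariates must have full column rank")
        if self.proportions is not None:
            p = np.asarray(self.proportions, dtype=float)
            if (p < -1e-8).any() or (p.sum(axis=1) > 1.0 + 1e-8).any():
                raise ValueError("proportions rows must be in [0, 1], sum <= 1")


def reference_from_pair(pair: CellProfilePair) -> ReferenceProfileSet:
    """Build reference profiles as per-probe means over individuals."""
    means = np.stack(
        [pair.beta[0].mean(axis=1), pair.beta[1].mean(axis=1)], axis=1
    )
    means = np.clip(means, BETA_FLOOR, 1.0 - BETA_FLOOR)
    return ReferenceProfileSet(pair.probe_ids, means)


def estimate_proportions_refbased(
    mixed_beta: np.ndarray,
    reference: ReferenceProfileSet,
    marker_count: int = 100,
    sum_to_one: bool = True,
) -> np.ndarray:
    """Estimate per-sample cell-type proportions by constrained least squares.

    Markers are the ``marker_count`` probes with the largest absolute
    between-cell-type reference difference.  Each sample's marker
    values are regressed on the two reference profiles under p_k >= 0
    and (by default) sum p_k = 1, via non-negative least squares with a
    heavily weighted sum constraint row.

    Returns an (n_samples, 2) proportion matrix.
    """
    mixed_beta = np.asarray(mixed_beta, dtype=float)
    if mixed_beta.shape[0] != reference.mean_beta.shape[0]:
        raise ValueError(
            "mixed matrix and reference must share an aligned probe axis"
        )
    if marker_count < 2 or marker_count > mixed_beta.shape[0]:
        raise ConfigurationError(
            f"marker_count must be in [2, n_probes], got {marker_count}"
        )
    diff = np.abs(reference.mean_beta[:, 0] - reference.mean_beta[:, 1])
    markers = np.argsort(diff)[::-1][:marker_count]
    R = reference.mean_beta[markers]  # (m, 2)
    if np.linalg.matrix_rank(R) < 2:
        raise ValueError(
            "singular marker design: reference profiles are collinear at markers"
        )
    Y = mixed_beta[markers]  # (m, n)
    n = Y.shape[1]
    props = np.empty((n, 2))
    if sum_to_one:
        w = 100.0 * np.abs(R).max()
        A = np.vstack([R, w * np.ones((1, 2))])
        for i in range(n):
            y = np.concatenate([Y[:, i], [w]])
            sol, _ = optimize.nnls(A, y)
            total = sol.sum()
            props[i] = sol / total if total > 0 else np.array([0.5, 0.5])
    else:
        for i in range(n):
            sol, _ = optimize.nnls(R, Y[:, i])
            props[i] = np.minimum(sol, 1.0)
    return props


def refbased_adjustment(
    mixed_beta, reference, marker_count: int = 100
) -> AdjustmentResult:
    """Reference-based adjustment: estimated proportions as covariates.

    With two cell types summing to one, only the first proportion
    enters the design (the second is collinear with the intercept).
    """
    props = estimate_proportions_refbased(mixed_beta, reference, marker_count)
    return AdjustmentResult(
        method="ref_based",
        covariates=props[:, :1],
        k_hat=1,
        proportions=props,
        diagnostics={"marker_count": marker_count},
    )


def _residuals_and_coefs(values: np.ndarray, design: np.ndarray):
    """OLS of each probe on the shared design: coefs (J, d), residuals (J, n)."""
    coef, *_ = np.linalg.lstsq(design, values.T, rcond=None)
    resid = values - (design @ coef).T
    return coef.T, resid


def reffree_components(
    values: np.ndarray, design: np.ndarray, k: int | None = None
) -> AdjustmentResult:
    """Reference-free decomposition of an unadjusted probe-wise fit.

    Fits each probe on ``design`` (intercept + phenotype [+ covariates])
    and takes the SVD of the concatenated coefficient and residual
    matrices [B | E] (J x (d + n)).  The top ``K`` left-singular
    vectors are probe-space loadings of the latent cell-type structure;
    per-sample covariate scores are the projections of the row-centered
    data onto those loadings.  Projecting the data — rather than the
    phenotype-residualized matrix — keeps the phenotype-aligned
    component of the latent structure, without which a confounded
    composition axis could never be adjusted away.  The retained
    dimension comes from random matrix theory unless ``k`` is given.
    """
    values = np.asarray(values, dtype=float)
    design = np.asarray(design, dtype=float)
    n, d = design.shape
    k_hat = estimate_latent_dim_rmt(values) if k is None else int(k)
    if k_hat >= n - np.linalg.matrix_rank(design):
        raise ConfigurationError(
            f"latent dimension {k_hat} >= residual degrees of freedom"
        )
    coefs, resid = _residuals_and_coefs(values, design)
    m = np.hstack([coefs, resid])
    u, _, _ = np.linalg.svd(m, full_matrices=False)
    loadings = u[:, :k_hat]  # (J, k_hat) probe-space directions
    centered = values - values.mean(axis=1, keepdims=True)
    covariates = centered.T @ loadings  # (n, k_hat)
    return AdjustmentResult(
        method="ref_free",
        covariates=covariates,
        k_hat=k_hat,
        diagnostics={"design_columns": d, "loadings": loadings},
    )


def _eigenvalue_fractions(resid: np.ndarray) -> np.ndarray:
    s = np.linalg.svd(resid, compute_uv=False)
    s2 = s**2
    return s2 / s2.sum()


def _num_sv_permutation(
    values: np.ndarray,
    design: np.ndarray,
    n_permutations: int,
    alpha: float,
    rng,
) -> int:
    """Permutation (parallel-analysis) estimate of the surrogate count.

    Each probe's values are permuted independently across samples,
    destroying inter-probe structure, and the permuted matrix is
    re-residualized against the design before its eigenvalues are
    computed (permuting the residuals themselves would compare
    rank-deficient to full-rank spectra and overcount).  An eigenvalue
    is kept while its variance fraction exceeds the permutation
    distribution at level ``alpha``, with monotonically enforced
    p-values.
    """
    _, resid = _residuals_and_coefs(values, design)
    obs = _eigenvalue_fractions(resid)
    exceed = np.zeros_like(obs)
    for _ in range(n_permutations):
        perm = rng.permuted(values, axis=1)
        _, perm_resid = _residuals_and_coefs(perm, design)
        exceed += _eigenvalue_fractions(perm_resid) >= obs
    pvals = (exceed + 1.0) / (n_permutations + 1.0)
    pvals = np.maximum.accumulate(pvals)
    return int(np.sum(pvals <= alpha))


def _f_pvalues(values, design_full, design_reduced):
    """Per-probe F-test p-values comparing nested OLS designs."""
    n = design_full.shape[0]
    d_full = np.linalg.matrix_rank(design_full)
    d_red = np.linalg.matrix_rank(design_reduced)
    _, r_full = _residuals_and_coefs(values, design_full)
    _, r_red = _residuals_and_coefs(values, design_reduced)
    rss_full = (r_full**2).sum(axis=1)
    rss_red = (r_red**2).sum(axis=1)
    df1 = d_full - d_red
    df2 = n - d_full
    if df1 <= 0 or df2 <= 0:
        raise ConfigurationError("nested designs leave no degrees of freedom")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_red - rss_full) / df1) / (rss_full / df2)
    f = np.where(rss_full <= 0, np.inf, f)
    return stats.f.sf(f, df1, df2)


def sva_surrogates(
    values: np.ndarray,
    design: np.ndarray,
    k: int | None = None,
    n_permutations: int = 100,
    alpha: float = 0.05,
    n_iter: int = 5,
    assoc_p_floor: float = 1e-3,
    seed=None,
) -> AdjustmentResult:
    """Surrogate variable analysis with iteratively re-weighted refinement.

    The number of surrogate variables is chosen by a row-permutation
    test on the eigenvalue variance fractions of the residual matrix
    (unless ``k`` is given).  Surrogates themselves are the top
    right-singular directions of the weighted, row-centered *data*
    matrix — not the phenotype-residualized matrix, whose directions
    are orthogonal to the phenotype by construction and therefore
    cannot carry the phenotype-aligned component of a confounder.

    Probe weights w_j = (1 - p_sv) * min(1, p_pheno|sv / floor) favor
    probes driven by the latent structure whose phenotype association,
    conditional on the current surrogates, is *not clearly beyond the
    bulk*.  The soft floor plays the role of the local-FDR posterior
    probabilities in the original algorithm: an entire confounded
    stratum of probes shows modest phenotype association and must keep
    its weight (it carries the confounder, including the
    phenotype-aligned component), while strongly associated probes —
    the likely true signals — are excised.  Iteration starts from the
    residual-matrix directions so that true signals are suppressed
    before any phenotype-aligned direction can enter; starting from
    the raw data SVD has a degenerate fixed point in which a surrogate
    collapses onto the phenotype itself and destroys power.

    ``design`` must contain an intercept and the phenotype as its first
    two columns (further columns are treated as modeled covariates).
    """
    values = np.asarray(values, dtype=float)
    design = np.asarray(design, dtype=float)
    n, d = design.shape
    if np.linalg.matrix_rank(design) < d:
        raise ConfigurationError("degenerate (rank-deficient) design")
    rng = np.random.default_rng(seed)
    k_hat = (
        _num_sv_permutation(values, design, n_permutations, alpha, rng)
        if k is None
        else int(k)
    )
    k_hat = min(k_hat, n - d - 1)
    if k_hat <= 0:
        return AdjustmentResult(
            method="sva", covariates=np.empty((n, 0)), k_hat=0,
            diagnostics={"n_permutations": n_permutations},
        )
    centered = values - values.mean(axis=1, keepdims=True)
    _, resid = _residuals_and_coefs(values, design)
    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    svs = vt[:k_hat].T  # (n, k_hat)
    for _ in range(n_iter):
        full = np.hstack([design, svs])
        p_sv = _f_pvalues(values, full, design)
        p_pheno = _f_pvalues(values, full, np.delete(full, 1, axis=1))
        weights = (1.0 - p_sv) * np.minimum(1.0, p_pheno / assoc_p_floor)
        _, _, vt = np.linalg.svd(
            weights[:, None] * centered, full_matrices=False
        )
        svs = vt[:k_hat].T
    return AdjustmentResult(
        method="sva",
        covariates=svs,
        k_hat=k_hat,
        diagnostics={"n_permutations": n_permutations, "n_iter": n_iter},
    )


def select_control_probes(
    base: CellProfilePair,
    mixed_values: np.ndarray,
    phenotype: np.ndarray,
    dms_indices=None,
    m: int = 500,
    corr_threshold: float = 0.5,
) -> np.ndarray:
    """Choose negative-control probes for RUV.

    Eligible probes are cell-type-differential in the separated base
    data, not in the known/putative DMS set, and not correlated with
    the phenotype beyond ``corr_threshold`` in the mixed data.  The
    ``m`` eligible probes with the largest between-cell-type logit-mean
    difference are returned.
    """
    mask = base.differential_probe_mask.copy()
    if dms_indices is not None:
        mask[np.asarray(dms_indices, dtype=int)] = False
    z = np.asarray(phenotype, dtype=float)
    zc = z - z.mean()
    denom_z = np.sqrt((zc**2).sum())
    if denom_z == 0:
        raise ConfigurationError("phenotype is constant; cannot screen controls")
    vals = np.asarray(mixed_values, dtype=float)
    vc = vals - vals.mean(axis=1, keepdims=True)
    denom_v = np.sqrt((vc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (vc @ zc) / (denom_v * denom_z)
    corr = np.nan_to_num(corr)
    mask &= np.abs(corr) < corr_threshold
    eligible = np.flatnonzero(mask)
    if len(eligible) < m:
        raise ConfigurationError(
            f"only {len(eligible)} eligible control probes, need {m}"
        )
    diff = np.abs(
        logit(base.beta[0].mean(axis=1)) - logit(base.beta[1].mean(axis=1))
    )
    order = eligible[np.argsort(diff[eligible])[::-1]]
    return np.sort(order[:m])


def ruv4_factors(
    values: np.ndarray,
    design: np.ndarray,
    controls: np.ndarray,
    k: int = 3,
    phenotype_col: int | None = 1,
) -> AdjustmentResult:
    """RUV-4-style factors from negative-control probes.

    The control-probe submatrix is residualized against the modeled
    design *excluding the phenotype column* — controls are assumed
    phenotype-null, so any phenotype-aligned variation they show is
    unwanted (e.g. cell composition) and must be retained by the
    factors — then decomposed by SVD; the top ``k`` right-singular
    directions are the unwanted-variation factors.  K defaults to the
    fixed value 3 used throughout the evaluation.
    """
    values = np.asarray(values, dtype=float)
    design = np.asarray(design, dtype=float)
    controls = np.asarray(controls, dtype=int)
    if k < 0:
        raise ConfigurationError("K must be >= 0")
    if k > len(controls):
        raise ConfigurationError(
            f"K={k} exceeds the number of control probes ({len(controls)})"
        )
    n = values.shape[1]
    if k == 0:
        return AdjustmentResult(
            method="ruv4", covariates=np.empty((n, 0)), k_hat=0
        )
    if phenotype_col is not None and design.shape[1] > 1:
        design = np.delete(design, phenotype_col, axis=1)
    _, resid_c = _residuals_and_coefs(values[controls], design)
    _, _, vt = np.linalg.svd(resid_c, full_matrices=False)
    return AdjustmentResult(
        method="ruv4",
        covariates=vt[:k].T,
        k_hat=k,
        diagnostics={"n_controls": len(controls)},
    )


def estimate_latent_dim_rmt(values: np.ndarray) -> int:
    """Latent dimension via the Marchenko-Pastur bulk edge.

    Rows (probes) are standardized; eigenvalues of the sample
    correlation matrix (1/J) X^T X are counted above the MP upper edge
    (1 + sqrt(n/J))^2 for aspect ratio n/J.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("values must be a 2-D matrix (probes x samples)")
    J, n = x.shape
    if n < 3:
        raise ConfigurationError(f"need at least 3 samples, got {n}")
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    x = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    J = x.shape[0]
    if J == 0:
        return 0
    s = np.linalg.svd(x, compute_uv=False)
    eigs = s**2 / J
    edge = (1.0 + np.sqrt(n / J)) ** 2
    return int(np.sum(eigs > edge))


class ExternalAdjustment:
    """Adapter for external adjustment tools via a stdin/stdout contract.

    The command receives the values matrix as TSV (probes x samples,
    header row of sample IDs) on stdin and must print a samples x K
    covariate TSV (no header) on stdout.  Failures raise
    ``RuntimeError``; the pipeline isolates them per method.
    """

    def __init__(self, name: str, command: list[str]):
        self.name = name
        self.command = list(command)

    def __call__(self, values: np.ndarray, design: np.ndarray) -> AdjustmentResult:
        payload = pd.DataFrame(np.asarray(values, dtype=float)).to_csv(
            sep="\t", index=False
        )
        proc = subprocess.run(
            self.command, input=payload, capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise RuntimeError(
                f"external adjustment {self.name!r} failed: {proc.stderr.strip()}"
            )
        from io import StringIO

        covs = pd.read_csv(StringIO(proc.stdout), sep="\t", header=None).to_numpy(
            dtype=float
        )
        if covs.shape[0] != np.asarray(values).shape[1]:
            raise RuntimeError(
                f"external adjustment {self.name!r} returned {covs.shape[0]} "
                f"rows for {np.asarray(values).shape[1]} samples"
            )
        return AdjustmentResult(
            method=self.name, covariates=covs, k_hat=covs.shape[1]
        )
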