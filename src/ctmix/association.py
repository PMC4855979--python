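"""Probe-wise association testing with empirical-Bayes moderation.

Every probe is fit by OLS on a shared design (intercept, phenotype,
adjustment covariates); phenotype coefficients are tested with
moderated t statistics in which per-probe residual variances are shrunk
toward a common prior fitted by the method of moments on the log
variances, the classic microarray moderation scheme.  Significance is
declared at a fixed raw p-value threshold of 1e-4 (strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from ctmix.errors import ConfigurationError

SIGNIFICANCE_THRESHOLD = 1e-4


@dataclass
class LinearFit:
    """Per-probe OLS summaries for the phenotype coefficient."""

    coef: np.ndarray
    se: np.ndarray
    sigma2: np.ndarray
    df: float
    unscaled_var: float  # (X'X)^-1 diagonal entry for the phenotype column


@dataclass
class ModerationParams:
    """Prior for variance shrinkage: d0 prior df (may be inf), s0^2 scale."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("prior degrees of freedom d0 must be >= 0")
        if self.s0_sq <= 0:
            raise ValueError("prior variance s0_sq must be > 0")


@dataclass
class AssociationResult:
    """Phenotype association statistics for every probe."""

    probe_ids: np.ndarray
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    df: float
    p: np.ndarray
    method: str = "unadjusted"
    k_hat: int | None = None
    moderation: ModerationParams | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.probe_ids,
                "coef": self.coef,
                "se": self.se,
                "t": self.t,
                "df": np.full(len(self.coef), self.df),
                "p": self.p,
            }
        )


def _design_matrix(phenotype, covariates) -> np.ndarray:
    z = np.asarray(phenotype, dtype=float)
    cols = [np.ones_like(z), z]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != len(z):
            raise ValueError("covariates and phenotype disagree on sample count")
        cols.extend(cov.T)
    return np.column_stack(cols)


def probewise_lm(values, phenotype, covariates=None) -> LinearFit:
    """OLS of every probe on [1, phenotype, covariates].

    Returns the phenotype coefficient, its standard error, the residual
    variance, and the residual degrees of freedom, shared across
    probes.  Raises on rank-deficient designs, naming the collinear
    columns.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    X = _design_matrix(phenotype, covariates)
    n, d = X.shape
    if n <= d:
        raise ConfigurationError(
            f"need more samples ({n}) than design columns ({d})"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < d:
        # identify offending columns via the QR diagonal
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = np.flatnonzero(diag < 1e-10 * diag.max())
        names = ["intercept", "phenotype"] + [
            f"covariate_{i}" for i in range(d - 2)
        ]
        raise ConfigurationError(
            "rank-deficient design; collinear columns: "
            + ", ".join(names[i] for i in bad)
        )
    xtx_inv = np.linalg.inv(X.T @ X)
    coefs = values @ X @ xtx_inv.T  # (J, d)
    resid = values - coefs @ X.T
    df = n - d
    sigma2 = (resid**2).sum(axis=1) / df
    unscaled = xtx_inv[1, 1]
    se = np.sqrt(sigma2 * unscaled)
    return LinearFit(
        coef=coefs[:, 1], se=se, sigma2=sigma2, df=float(df),
        unscaled_var=float(unscaled),
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        step = tri * (1.0 - tri / y) / polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def fit_moderation_params(sigma2, df) -> ModerationParams:
    """Method-of-moments fit of the scaled inverse-chi-square prior.

    Matches the mean and variance of log sample variances against the
    log-F distribution implied by the hierarchical model; an excess
    variance of zero or less yields an infinite-prior (complete
    pooling) fit.
    """
    s2 = np.asarray(sigma2, dtype=float)
    positive = s2 > 0
    if positive.sum() < 2:
        raise ConfigurationError("need at least two positive variances")
    z = np.log(s2[positive])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    evar = e.var(ddof=1) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(e.mean())
    return ModerationParams(d0=float(d0), s0_sq=float(s0_sq))


def posterior_variance(sigma2, df, params: ModerationParams):
    """Shrunk variance s~^2 = (d0 s0^2 + df s^2) / (d0 + df)."""
    s2 = np.asarray(sigma2, dtype=float)
    if np.isinf(params.d0):
        return np.full_like(s2, params.s0_sq)
    if params.d0 == 0:
        return s2
    return (params.d0 * params.s0_sq + df * s2) / (params.d0 + df)


def ebayes_moderate(
    fit: LinearFit,
    probe_ids=None,
    params: ModerationParams | None = None,
    method: str = "unadjusted",
    k_hat: int | None = None,
) -> AssociationResult:
    """Moderated t statistics and two-sided p values for a probe-wise fit.

    The prior (d0, s0^2) is estimated from the fit unless supplied.
    If all residual variances are identical there is nothing to shrink;
    the ordinary t statistics are returned with a warning.
    """
    if probe_ids is None:
        probe_ids = np.arange(len(fit.coef))
    if params is None:
        if np.ptp(fit.sigma2) < 1e-14 * max(fit.sigma2.max(), 1e-300):
            warnings.warn(
                "all residual variances identical; returning unmoderated "
                "statistics",
                stacklevel=2,
            )
            params = ModerationParams(d0=0.0, s0_sq=max(fit.sigma2[0], 1e-300))
        else:
            params = fit_moderation_params(fit.sigma2, fit.df)
    s2_tilde = posterior_variance(fit.sigma2, fit.df, params)
    se_tilde = np.sqrt(s2_tilde * fit.unscaled_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_tilde > 0, fit.coef / se_tilde, 0.0)
    df_total = fit.df + params.d0
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return AssociationResult(
        probe_ids=np.asarray(probe_ids),
        coef=fit.coef,
        se=se_tilde,
        t=t,
        df=float(df_total),
        p=p,
        method=method,
        k_hat=k_hat,
        moderation=params,
    )


def bootstrap_association(
    values,
    phenotype,
    covariates=None,
    n_boot: int = 100,
    seed=None,
    probe_ids=None,
    method: str = "ref_free",
    k_hat: int | None = None,
) -> AssociationResult:
    """Phenotype tests with bootstrap standard errors.

    Individuals are resampled with replacement ``n_boot`` times; the
    SE of each probe's phenotype coefficient is the SD of its bootstrap
    replicates, and p values come from the normal reference
    distribution.  Used for the reference-free method, whose original
    formulation obtains standard errors this way.
    """
    values = np.asarray(values, dtype=float)
    point = probewise_lm(values, phenotype, covariates)
    X = _design_matrix(phenotype, covariates)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, values.shape[0]))
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            Xb = X[idx]
            if np.linalg.matrix_rank(Xb) == X.shape[1]:
                break
        coef, *_ = np.linalg.lstsq(Xb, values[:, idx].T, rcond=None)
        boots[b] = coef[1]
    se = boots.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, point.coef / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(t))
    if probe_ids is None:
        probe_ids = np.arange(values.shape[0])
    return AssociationResult(
        probe_ids=np.asarray(probe_ids),
        coef=point.coef,
        se=se,
        t=t,
        df=np.inf,
        p=p,
        method=method,
        k_hat=k_hat,
    )


def declare_significant(p, threshold: float = SIGNIFICANCE_THRESHOLD):
    """Boolean mask of probes with p strictly below the threshold."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any()):
        raise ValueError("p values must lie in [0, 1]")
    return p < threshold
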