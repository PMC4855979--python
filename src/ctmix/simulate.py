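"""Multi-layer mixture simulation.

Starting from cell-type-separated beta profiles, the simulation

1. randomly selects S differentially methylated sites (DMSs),
2. draws a binary or continuous phenotype z_i per subject,
3. leaves non-DMS probes at their observed cell-type-specific values,
4. for DMS probes adds a phenotype-scaled random effect on the logit
   scale: cell-type means mu_jk ~ N(mu_k, sigma_k^2) (optionally with
   equicorrelated blocks), individual effects e_ijk ~ N(mu_jk,
   sigma_jk^2), and beta'_ijk = invlogit(logit(beta_ijk) + z_i e_ijk),
5. mixes the two cell types per subject with Dirichlet proportions
   p_i ~ Dirichlet(rho * alpha^(z_i)) where alpha^(z) = alpha^(0) +
   z * delta_alpha, so composition is confounded with phenotype.

Eight named scenario presets (shipped as YAML under
``ctmix/scenarios``) parameterize this pipeline; see
:func:`ctmix.pipeline.load_scenario`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

from ctmix.base_data import BETA_FLOOR, CellProfilePair
from ctmix.errors import ConfigurationError

#: Floor applied to Dirichlet parameter components: alpha^(z) can leave
#: the simplex for extreme continuous z, but Dirichlet parameters must
#: stay positive.
ALPHA_FLOOR = 1e-6


@dataclass(frozen=True)
class BlockSpec:
    """One block of correlated DMS effect means.

    ``size`` probes share an equicorrelated covariance (correlation
    ``background_correlation``) on each cell type's effect means, with
    block-specific (mu_k, sigma_k).
    """

    size: int
    background_correlation: float
    mu_k: tuple
    sigma_k: tuple

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ConfigurationError("block size must be positive")
        if not 0.0 <= self.background_correlation < 1.0:
            raise ConfigurationError(
                "background_correlation must lie in [0, 1), got "
                f"{self.background_correlation}"
            )
        if len(self.mu_k) != 2 or len(self.sigma_k) != 2:
            raise ConfigurationError("block mu_k and sigma_k must have length 2")
        if any(s < 0 for s in self.sigma_k):
            raise ConfigurationError("block sigma_k must be >= 0")


@dataclass(frozen=True)
class ScenarioConfig:
    """All parameters of one simulation scenario.

    ``sigma_jk`` is either a scalar or a ``(low, high)`` range; a range
    is realized once per (probe, cell type) per replication from
    Unif(low, high).  ``delta_alpha`` is the average change in mixture
    proportion per unit increase in phenotype.
    """

    name: str
    s: int
    mu_k: tuple
    sigma_k: tuple
    sigma_jk: object  # scalar or (low, high)
    rho: float
    alpha0: tuple = (0.57, 0.43)
    delta_alpha: tuple = (0.08, -0.08)
    phenotype: str = "binary"
    blocks: tuple = ()
    n_replications: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ConfigurationError("S (DMS count) must be >= 0")
        if len(self.mu_k) != 2 or len(self.sigma_k) != 2:
            raise ConfigurationError("mu_k and sigma_k must have length 2")
        if any(s < 0 for s in self.sigma_k):
            raise ConfigurationError("sigma_k entries must be >= 0")
        lo, hi = self.sigma_jk_range
        if lo < 0 or hi < lo:
            raise ConfigurationError(
                f"sigma_jk must be a nonnegative scalar or (low, high) range, "
                f"got {self.sigma_jk!r}"
            )
        if self.rho <= 0:
            raise ConfigurationError(f"rho (precision) must be > 0, got {self.rho}")
        if len(self.alpha0) != 2 or any(a <= 0 for a in self.alpha0):
            raise ConfigurationError("alpha0 components must be positive")
        if not np.isclose(sum(self.alpha0), 1.0):
            raise ConfigurationError(
                f"alpha0 must sum to 1, got {sum(self.alpha0)}"
            )
        if len(self.delta_alpha) != 2 or not np.isclose(sum(self.delta_alpha), 0.0):
            raise ConfigurationError("delta_alpha must have length 2 and sum to 0")
        if self.phenotype not in ("binary", "continuous"):
            raise ConfigurationError(
                f"phenotype must be 'binary' or 'continuous', got {self.phenotype!r}"
            )
        if self.blocks:
            total = sum(b.size for b in self.blocks)
            if total != self.s:
                raise ConfigurationError(
                    f"block sizes must sum to S={self.s}, got {total}"
                )
        if self.n_replications < 1:
            raise ConfigurationError("n_replications must be >= 1")

    @property
    def sigma_jk_range(self) -> tuple:
        """Normalize sigma_jk to a (low, high) pair (scalar -> (x, x))."""
        if np.isscalar(self.sigma_jk):
            return (float(self.sigma_jk), float(self.sigma_jk))
        lo, hi = self.sigma_jk
        return (float(lo), float(hi))


@dataclass
class TruthRecord:
    """Complete ground truth of one simulated replication."""

    dms_indices: np.ndarray  # (S,) probe indices
    z: np.ndarray  # (n,) phenotype
    mu_jk: np.ndarray  # (S, 2) effect means
    e_ijk: np.ndarray  # (2, S, n) individual effects
    p_ik: np.ndarray  # (n, 2) mixture proportions
    sigma_jk: np.ndarray  # (S, 2) realized individual-effect SDs
    scenario: ScenarioConfig
    seeds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dms_indices = np.asarray(self.dms_indices, dtype=int)
        if len(np.unique(self.dms_indices)) != len(self.dms_indices):
            raise ValueError("dms_indices must be unique")
        p = np.asarray(self.p_ik, dtype=float)
        if not np.allclose(p.sum(axis=1), 1.0):
            raise ValueError("each row of p_ik must sum to 1")
        if (p < 0).any() or (p > 1).any():
            raise ValueError("p_ik entries must lie in [0, 1]")


@dataclass
class SimulationResult:
    """Mixed beta matrix plus the truth that generated it."""

    mixed_beta: np.ndarray  # (n_probes, n)
    truth: TruthRecord
    base: CellProfilePair


def select_dms(n_probes: int, s: int, seed=None) -> np.ndarray:
    """Uniformly sample S distinct probe indices to carry true effects."""
    if s < 0 or s > n_probes:
        raise ConfigurationError(
            f"S must satisfy 0 <= S <= n_probes, got S={s}, n_probes={n_probes}"
        )
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n_probes, size=s, replace=False))


def generate_phenotype(n: int, kind: str, seed=None) -> np.ndarray:
    """Draw the phenotype: Bernoulli(0.5) in {0,1} or standard normal."""
    if n < 2:
        raise ConfigurationError(f"need n >= 2 subjects, got {n}")
    rng = np.random.default_rng(seed)
    if kind == "binary":
        return rng.binomial(1, 0.5, size=n).astype(float)
    if kind == "continuous":
        return rng.standard_normal(n)
    raise ConfigurationError(f"unknown phenotype kind {kind!r}")


def _equicorrelated_normal(rng, mean, sd, correlation, size):
    """Draw `size` jointly normal values with common mean/sd and
    pairwise correlation `correlation` (shared-factor construction)."""
    shared = rng.standard_normal()
    own = rng.standard_normal(size)
    return mean + sd * (
        np.sqrt(correlation) * shared + np.sqrt(1.0 - correlation) * own
    )


def sample_effect_means(scenario: ScenarioConfig, seed=None) -> np.ndarray:
    """Draw per-DMS, per-cell-type effect means mu_jk (S x 2).

    Independent case: mu_jk ~ N(mu_k, sigma_k^2) over probes.  Blocked
    case: within each block each cell type's means are equicorrelated
    at the block's background correlation; blocks are independent of
    one another, and the two cell types are independent.
    """
    rng = np.random.default_rng(seed)
    mu = np.empty((scenario.s, 2))
    if not scenario.blocks:
        for k in range(2):
            mu[:, k] = rng.normal(
                scenario.mu_k[k], scenario.sigma_k[k], size=scenario.s
            )
        return mu
    start = 0
    for block in scenario.blocks:
        stop = start + block.size
        for k in range(2):
            mu[start:stop, k] = _equicorrelated_normal(
                rng,
                block.mu_k[k],
                block.sigma_k[k],
                block.background_correlation,
                block.size,
            )
        start = stop
    return mu


def realize_sigma_jk(scenario: ScenarioConfig, seed=None) -> np.ndarray:
    """Realize the per-(probe, cell type) individual-effect SDs (S x 2).

    A scalar sigma_jk broadcasts; a (low, high) range is drawn once per
    probe-cell-type pair per replication.
    """
    lo, hi = scenario.sigma_jk_range
    if lo == hi:
        return np.full((scenario.s, 2), lo)
    rng = np.random.default_rng(seed)
    return rng.uniform(lo, hi, size=(scenario.s, 2))


def sample_individual_effects(mu_jk, sigma_jk, n: int, seed=None) -> np.ndarray:
    """Draw e_ijk ~ N(mu_jk, sigma_jk^2), shape (2, S, n)."""
    mu_jk = np.atleast_2d(np.asarray(mu_jk, dtype=float))
    sigma = np.broadcast_to(
        np.asarray(sigma_jk, dtype=float), mu_jk.shape
    )
    if (sigma < 0).any():
        raise ConfigurationError("sigma_jk must be >= 0")
    rng = np.random.default_rng(seed)
    # mu_jk is (S, 2); produce (2, S, n)
    e = rng.normal(
        mu_jk.T[:, :, None], sigma.T[:, :, None], size=(2, mu_jk.shape[0], n)
    )
    return e


def apply_dms_effect(beta, z, e):
    """beta' = invlogit(logit(beta) + z * e), elementwise.

    ``z`` broadcasts along the trailing (subject) axis.  Works on
    scalars and on (2, S, n) stacks alike.  Output is clipped into the
    open interval used throughout the package.
    """
    beta = np.asarray(beta, dtype=float)
    if (beta <= 0).any() or (beta >= 1).any():
        raise ValueError("beta values must lie strictly in (0, 1)")
    shifted = logit(beta) + np.asarray(z, dtype=float) * np.asarray(e, dtype=float)
    return np.clip(expit(shifted), BETA_FLOOR, 1.0 - BETA_FLOOR)


def sample_mixture_proportions(z, alpha0, delta_alpha, rho: float, seed=None):
    """Draw per-subject mixture proportions p_i ~ Dirichlet(rho * alpha^(z)).

    alpha^(z) = alpha0 + z * delta_alpha componentwise; components are
    floored at a small positive value and renormalized if any becomes
    non-positive (possible for extreme continuous z).  Returns (n, 2)
    for vector ``z`` or (2,) for scalar ``z``.
    """
    if rho <= 0:
        raise ConfigurationError(f"rho must be > 0, got {rho}")
    z_arr = np.atleast_1d(np.asarray(z, dtype=float))
    alpha0 = np.asarray(alpha0, dtype=float)
    delta = np.asarray(delta_alpha, dtype=float)
    alpha_z = alpha0[None, :] + z_arr[:, None] * delta[None, :]
    bad = (alpha_z <= ALPHA_FLOOR).any(axis=1)
    if bad.any():
        clipped = np.clip(alpha_z[bad], ALPHA_FLOOR, None)
        alpha_z[bad] = clipped / clipped.sum(axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    gamma = rng.gamma(shape=rho * alpha_z)
    p = gamma / gamma.sum(axis=1, keepdims=True)
    if np.isscalar(z) or np.ndim(z) == 0:
        return p[0]
    return p


def mix_profiles(beta_prime, p):
    """Mix the two cell-type profiles: beta_f_ij = sum_k p_ik beta'_ijk.

    ``beta_prime`` is (2, J, n); ``p`` is (n, 2).  Returns (J, n), each
    entry a convex combination of the two cell-type values.
    """
    beta_prime = np.asarray(beta_prime, dtype=float)
    p = np.asarray(p, dtype=float)
    if beta_prime.shape[0] != 2 or p.shape != (beta_prime.shape[2], 2):
        raise ValueError(
            f"shape mismatch: beta_prime {beta_prime.shape}, p {p.shape}"
        )
    return p[:, 0] * beta_prime[0] + p[:, 1] * beta_prime[1]


def run_scenario(
    base: CellProfilePair, scenario: ScenarioConfig, seed=None
) -> SimulationResult:
    """Run one full replication of the simulation pipeline.

    Stages (DMS selection, phenotype, effect means, sigma realization,
    individual effects, mixture proportions) draw from independently
    spawned child seeds of ``seed`` (default: ``scenario.seed``) and
    are recorded in ``truth.seeds``.
    """
    if base.n_probes < scenario.s:
        raise ConfigurationError(
            f"base data has {base.n_probes} probes < S={scenario.s}"
        )
    if seed is None:
        seed = scenario.seed
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    stages = ("dms", "phenotype", "effect_means", "sigma_jk", "effects",
              "proportions")
    children = dict(zip(stages, root.spawn(len(stages))))
    seeds = {k: int(v.generate_state(1)[0]) for k, v in children.items()}

    n = base.n_individuals
    dms = select_dms(base.n_probes, scenario.s, children["dms"])
    z = generate_phenotype(n, scenario.phenotype, children["phenotype"])
    mu_jk = sample_effect_means(scenario, children["effect_means"])
    sigma_jk = realize_sigma_jk(scenario, children["sigma_jk"])
    e_ijk = sample_individual_effects(mu_jk, sigma_jk, n, children["effects"])

    beta_prime = base.beta.copy()
    if scenario.s:
        beta_prime[:, dms, :] = apply_dms_effect(base.beta[:, dms, :], z, e_ijk)

    p_ik = sample_mixture_proportions(
        z, scenario.alpha0, scenario.delta_alpha, scenario.rho,
        children["proportions"],
    )
    mixed = mix_profiles(beta_prime, p_ik)

    truth = TruthRecord(
        dms_indices=dms, z=z, mu_jk=mu_jk, e_ijk=e_ijk, p_ik=p_ik,
        sigma_jk=sigma_jk, scenario=scenario, seeds=seeds,
    )
    return SimulationResult(mixed_beta=mixed, truth=truth, base=base)


def run_replications(base: CellProfilePair, scenario: ScenarioConfig, seed=None):
    """Yield ``scenario.n_replications`` independent simulation runs.

    DMSs, phenotype, effects, sigma_jk realizations, and proportions
    are all re-drawn in each replication from spawned child seeds.
    """
    root = np.random.SeedSequence(scenario.seed if seed is None else seed)
    for child in root.spawn(scenario.n_replications):
        yield run_scenario(base, scenario, seed=child)
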