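"""Synthetic cell-type-separated methylation profiles.

Generates beta-value matrices for two sorted immune cell populations
(monocytes as cell type 1, CD4+ T cells as cell type 2) with the gross
statistical features of real 450K array data: a bimodal distribution of
probe mean methylation, a subset of probes strongly differential between
the two cell types, inter-individual variation on the logit (M-value)
scale, and optional latent factors (batch-like structure and residual
lineage heterogeneity) shared across cell types with cell-type-specific
loadings.

All randomness flows through a single :class:`numpy.random.Generator`
seeded from the config, so a config is a complete recipe for its output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ctmix.errors import ConfigurationError, FormatError

# Betas are clipped to this open interval so logit transforms stay finite.
BETA_FLOOR = 1e-6

#: Three-component mixture over probe mean beta values: (weight, a, b)
#: Beta-distribution triples.  Two sharp components near 0.08 and 0.92
#: reproduce the unmethylated/methylated peaks of 450K data; a broad
#: middle component covers intermediate CpGs.
DEFAULT_PROBE_MEAN_MIXTURE = (
    (0.40, 2.0, 18.0),
    (0.35, 18.0, 2.0),
    (0.25, 2.0, 2.0),
)


@dataclass(frozen=True)
class BaseProfileConfig:
    """Recipe for a pair of cell-type-separated beta matrices.

    Parameters
    ----------
    n_individuals:
        Number of subjects with profiles in both cell types (the study
        this emulates had 46).
    n_probes:
        Probe universe size.  The full array after filtering has 375,639
        probes; the default is a desk-scale 20,000.
    frac_celltype_differential:
        Expected fraction of probes whose cell-type-2 mean is shifted on
        the logit scale relative to cell type 1.
    min_differential_shift:
        Minimum magnitude (logit scale) of that shift; realized shifts
        are uniform on [min, min + 2] with random sign.
    probe_mean_mixture:
        ``(weight, a, b)`` triples of a Beta mixture for probe means.
    individual_sd_logit:
        SD of independent per-(probe, subject, cell type) logit noise.
    n_latent_factors, latent_factor_sd:
        Number of latent per-subject factors shared across cell types,
        and the SD of their per-probe, per-cell-type loadings.
    """

    n_individuals: int = 46
    n_probes: int = 20_000
    frac_celltype_differential: float = 0.2
    min_differential_shift: float = 1.0
    probe_mean_mixture: tuple = DEFAULT_PROBE_MEAN_MIXTURE
    individual_sd_logit: float = 0.15
    n_latent_factors: int = 10
    latent_factor_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_probes <= 0:
            raise ConfigurationError(
                "n_individuals and n_probes must be positive, got "
                f"{self.n_individuals} and {self.n_probes}"
            )
        if not 0.0 <= self.frac_celltype_differential <= 1.0:
            raise ConfigurationError(
                "frac_celltype_differential must lie in [0, 1], got "
                f"{self.frac_celltype_differential}"
            )
        if self.min_differential_shift < 0:
            raise ConfigurationError("min_differential_shift must be >= 0")
        if self.individual_sd_logit < 0:
            raise ConfigurationError("individual_sd_logit must be >= 0")
        if self.n_latent_factors < 0:
            raise ConfigurationError("n_latent_factors must be >= 0")
        if self.latent_factor_sd < 0:
            raise ConfigurationError("latent_factor_sd must be >= 0")
        weights = [w for w, _, _ in self.probe_mean_mixture]
        if not np.isclose(sum(weights), 1.0):
            raise ConfigurationError("probe_mean_mixture weights must sum to 1")
        if any(a <= 0 or b <= 0 for _, a, b in self.probe_mean_mixture):
            raise ConfigurationError("probe_mean_mixture shape parameters must be > 0")


@dataclass
class CellProfilePair:
    """True cell-type-specific beta values for two sorted cell types.

    ``beta`` is a ``(2, n_probes, n_individuals)`` array;
    ``beta[k - 1]`` holds cell type ``k``.  ``differential_probe_mask``
    flags probes whose population logit means differ between the two
    cell types.
    """

    probe_ids: np.ndarray
    sample_ids: np.ndarray
    beta: np.ndarray
    differential_probe_mask: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids)
        self.sample_ids = np.asarray(self.sample_ids)
        self.beta = np.asarray(self.beta, dtype=float)
        self.differential_probe_mask = np.asarray(
            self.differential_probe_mask, dtype=bool
        )
        if self.beta.ndim != 3 or self.beta.shape[0] != 2:
            raise ValueError(
                f"beta must have shape (2, n_probes, n), got {self.beta.shape}"
            )
        if self.beta.shape[1] != len(self.probe_ids):
            raise ValueError("probe_ids length does not match beta")
        if self.beta.shape[2] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match beta")
        if len(self.differential_probe_mask) != len(self.probe_ids):
            raise ValueError("differential_probe_mask length does not match probes")
        if not ((self.beta > 0.0) & (self.beta < 1.0)).all():
            raise ValueError("all beta values must lie strictly in (0, 1)")

    @property
    def n_probes(self) -> int:
        return self.beta.shape[1]

    @property
    def n_individuals(self) -> int:
        return self.beta.shape[2]

    def celltype(self, k: int) -> np.ndarray:
        """Beta matrix (probes x samples) for cell type ``k`` in {1, 2}."""
        if k not in (1, 2):
            raise ValueError("cell type must be 1 or 2")
        return self.beta[k - 1]


def _clip_logit_to_beta(logits: np.ndarray) -> np.ndarray:
    """Inverse-logit with clipping into [BETA_FLOOR, 1 - BETA_FLOOR]."""
    return np.clip(expit(logits), BETA_FLOOR, 1.0 - BETA_FLOOR)


def generate_base_profiles(
    config: BaseProfileConfig, cohort: str = "study"
) -> CellProfilePair:
    """Draw a synthetic pair of cell-type-separated beta matrices.

    Probe means come from the configured bimodal Beta mixture; a random
    subset of probes receives a cell-type-2 logit-mean shift of at least
    ``min_differential_shift``; individual values add shared latent
    factor structure and independent logit-scale noise.

    The probe-level population (means, differential mask, shifts) is a
    function of ``config.seed`` alone; individual-level draws also mix
    in ``cohort``, so two cohorts (e.g. a study cohort and a held-out
    reference panel) share the same probe universe and population means
    while containing different subjects.  Deterministic given
    ``config.seed`` and ``cohort``.
    """
    pop_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(b"population")])
    )
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(cohort.encode())])
    )
    J, n = config.n_probes, config.n_individuals

    weights = np.array([w for w, _, _ in config.probe_mean_mixture])
    comps = pop_rng.choice(len(weights), size=J, p=weights / weights.sum())
    mean_beta = np.empty(J)
    for c, (_, a, b) in enumerate(config.probe_mean_mixture):
        idx = comps == c
        mean_beta[idx] = pop_rng.beta(a, b, size=idx.sum())
    mean_beta = np.clip(mean_beta, BETA_FLOOR, 1.0 - BETA_FLOOR)
    mu1 = logit(mean_beta)

    mask = pop_rng.random(J) < config.frac_celltype_differential
    shift = np.zeros(J)
    n_diff = int(mask.sum())
    if n_diff:
        magnitude = pop_rng.uniform(
            config.min_differential_shift, config.min_differential_shift + 2.0,
            size=n_diff,
        )
        sign = pop_rng.choice([-1.0, 1.0], size=n_diff)
        shift[mask] = sign * magnitude
    mu2 = mu1 + shift

    if config.n_latent_factors > 0:
        factors = rng.standard_normal((config.n_latent_factors, n))
        loadings = rng.normal(
            0.0, config.latent_factor_sd, size=(2, J, config.n_latent_factors)
        )
        latent = loadings @ factors  # (2, J, n)
    else:
        latent = np.zeros((2, J, n))

    noise = rng.normal(0.0, config.individual_sd_logit, size=(2, J, n))
    logits = np.stack([mu1, mu2])[:, :, None] + latent + noise
    beta = _clip_logit_to_beta(logits)

    probe_ids = np.array([f"cg{j:08d}" for j in range(J)])
    sample_ids = np.array([f"S{i:03d}" for i in range(n)])
    return CellProfilePair(probe_ids, sample_ids, beta, mask)


def write_beta_matrix(matrix, path, probe_ids=None, sample_ids=None, sep="\t") -> None:
    """Write a probes-x-samples beta matrix as delimited text.

    Accepts a DataFrame (probe IDs in the index) or an array plus
    explicit ``probe_ids``/``sample_ids``.  Values are written at full
    float precision so a read round-trips exactly.
    """
    if isinstance(matrix, pd.DataFrame):
        frame = matrix
    else:
        matrix = np.asarray(matrix, dtype=float)
        if probe_ids is None:
            probe_ids = [f"cg{j:08d}" for j in range(matrix.shape[0])]
        if sample_ids is None:
            sample_ids = [f"S{i:03d}" for i in range(matrix.shape[1])]
        frame = pd.DataFrame(matrix, index=probe_ids, columns=sample_ids)
    frame.index.name = "probe_id"
    frame.to_csv(path, sep=sep)


def read_beta_matrix(path, sep="\t") -> pd.DataFrame:
    """Read a probes-x-samples beta matrix from delimited text.

    The first column holds probe IDs; remaining columns are samples.
    Rejects ragged rows, non-numeric cells, duplicate probe IDs, and
    values outside [0, 1].
    """
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse beta matrix {path}: {exc}") from exc
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate probe IDs in {path}: {dupes[:5]}")
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in beta matrix {path}: {exc}") from exc
    if np.isnan(values).any():
        raise FormatError(f"missing or non-numeric cells in beta matrix {path}")
    if (values < 0.0).any() or (values > 1.0).any():
        bad = values[(values < 0.0) | (values > 1.0)]
        raise FormatError(
            f"beta values outside [0, 1] in {path} (e.g. {bad.flat[0]!r})"
        )
    return frame.astype(float)
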