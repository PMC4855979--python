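"""Performance metrics for the method comparison.

Four quantities score each adjustment method against the simulation
truth at the fixed raw threshold 1e-4:

* NFP — number of non-DMS probes declared significant;
* power — fraction of true DMS probes declared significant;
* KS — Kolmogorov-Smirnov distance between the p-value distribution
  and Uniform(0,1), reported as a calibration statistic only;
* GIF — genomic inflation factor, the least-squares-through-the-origin
  slope of observed versus expected -log10 p quantiles after removing
  the true DMSs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ctmix.association import SIGNIFICANCE_THRESHOLD

P_FLOOR = 1e-300


@dataclass
class MetricsRow:
    """One method's scorecard for one simulated replication."""

    method: str
    nfp: int
    power: float
    ks: float
    gif: float
    k_hat: int | None = None


def count_false_positives(
    p, dms_indices, threshold: float = SIGNIFICANCE_THRESHOLD
) -> int:
    """Number of non-DMS probes with p below the threshold."""
    p = np.asarray(p, dtype=float)
    mask = np.ones(len(p), dtype=bool)
    dms = np.asarray(dms_indices, dtype=int)
    if dms.size and (dms.min() < 0 or dms.max() >= len(p)):
        raise ValueError("dms_indices out of range")
    mask[dms] = False
    return int(np.sum(p[mask] < threshold))


def compute_power(
    p, dms_indices, threshold: float = SIGNIFICANCE_THRESHOLD
) -> float:
    """Fraction of true DMS probes with p below the threshold."""
    dms = np.asarray(dms_indices, dtype=int)
    if dms.size == 0:
        warnings.warn("power is undefined with an empty DMS set", stacklevel=2)
        return float("nan")
    p = np.asarray(p, dtype=float)
    return float(np.mean(p[dms] < threshold))


def ks_uniform(p) -> float:
    """Two-sided KS distance sup |F_hat(x) - x| versus Uniform(0,1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("cannot compute a KS distance on an empty vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    return float(stats.kstest(p, "uniform").statistic)


def genomic_inflation(p, exclude_indices=None, method: str = "qq_slope") -> float:
    """Genomic inflation factor of a p-value vector.

    ``qq_slope`` (default): drop excluded probes, sort -log10 p, and
    regress observed on expected quantiles -log10((i - 0.5) / m) by
    least squares through the origin; the slope is the GIF.  ``median``
    gives the classic median-chi-square lambda for cross-checking.
    """
    p = np.asarray(p, dtype=float)
    if exclude_indices is not None:
        mask = np.ones(len(p), dtype=bool)
        mask[np.asarray(exclude_indices, dtype=int)] = False
        p = p[mask]
    if len(p) < 100:
        raise ValueError(
            f"need at least 100 p values after exclusion, got {len(p)}"
        )
    if (p <= 0).any():
        warnings.warn(
            "zero p values clipped at 1e-300 before log transform",
            stacklevel=2,
        )
        p = np.clip(p, P_FLOOR, None)
    if method == "median":
        chi2 = stats.chi2.isf(p, df=1)
        return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
    if method != "qq_slope":
        raise ValueError(f"unknown GIF method {method!r}")
    m = len(p)
    observed = -np.log10(np.sort(p))  # descending
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)  # descending
    return float((expected @ observed) / (expected @ expected))


@dataclass
class QQTable:
    """Sorted expected and observed -log10 p quantiles for QQ plotting."""

    expected_neglog10: np.ndarray
    observed_neglog10: np.ndarray
    excluded: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "expected_neglog10": self.expected_neglog10,
                "observed_neglog10": self.observed_neglog10,
            }
        )


def export_qq(p, exclude_indices=None) -> QQTable:
    """QQ coordinates (ascending) for the non-excluded p values."""
    p = np.asarray(p, dtype=float)
    excluded = (
        np.asarray(exclude_indices, dtype=int)
        if exclude_indices is not None
        else np.empty(0, dtype=int)
    )
    if excluded.size:
        mask = np.ones(len(p), dtype=bool)
        mask[excluded] = False
        p = p[mask]
    p = np.clip(p, P_FLOOR, None)
    m = len(p)
    observed = np.sort(-np.log10(p))
    expected = np.sort(-np.log10((np.arange(1, m + 1) - 0.5) / m))
    return QQTable(
        expected_neglog10=expected, observed_neglog10=observed, excluded=excluded
    )


def build_metrics_table(
    results: dict,
    dms_indices,
    threshold: float = SIGNIFICANCE_THRESHOLD,
    exclude_dms_from_ks: bool = True,
) -> pd.DataFrame:
    """Score every method's association result against the truth.

    ``results`` maps method name -> AssociationResult (or anything with
    ``p`` and optionally ``k_hat``).  KS and GIF are computed on the
    same exclusion set (non-DMS probes by default).  Returns a frame
    with columns Method / NFP / Power / KS / GIF / K_hat, one row per
    method.
    """
    probe_count = None
    rows = []
    for name, res in results.items():
        p = np.asarray(res.p, dtype=float)
        if probe_count is None:
            probe_count = len(p)
        elif len(p) != probe_count:
            raise ValueError(
                f"method {name!r} tested {len(p)} probes, others {probe_count}"
            )
        ks_p = p
        if exclude_dms_from_ks:
            mask = np.ones(len(p), dtype=bool)
            mask[np.asarray(dms_indices, dtype=int)] = False
            ks_p = p[mask]
        rows.append(
            MetricsRow(
                method=name,
                nfp=count_false_positives(p, dms_indices, threshold),
                power=compute_power(p, dms_indices, threshold),
                ks=ks_uniform(ks_p),
                gif=genomic_inflation(p, exclude_indices=dms_indices),
                k_hat=getattr(res, "k_hat", None),
            )
        )
    return pd.DataFrame(
        {
            "Method": [r.method for r in rows],
            "NFP": [r.nfp for r in rows],
            "Power": [r.power for r in rows],
            "KS": [r.ks for r in rows],
            "GIF": [r.gif for r in rows],
            "K_hat": [r.k_hat for r in rows],
        }
    )
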