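"""Volume-proportional null model and the one-sample proportion z-test.

The null hypothesis is equal metastatic risk per voxel: a region's expected
lesion rate p0 is its share of the total parcellated volume,

    p0(g) = V(g) / sum_g' V(g').

Each region's observed rate p = count/n (n = lesions assigned to any tested
region, *not* the cohort total — lesions whose centroid falls outside labeled
tissue are excluded) is compared to p0 with

    Z = (p - p0) / sqrt(p0 (1 - p0) / n),

two-tailed P = 2 (1 - Phi(|Z|)).  No continuity or finite-population
correction is applied.  Family-wise error across the k tested ROIs is
controlled by Bonferroni: significance at P <= alpha / k.

The normal approximation is poor when n*p0 or n*(1-p0) is small; results
carry an ``approximation_warning`` flag when either falls below 5, and
:func:`exact_binomial_p` provides the exact two-sided binomial P as an oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import RegionCountTable

__all__ = [
    "RiskTestResult",
    "expected_rates",
    "proportion_z",
    "two_tailed_p",
    "bonferroni_threshold",
    "exact_binomial_p",
    "risk_table",
    "risk_table_from_rates",
]

HIGHER = "HIGHER"
LOWER = "LOWER"
NONE = "NONE"


@dataclass(frozen=True)
class RiskTestResult:
    """One region's observed-vs-expected proportion test."""

    group: str
    volume_mm3: float
    expected_rate: float  # p0, fraction in [0, 1]
    observed_count: int
    observed_rate: float  # p = count / n
    n: int
    z: float
    p_two_tailed: float
    significant: bool
    direction: str  # HIGHER | LOWER | NONE
    approximation_warning: bool


def expected_rates(volumes: Mapping[str, float] | pd.DataFrame) -> dict[str, float]:
    """Expected rate per group under the equal-risk-per-voxel null.

    ``volumes`` maps group -> volume_mm3 (or is a DataFrame with columns
    ``group`` and ``volume_mm3``).  Returns p0 values summing to 1.
    """
    if isinstance(volumes, pd.DataFrame):
        volumes = dict(zip(volumes["group"], volumes["volume_mm3"]))
    if any(v < 0 for v in volumes.values()):
        raise ValueError("region volumes must be nonnegative")
    total = float(sum(volumes.values()))
    if total <= 0:
        raise ValueError("total region volume must be positive")
    return {g: float(v) / total for g, v in volumes.items()}


def proportion_z(p: float, p0: float, n: int) -> float:
    """One-sample proportion z-score, Z = (p - p0)/sqrt(p0(1-p0)/n)."""
    if not 0 < p0 < 1:
        raise ValueError(f"p0 must be strictly between 0 and 1, got {p0}")
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    return (p - p0) / math.sqrt(p0 * (1.0 - p0) / n)


def two_tailed_p(z: float) -> float:
    """Two-tailed P from the standard normal: P = 2(1 - Phi(|z|))."""
    if not np.isfinite(z):
        raise ValueError(f"z must be finite, got {z}")
    return float(np.clip(2.0 * stats.norm.sf(abs(z)), 0.0, 1.0))


def bonferroni_threshold(alpha: float, k_rois: int) -> float:
    """Corrected per-test significance level alpha / k."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if k_rois < 1:
        raise ValueError(f"k_rois must be >= 1, got {k_rois}")
    return alpha / k_rois


def exact_binomial_p(count: int, n: int, p0: float) -> float:
    """Exact two-sided binomial P (sum of outcome probabilities no larger
    than that of the observed count); the oracle for the normal approximation."""
    if not 0 <= count <= n:
        raise ValueError(f"count must be in [0, n], got {count} of {n}")
    if not 0 < p0 < 1:
        raise ValueError(f"p0 must be strictly between 0 and 1, got {p0}")
    return float(stats.binomtest(count, n, p0, alternative="two-sided").pvalue)


def _one_test(
    group: str,
    volume: float,
    count: int,
    n: int,
    p0: float,
    threshold: float,
    exact: bool,
) -> RiskTestResult:
    p = count / n
    z = proportion_z(p, p0, n)
    pval = exact_binomial_p(count, n, p0) if exact else two_tailed_p(z)
    significant = pval <= threshold
    direction = NONE
    if significant:
        direction = HIGHER if z > 0 else LOWER
    return RiskTestResult(
        group=group,
        volume_mm3=volume,
        expected_rate=p0,
        observed_count=int(count),
        observed_rate=p,
        n=int(n),
        z=z,
        p_two_tailed=pval,
        significant=significant,
        direction=direction,
        approximation_warning=bool(n * p0 < 5 or n * (1 - p0) < 5),
    )


def risk_table(
    counts: RegionCountTable,
    volumes: Mapping[str, float] | pd.DataFrame,
    alpha: float = 0.05,
    k_rois: int | None = None,
    exact: bool = False,
) -> list[RiskTestResult]:
    """Per-region risk tests with expected rates derived from region volumes.

    ``n`` is ``counts.n_assigned``.  Zero-count regions are tested (they get a
    computed negative z); zero-volume regions are excluded with a warning, and
    a zero-volume region with a positive count is a consistency error.
    ``k_rois`` defaults to the number of tested groups; override it to match a
    published correction family.  Results are ordered by descending |z|, ties
    by group name.
    """
    if isinstance(volumes, pd.DataFrame):
        volumes = dict(zip(volumes["group"], volumes["volume_mm3"]))
    missing = set(counts.counts) - set(volumes)
    if missing:
        raise ValueError(f"groups with counts but no volume: {sorted(missing)}")
    if counts.n_assigned < 1:
        raise ValueError("no assigned lesions; nothing to test")

    tested = {}
    for g, v in volumes.items():
        c = counts.counts.get(g, 0)
        if v <= 0:
            if c > 0:
                raise ValueError(f"group '{g}' has zero volume but {c} observed lesions")
            warnings.warn(f"group '{g}' has zero volume; excluded from testing", stacklevel=2)
            continue
        tested[g] = (v, c)

    p0s = expected_rates({g: v for g, (v, _) in tested.items()})
    k = k_rois if k_rois is not None else len(tested)
    threshold = bonferroni_threshold(alpha, k)
    n = counts.n_assigned
    results = [
        _one_test(g, v, c, n, p0s[g], threshold, exact) for g, (v, c) in tested.items()
    ]
    results.sort(key=lambda r: (-abs(r.z), r.group))
    return results


def risk_table_from_rates(
    rates: Mapping[str, float],
    counts: Mapping[str, int],
    n: int,
    alpha: float = 0.05,
    k_rois: int | None = None,
    volumes: Mapping[str, float] | None = None,
    exact: bool = False,
) -> list[RiskTestResult]:
    """Risk tests with expected rates supplied directly (they need not sum
    to 1 — useful when only a subset of a published table is available)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    k = k_rois if k_rois is not None else len(rates)
    threshold = bonferroni_threshold(alpha, k)
    results = []
    for g, p0 in rates.items():
        v = float(volumes.get(g, float("nan"))) if volumes else float("nan")
        results.append(_one_test(g, v, int(counts.get(g, 0)), n, p0, threshold, exact))
    results.sort(key=lambda r: (-abs(r.z), r.group))
    return results
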