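"""Preclinical quantification helpers: tumor volume, power-based sample size,
and multi-group comparison.

``tumor_volume`` implements the ellipsoid caliper approximation
``V = (pi/6) * length * width * thickness`` used for subcutaneous tumors;
``min_sample_size`` the two-group normal-approximation formula
``n = 2 * sigma^2 / delta^2 * (z_{1-alpha/2} + z_{1-beta})^2`` rounded up;
``group_compare`` a one-way ANOVA followed by Tukey-Kramer all-pairs tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TumorMeasurement",
    "SampleSizeSpec",
    "GroupComparison",
    "tumor_volume",
    "min_sample_size",
    "group_compare",
]


@dataclass(frozen=True)
class TumorMeasurement:
    """Caliper dimensions of one tumor, in millimetres."""

    length: float
    width: float
    thickness: float

    def __post_init__(self) -> None:
        for name in ("length", "width", "thickness"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def tumor_volume(m: TumorMeasurement) -> float:
    """Ellipsoid-approximation tumor volume in mm^3: (pi/6) * t * l * w."""
    return math.pi / 6.0 * m.thickness * m.length * m.width


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs of the two-group minimum sample-size formula.

    ``sigma`` is the common standard deviation and ``delta`` the smallest
    between-group difference to detect, in the same units; ``alpha`` and
    ``beta`` are the two-sided type-I and the type-II error probabilities.
    """

    sigma: float
    delta: float
    alpha: float = 0.05
    beta: float = 0.20

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not self.delta > 0:
            raise ValueError("delta must be positive (a zero difference is undetectable)")
        for name in ("alpha", "beta"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")


def min_sample_size(spec: SampleSizeSpec) -> int:
    """Minimum per-group n: ceil( 2 sigma^2/delta^2 (z_{1-a/2}+z_{1-b})^2 ), at least 2.

    The ceiling is taken with a small tolerance so exact-integer raw values do
    not round up spuriously.
    """
    z_a = float(stats.norm.ppf(1.0 - spec.alpha / 2.0))
    z_b = float(stats.norm.ppf(1.0 - spec.beta))
    raw = 2.0 * spec.sigma**2 / spec.delta**2 * (z_a + z_b) ** 2
    return max(2, math.ceil(raw - 1e-9))


@dataclass
class GroupComparison:
    """One-way ANOVA F/p plus Tukey-Kramer adjusted pairwise p-values."""

    f_statistic: float
    p_value: float
    pairwise_p: np.ndarray  # symmetric (k, k) matrix, diagonal 1

    def pair(self, i: int, j: int) -> float:
        return float(self.pairwise_p[i, j])


def group_compare(groups: Sequence[Sequence[float]]) -> GroupComparison:
    """One-way ANOVA with Tukey-Kramer all-pairs follow-up.

    Accepts unequal group sizes (the Kramer adjustment).  Degenerate input
    with zero total variance returns F = 0 and all p-values 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs at least two values")
    pooled = np.concatenate(arrays)
    k = len(arrays)
    if np.ptp(pooled) == 0:
        return GroupComparison(0.0, 1.0, np.ones((k, k)))
    f_stat, p = stats.f_oneway(*arrays)
    if not np.isfinite(f_stat):  # zero within-group variance
        f_stat, p = math.inf, 0.0
    tukey = stats.tukey_hsd(*arrays)
    pairwise = np.asarray(tukey.pvalue, dtype=float)
    np.fill_diagonal(pairwise, 1.0)
    return GroupComparison(float(f_stat), float(p), pairwise)
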