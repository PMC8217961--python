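"""Group comparison statistics for calibration and cohort experiments.

Two-sided Wilcoxon rank-sum (Mann-Whitney U) tests on per-image scores,
with discrimination counting over consecutive angle-range pairs: a method
"discriminates" a pair when p < alpha, with no multiple-testing correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.stats

__all__ = ["GroupComparison", "DiscriminationResult", "compare_groups",
           "discrimination_count"]

log = logging.getLogger(__name__)

_EXACT_MAX_N = 20


@dataclass(frozen=True)
class GroupComparison:
    """Result of one two-sided rank-sum test at significance level alpha."""

    p_value: float
    statistic: float
    alpha: float
    n_a: int
    n_b: int
    label_a: str = "a"
    label_b: str = "b"

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class DiscriminationResult:
    """Count of consecutive group pairs separated at p < alpha."""

    n_pairs: int
    n_discriminated: int
    p_values: tuple[float, ...]
    alpha: float
    method: str = ""
    diameter_um: float = float("nan")
    scale_um: float = float("nan")

    def __post_init__(self) -> None:
        if not 0 <= self.n_discriminated <= self.n_pairs:
            raise ValueError("n_discriminated out of range")


def compare_groups(a, b, alpha: float = 0.05,
                   label_a: str = "a", label_b: str = "b") -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test on two score samples.

    Uses the exact permutation null when the pooled sample is small
    (n ≤ 20) and tie-free, otherwise the tie-corrected normal
    approximation.  Pooled samples with all values identical give p = 1
    by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples must be finite (drop missing values first)")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        log.info("all pooled values identical; p = 1 by convention")
        return GroupComparison(1.0, float(a.size * b.size / 2), alpha,
                               a.size, b.size, label_a, label_b)
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= _EXACT_MAX_N and tie_free) else \
        "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                   method=method)
    return GroupComparison(float(res.pvalue), float(res.statistic), alpha,
                           a.size, b.size, label_a, label_b)


def discrimination_count(groups, alpha: float = 0.05, method: str = "",
                         diameter_um: float = float("nan"),
                         scale_um: float = float("nan"),
                         expected_n_groups: int | None = 19
                         ) -> DiscriminationResult:
    """Rank-sum tests on every consecutive pair of ordered score groups.

    ``groups`` are ordered by angle-range width (narrowest first in the
    calibration design).  The standard design has 19 groups hence 18
    pairs; pass ``expected_n_groups=None`` to lift that check.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if expected_n_groups is not None and len(groups) != expected_n_groups:
        raise ValueError(f"expected {expected_n_groups} groups, "
                         f"got {len(groups)}")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    p_values = tuple(
        compare_groups(groups[i], groups[i + 1], alpha).p_value
        for i in range(len(groups) - 1))
    n_disc = int(sum(p < alpha for p in p_values))
    return DiscriminationResult(n_pairs=len(p_values),
                                n_discriminated=n_disc,
                                p_values=p_values, alpha=alpha,
                                method=method, diameter_um=diameter_um,
                                scale_um=scale_um)
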