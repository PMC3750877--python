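"""Between-group statistics: weighted median, rank-sum, Fisher, BH.

The group-level density comparison uses the two-sided Wilcoxon rank-sum
(Mann-Whitney) test, since the CNVR groups are unpaired samples.  Fraction
comparisons (targeted genes, brain-related miRNAs) use the two-sided
Fisher's exact test.  Multiplicity control is Benjamini-Hochberg step-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "WeightedSample",
    "ComparisonResult",
    "weighted_median",
    "rank_sum_test",
    "fisher_fraction_test",
    "bh_adjust",
]


@dataclass(frozen=True)
class WeightedSample:
    """Per-region densities with aligned positive weights (region sizes)."""

    values: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        if len(self.values) != len(self.weights):
            raise ValueError("values and weights must align")
        if any(w <= 0 for w in self.weights):
            raise ValueError("weights must be positive")


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    statistic_name: str
    statistic: float
    p_value: float
    method_note: str = ""


def weighted_median(sample: WeightedSample) -> float:
    """Lower weighted median of a weighted sample.

    The smallest value ``v`` (scanning values in ascending order) whose
    cumulative weight reaches at least half the total weight.  With equal
    weights this is the ordinary lower median.  No interpolation is done
    when the cumulative weight hits exactly half — the lower value wins,
    which keeps the statistic at 0 for groups where more than half the
    weighted mass sits on empty regions.
    """
    if not sample.values:
        raise ValueError("weighted median of an empty sample")
    order = np.argsort(np.asarray(sample.values), kind="stable")
    values = np.asarray(sample.values)[order]
    weights = np.asarray(sample.weights, dtype=float)[order]
    half = weights.sum() / 2.0
    cum = np.cumsum(weights)
    idx = int(np.searchsorted(cum, half, side="left"))
    return float(values[idx])


def rank_sum_test(
    a: Sequence[float], b: Sequence[float],
    group_a: str = "A", group_b: str = "B",
) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test on two densities lists.

    Exact enumeration when both samples have <= 10 observations and the
    pooled data has no ties; the tie-corrected normal approximation
    otherwise.  The method note records which path ran.
    """
    if not len(a) or not len(b):
        raise ValueError("rank-sum test requires two non-empty samples")
    pooled = list(a) + list(b)
    exact = len(a) <= 10 and len(b) <= 10 and len(set(pooled)) == len(pooled)
    method = "exact" if exact else "asymptotic"
    # no continuity correction: identical samples give z = 0, p = 1 exactly
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=False)
    return ComparisonResult(
        group_a, group_b, "mann_whitney_U", float(res.statistic),
        float(min(1.0, res.pvalue)),
        method_note=f"wilcoxon rank-sum, {method} path",
    )


def fisher_fraction_test(
    k1: int, n1: int, k2: int, n2: int,
    group_a: str = "A", group_b: str = "B",
) -> ComparisonResult:
    """Two-sided Fisher's exact test comparing k1/n1 against k2/n2.

    The two-sided p sums the probabilities of all tables (with the same
    margins) at most as probable as the observed one.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2) or n1 == 0 or n2 == 0:
        raise ValueError("require 0 <= k <= n with n > 0 for both groups")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    res = sps.fisher_exact(table, alternative="two-sided")
    return ComparisonResult(
        group_a, group_b, "odds_ratio", float(res[0]), float(res[1]),
        method_note="two-sided Fisher's exact",
    )


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adj]


def pairwise_density_comparisons(
    samples: dict[str, Sequence[float]]
) -> list[ComparisonResult]:
    """Rank-sum comparison for every unordered pair of groups."""
    results = []
    for ga, gb in combinations(sorted(samples), 2):
        if len(samples[ga]) and len(samples[gb]):
            results.append(rank_sum_test(samples[ga], samples[gb], ga, gb))
    return results
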