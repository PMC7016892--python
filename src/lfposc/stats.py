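"""Nonparametric genotype-group comparison.

Per-animal scalar metrics are compared across groups with a
Kruskal-Wallis omnibus test evaluated at a Dunn-Sidak-adjusted level for
``k`` planned comparisons (the number of transgenic lines compared to
wild type).  Only when the omnibus test passes the adjusted level are
pairwise Mann-Whitney tests against the reference group run; results are
flagged ``*`` (p < 0.05) and ``**`` (p < 0.01).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class PairwiseTest:
    u: float
    p: float
    flag: str  # "", "*", "**"


@dataclass
class ComparisonResult:
    h: float
    p_omnibus: float
    alpha_adjusted: float
    gate_passed: bool
    pairwise: dict[str, PairwiseTest] = field(default_factory=dict)

    @property
    def significant_groups(self) -> list[str]:
        return [g for g, t in self.pairwise.items() if t.flag]


def kruskal_wallis(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Tie-corrected H statistic with chi-square p (df = n_groups - 1).

    If every value is identical the test is degenerate: H = 0, p = 1,
    with a warning.
    """
    vals = [np.asarray(v, float) for v in groups.values()]
    if len(vals) < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate(vals)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; Kruskal-Wallis is degenerate")
        return 0.0, 1.0
    h, p = sps.kruskal(*vals)
    return float(h), float(p)


def sidak_threshold(alpha: float, k: int) -> float:
    """Dunn-Sidak per-comparison level: 1 - (1 - alpha)**(1/k)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / k)


def mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact null distribution for small samples (min n <= 8, no ties);
    otherwise the normal approximation with tie and continuity
    correction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate((a, b))
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _flag(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_metric(groups: dict[str, np.ndarray], reference: str = "WT",
                   alpha: float = 0.05, k: int = 4) -> ComparisonResult:
    """Gatekept comparison of one metric across genotype groups.

    The Kruskal-Wallis omnibus test is the gate, evaluated at the
    Sidak-adjusted level for ``k`` comparisons; pairwise Mann-Whitney
    tests versus the reference group run only when the gate passes.
    """
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} missing")
    for g, v in groups.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 values")
    h, p = kruskal_wallis(groups)
    a_adj = sidak_threshold(alpha, k)
    result = ComparisonResult(h, p, a_adj, gate_passed=p < a_adj)
    if result.gate_passed:
        ref = np.asarray(groups[reference], float)
        for g, v in groups.items():
            if g == reference:
                continue
            u, pp = mann_whitney(np.asarray(v, float), ref)
            result.pairwise[g] = PairwiseTest(u, pp, _flag(pp))
    return result
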