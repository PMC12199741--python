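"""Rank-based two-sample tests with Bonferroni correction.

The Wilcoxon–Mann–Whitney rank-sum test is computed by exact enumeration of
all C(n+m, n) group assignments (midrank U statistic, so ties are handled)
when both samples have at most ``EXACT_MAX`` observations, and by the
tie-corrected normal approximation (scipy) otherwise.  Families of pairwise
comparisons are Bonferroni-adjusted: p_adj = min(1, m·p).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Sequence

import numpy as np
from scipy import stats as sps

EXACT_MAX = 8


@dataclass
class TestReport:
    """One pairwise rank-sum comparison inside a Bonferroni family."""

    group_a: str
    group_b: str
    statistic: float  # Mann–Whitney U of group_a
    p_raw: float
    p_adjusted: float
    m: int  # family size (number of comparisons)


def _midrank_u(x: np.ndarray, y: np.ndarray) -> float:
    """Mann–Whitney U of x vs y with 0.5 credit for ties."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def rank_sum_test(x: Sequence[float], y: Sequence[float]):
    """Two-sided rank-sum test; returns (U, p).

    Exact enumeration when both n, m <= 8; two-sidedness is the probability of
    a U at least as far from its null mean nm/2 as the observed one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    u_obs = _midrank_u(x, y)
    n, m = x.size, y.size
    if n <= EXACT_MAX and m <= EXACT_MAX:
        pooled = np.concatenate([x, y])
        centre = n * m / 2.0
        dev = abs(u_obs - centre)
        idx = range(n + m)
        hits = total = 0
        for comb in combinations(idx, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(comb)] = True
            u = _midrank_u(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - centre) >= dev - 1e-12:
                hits += 1
        return u_obs, hits / total
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value, capped at 1."""
    return min(1.0, p * m)


def pairwise_rank_sum(groups: Dict[str, Sequence[float]]) -> List[TestReport]:
    """All pairwise rank-sum tests among the groups, Bonferroni over the family."""
    names = [k for k, v in groups.items() if len(v) > 0]
    pairs = list(combinations(names, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        u, p = rank_sum_test(groups[a], groups[b])
        out.append(TestReport(a, b, u, p, bonferroni(p, m), m))
    return out
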