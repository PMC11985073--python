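"""Categorical and rank-based hypothesis tests for the feeding analyses.

All tests are two-sided.  Conventions:

* Fisher's exact 2x2 uses the probability-mass rule: the two-sided p is the
  sum of hypergeometric probabilities (margins fixed) of every table at most
  as likely as the one observed.
* Pearson chi-square is computed without continuity correction; a warning is
  issued when any expected count falls below 5.
* Mann-Whitney uses the exact permutation null when min(n) <= 8 and there are
  no ties, otherwise the normal approximation with tie and continuity
  corrections.  Censored values must never reach it — callers flag the input.
* Kruskal-Wallis uses the tie-corrected H with a chi-square reference
  (k - 1 df); Dunn's posttest compares mean ranks pairwise with a Bonferroni
  adjustment over the reported pairs (all pairs, or each group versus a
  control).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float | None
    p: float
    df: int | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"test": self.test, "statistic": self.statistic, "p": self.p}
        if self.df is not None:
            out["df"] = self.df
        out.update(self.extra)
        return out


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)) or np.any(arr < 0):
            raise ValueError("counts must be non-negative integers")
        arr = np.round(arr).astype(int)
    if arr.sum() < 1:
        raise ValueError("grand total must be >= 1")
    return arr


def fisher_exact_2x2(table) -> TestResult:
    arr = _as_table(table)
    if arr.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table; use chi_square_test for r x c")
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return TestResult("fisher_exact", None, float(min(p, 1.0)))


def chi_square_test(table) -> TestResult:
    arr = _as_table(table)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero row/column margin: chi-square undefined")
    stat, p, df, expected = stats.chi2_contingency(arr, correction=False)
    if np.any(expected < 5):
        warnings.warn(
            f"expected count below 5 (min {expected.min():.2f}); chi-square approximation "
            "may be unreliable",
            stacklevel=2,
        )
    return TestResult("chi_square", float(stat), float(p), int(df))


#: Largest min(n) at which the exact Mann-Whitney permutation null is used.
MANN_WHITNEY_EXACT_MAX_N = 8


def mann_whitney(values_a, values_b, censored: bool = False) -> TestResult:
    """Two-sided Mann-Whitney U on uncensored values.

    ``censored=True`` signals that the caller failed to strip censored
    records and is an error: rank tests on window-truncated values are
    meaningless.
    """
    if censored:
        raise ValueError("mann_whitney requires uncensored values; strip censored records first")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if min(a.size, b.size) <= MANN_WHITNEY_EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return TestResult("mann_whitney", float(res.statistic), float(res.pvalue), extra={"method": method})


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: p -> min(1, p * m), m >= number of p-values."""
    ps = list(np.atleast_1d(np.asarray(p_values, dtype=float)))
    if m is None:
        m = len(ps)
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if m < len(ps):
        raise ValueError(f"family size m={m} smaller than number of p-values ({len(ps)})")
    return [float(min(1.0, p * m)) for p in ps]


@dataclass(frozen=True)
class DunnComparison:
    pair: tuple[int, int]
    z: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class KruskalDunnResult:
    H: float
    p_overall: float
    df: int
    pairwise: list[DunnComparison]

    def to_dict(self) -> dict:
        return {
            "test": "kruskal_wallis",
            "statistic": self.H,
            "p": self.p_overall,
            "df": self.df,
            "dunn": [
                {"pair": list(c.pair), "z": c.z, "p_raw": c.p_raw, "p_adjusted": c.p_adjusted}
                for c in self.pairwise
            ],
        }


def kruskal_wallis_dunn(
    groups: Sequence[Sequence[float]], pairs: str = "all"
) -> KruskalDunnResult:
    """Tie-corrected Kruskal-Wallis H with Dunn's pairwise posttest.

    ``pairs="all"`` adjusts over all k(k-1)/2 pairs; ``pairs="vs-first"``
    treats group 0 as the control and adjusts over the k - 1 comparisons
    against it (the convention for a time-course with a starved control).
    """
    k = len(groups)
    if k < 3:
        raise ValueError("need at least 3 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    H, p_overall = stats.kruskal(*arrays)

    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [a.size for a in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(k)]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    variance_scale = n_total * (n_total + 1) / 12.0 - tie_term

    if pairs == "all":
        index_pairs = list(itertools.combinations(range(k), 2))
    elif pairs == "vs-first":
        index_pairs = [(0, j) for j in range(1, k)]
    else:
        raise ValueError("pairs must be 'all' or 'vs-first'")
    m = len(index_pairs)
    comparisons = []
    for i, j in index_pairs:
        se = np.sqrt(variance_scale * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        comparisons.append(DunnComparison((i, j), float(z), float(p_raw), min(1.0, float(p_raw) * m)))
    return KruskalDunnResult(float(H), float(p_overall), k - 1, comparisons)
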