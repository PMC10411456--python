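"""Exact nonparametric tests and multiplicity adjustment.

Conventions (all documented because alternatives exist in the literature):

* **Fisher's exact test**, two-sided, probability-mass rule: the p-value
  sums the hypergeometric probabilities (margins fixed) of every 2x2 table
  whose probability does not exceed that of the observed table.  Computed
  in exact integer arithmetic, so no floating-point tie ambiguity.
* **Wilcoxon signed-rank**: zero differences are dropped (Wilcoxon's
  convention); ties in |difference| receive midranks.  For m <= ``exact_limit``
  remaining pairs the two-sided p is exact over the 2^m equiprobable sign
  assignments (computed by subset-sum convolution over doubled midranks,
  which yields the identical distribution), as
  ``min(1, 2 * min(P(W+ <= w), P(W+ >= w)))``.  Above the limit a normal
  approximation with tie-corrected variance and no continuity correction
  is used.
* **Pearson chi-square** without continuity correction (tables larger than
  2x2 appear in the characteristics analysis; one uniform rule).
* **Bonferroni**: adjusted p = min(1, m * p) with family size m surfaced in
  the result rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb, sqrt

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class ContingencyTable:
    """r x c table of non-negative integer counts with axis labels."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise ValueError("cell counts must be integers")
        if (arr < 0).any():
            raise ValueError("cell counts must be non-negative")
        if arr.sum() < 1:
            raise ValueError("grand total must be >= 1")

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: int
    adjustment: str = "none"
    degenerate: bool = False


def _as_2x2(table) -> np.ndarray:
    arr = table.to_array() if isinstance(table, ContingencyTable) else np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 needs a 2x2 table")
    if not np.all(arr == np.floor(arr)) or (arr < 0).any():
        raise ValueError("cells must be non-negative integers")
    return arr.astype(np.int64)


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table (probability-mass rule).

    All tables with the observed margins are enumerated; p sums the exact
    hypergeometric weights ``C(r1, k) * C(r2, c1 - k)`` of tables no more
    probable than the observed one, normalised by ``C(N, c1)``.
    """
    arr = _as_2x2(table)
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    w_obs = comb(r1, a) * comb(r2, c)
    num = sum(
        w for k in range(lo, hi + 1) if (w := comb(r1, k) * comb(r2, c1 - k)) <= w_obs
    )
    p = float(Fraction(num, comb(n, c1))) if n > 0 else 1.0
    odds = float(a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
    return TestResult(statistic=odds, p_value=min(p, 1.0), method="fisher_exact", n=n)


def chi_square(table) -> TestResult:
    """Pearson chi-square on an r x c table, no continuity correction."""
    arr = table.to_array() if isinstance(table, ContingencyTable) else np.asarray(table)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValueError("chi_square needs an r x c table, r, c >= 2")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin: expected counts undefined")
    stat, p, dof, _ = sps.chi2_contingency(arr, correction=False)
    return TestResult(
        statistic=float(stat), p_value=float(p), method=f"chi_square_df{dof}", n=int(arr.sum())
    )


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p over all sign assignments, via the null distribution.

    Midranks are multiples of 1/2, so doubling makes them integers; the
    number of sign assignments achieving each doubled rank-sum is built by
    convolution, which enumerates the same 2^m assignments implicitly.
    """
    doubled = np.rint(2 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=object)  # exact integers, no overflow
    counts[0] = 1
    for r in doubled:  # r >= 2: smallest midrank is 1 after zero-dropping
        counts[r:] = counts[r:] + counts[:-r]
    w = int(round(2 * w_plus))
    m = len(ranks)
    denom = 1 << m
    p_le = int(sum(counts[: w + 1])) / denom
    p_ge = int(sum(counts[w:])) / denom
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(baseline, scenario, exact_limit: int = 25) -> TestResult:
    """Paired Wilcoxon signed-rank test on (baseline_i, scenario_i).

    Returns W+ (sum of ranks of positive ``scenario - baseline``
    differences) and the two-sided p; see module docstring for the exact /
    approximate switch and tie handling.  A sample whose differences are
    all zero yields p = 1 with ``degenerate=True``.
    """
    x = np.asarray(baseline, dtype=float)
    y = np.asarray(scenario, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("baseline and scenario must be aligned 1-d samples")
    if x.size < 1:
        raise ValueError("need at least one pair")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    d = y - x
    d = d[d != 0]  # drop-zeros convention
    m = d.size
    if m == 0:
        return TestResult(0.0, 1.0, "wilcoxon_signed_rank", n=x.size, degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if m <= exact_limit:
        p = _signed_rank_exact_p(ranks, w_plus)
        method = "wilcoxon_signed_rank_exact"
    else:
        mean = m * (m + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = m * (m + 1) * (2 * m + 1) / 24.0 - float(
            ((tie_counts**3 - tie_counts) / 48.0).sum()
        )
        if var <= 0:
            return TestResult(w_plus, 1.0, "wilcoxon_signed_rank_normal", n=x.size, degenerate=True)
        z = (w_plus - mean) / sqrt(var)
        p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
        method = "wilcoxon_signed_rank_normal"
    return TestResult(w_plus, p, method, n=x.size)


def bonferroni_adjust(p_values, family_size: int | None = None) -> list[float]:
    """Bonferroni adjustment: min(1, m * p) per value, order preserving."""
    p = list(map(float, p_values))
    if any(not 0 <= v <= 1 for v in p):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p) if family_size is None else int(family_size)
    if m < len(p):
        raise ValueError("family size must be >= number of p values")
    return [min(1.0, m * v) for v in p]
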