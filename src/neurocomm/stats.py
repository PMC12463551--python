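"""Shared statistical utilities.

Bespoke implementations are limited to the procedures whose exact behavior
matters downstream (Benjamini–Hochberg step-up, Mann–Kendall trend,
permutation test of mean difference, balanced bootstrap CIs).  Standard
two-sample machinery (t, Wilcoxon, Kruskal–Wallis, one-way ANOVA) is
delegated to scipy and wrapped for a uniform result record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    """Uniform container for a hypothesis-test outcome."""

    statistic: float
    p_value: float
    method: str
    n: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# Multiple comparisons


def benjamini_hochberg(pvals: Sequence[float], q: float = 0.05):
    """Benjamini–Hochberg step-up FDR control.

    Returns (reject, p_adjusted), both aligned with the input order.
    Adjusted p values are monotone nondecreasing in the raw-p order.
    """
    p = np.asarray(pvals, dtype=float)
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    # step-up: largest i with p_(i) <= i*q/m; everything up to it rejected
    thresh = (np.arange(1, m + 1) / m) * q
    passing = np.nonzero(ranked <= thresh)[0]
    reject_sorted = np.zeros(m, dtype=bool)
    if passing.size:
        reject_sorted[: passing[-1] + 1] = True
    adj_sorted = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    reject = np.zeros(m, dtype=bool)
    p_adj = np.zeros(m)
    reject[order] = reject_sorted
    p_adj[order] = adj_sorted
    return reject, p_adj


# ---------------------------------------------------------------------------
# Mann–Kendall trend test


def _kendall_s(x: np.ndarray) -> int:
    diff = np.sign(x[None, :] - x[:, None])
    return int(np.triu(diff, k=1).sum())


def _exact_s_distribution(n: int) -> dict[int, int]:
    """Null distribution of the Mann–Kendall S statistic for tie-free data.

    Counts permutations by inversion number (Mahonian recursion);
    S = C(n,2) - 2 * inversions.
    """
    counts = {0: 1}
    for k in range(2, n + 1):
        new: dict[int, int] = {}
        for inv, c in counts.items():
            for add in range(k):
                new[inv + add] = new.get(inv + add, 0) + c
        counts = new
    total_pairs = n * (n - 1) // 2
    return {total_pairs - 2 * inv: c for inv, c in counts.items()}


def mann_kendall(series: Sequence[float]) -> TestResult:
    """Mann–Kendall trend test (two-sided).

    Exact enumeration of the S null for n <= 10 with no ties; otherwise the
    normal approximation with tie-corrected variance and continuity
    correction.  tau = S / (n(n-1)/2).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("Mann–Kendall requires at least 4 observations")
    s = _kendall_s(x)
    n_pairs = n * (n - 1) / 2
    tau = s / n_pairs
    _, tie_counts = np.unique(x, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    if np.all(tie_counts == n):  # constant series
        return TestResult(0.0, 1.0, "mann-kendall", n)
    if n <= 10 and not has_ties:
        dist = _exact_s_distribution(n)
        total = sum(dist.values())
        p = sum(c for val, c in dist.items() if abs(val) >= abs(s)) / total
    else:
        var = n * (n - 1) * (2 * n + 5) / 18.0
        var -= np.sum(tie_counts * (tie_counts - 1) * (2 * tie_counts + 5)) / 18.0
        if var <= 0:
            return TestResult(tau, 1.0, "mann-kendall", n)
        if s > 0:
            z = (s - 1) / np.sqrt(var)
        elif s < 0:
            z = (s + 1) / np.sqrt(var)
        else:
            z = 0.0
        p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(tau, min(p, 1.0), "mann-kendall", n, {"S": s})


# ---------------------------------------------------------------------------
# Permutation test


def permutation_test_means(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> TestResult:
    """Two-sided permutation test on the difference of group means.

    p = (1 + #{|Δ_perm| >= |Δ_obs|}) / (1 + n_perm).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    n_a = a.size
    d_obs = a.mean() - b.mean()
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = perm[:n_a].mean() - perm[n_a:].mean()
        if abs(d) >= abs(d_obs) - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return TestResult(d_obs, p, "permutation-means", a.size + b.size)


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_ci(
    samples_by_group: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    ci: float = 0.95,
):
    """Balanced bootstrap mean and percentile CI.

    Each group (e.g. animal) contributes an equal number of resampled points
    per draw — the minimum group size — so no group dominates.  Returns
    (point_estimate, (lo, hi), draws).
    """
    if isinstance(samples_by_group, Mapping):
        groups = [np.asarray(v, dtype=float) for v in samples_by_group.values()]
    else:
        groups = [np.asarray(v, dtype=float) for v in samples_by_group]
    groups = [g for g in groups if g.size > 0]
    if not groups:
        raise ValueError("no non-empty groups")
    rng = np.random.default_rng(seed)
    n_take = min(g.size for g in groups)
    draws = np.empty(n_boot)
    for i in range(n_boot):
        resampled = np.concatenate(
            [g[rng.integers(0, g.size, size=n_take)] for g in groups]
        )
        draws[i] = statistic(resampled)
    point = statistic(np.concatenate(groups))
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    degenerate = all(g.size == 1 for g in groups)
    if degenerate:
        lo = hi = point
    return point, (float(lo), float(hi)), draws


# ---------------------------------------------------------------------------
# scipy-backed wrappers


def two_sample_t(a, b) -> TestResult:
    a, b = np.asarray(a, float), np.asarray(b, float)
    res = sps.ttest_ind(a, b)
    return TestResult(float(res.statistic), float(res.pvalue), "two-sample-t", a.size + b.size)


def paired_t(a, b) -> TestResult:
    a, b = np.asarray(a, float), np.asarray(b, float)
    res = sps.ttest_rel(a, b)
    return TestResult(float(res.statistic), float(res.pvalue), "paired-t", a.size)


def wilcoxon_signed_rank(a, b=None) -> TestResult:
    res = sps.wilcoxon(a, b)
    n = len(a)
    return TestResult(float(res.statistic), float(res.pvalue), "wilcoxon", n)


def rank_sum(a, b) -> TestResult:
    res = sps.ranksums(a, b)
    return TestResult(float(res.statistic), float(res.pvalue), "rank-sum", len(a) + len(b))


def kruskal_wallis(*groups) -> TestResult:
    res = sps.kruskal(*groups)
    return TestResult(float(res.statistic), float(res.pvalue), "kruskal-wallis", sum(len(g) for g in groups))


def one_way_anova(*groups) -> TestResult:
    res = sps.f_oneway(*groups)
    return TestResult(float(res.statistic), float(res.pvalue), "anova", sum(len(g) for g in groups))
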