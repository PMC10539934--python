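"""Group-comparison statistics: normality-gated tests, exact rank-sum,
chi-square, Benjamini-Hochberg FDR with per-family schemes, and bootstrap CIs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "normality_gate_compare",
    "wilcoxon_rank_sum",
    "chi_square_counts",
    "bh_fdr",
    "fdr_scheme",
    "bootstrap_ci",
]


@dataclass
class ComparisonResult:
    """One feature's group contrast."""

    feature: dict = field(default_factory=dict)  # e.g. {"band": "theta", "channel": "C4"}
    test: str = ""
    statistic: float = float("nan")
    p_raw: float = float("nan")
    p_fdr: float | None = None
    summary_a: str = ""
    summary_b: str = ""
    ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.p_raw) and not 0 <= self.p_raw <= 1:
            raise ValueError("p-value out of [0, 1]")


def _exact_ranksum_no_ties(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum p via the shift-count distribution (no ties)."""
    n1, n2 = len(a), len(b)
    # Null distribution of the Mann-Whitney U statistic by the standard
    # recurrence on the largest pooled element:
    #   N(u; n1, n2) = N(u - n2; n1-1, n2) + N(u; n1, n2-1)
    dp: dict[tuple[int, int], np.ndarray] = {}

    def dist(i: int, j: int) -> np.ndarray:
        key = (i, j)
        if key in dp:
            return dp[key]
        if i == 0 or j == 0:
            out = np.ones(1)
        else:
            left = dist(i - 1, j)   # largest element in sample a: U shifted by j
            right = dist(i, j - 1)  # largest element in sample b: U unchanged
            out = np.zeros(i * j + 1)
            out[j : j + left.size] += left
            out[: right.size] += right
        dp[key] = out
        return out

    pmf = dist(n1, n2)
    pmf = pmf / pmf.sum()
    u = 0.0
    for x in a:
        u += np.sum(b < x)
    u = float(u)
    # two-sided: double the smaller tail (with point mass), capped at 1
    lo = pmf[: int(u) + 1].sum()
    hi = pmf[int(u):].sum()
    p = min(1.0, 2.0 * min(lo, hi))
    w = u + n1 * (n1 + 1) / 2.0  # rank-sum statistic of sample a
    return w, float(p)


def _exact_ranksum_enumerate(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Full enumeration with midranks; feasible for small combined n."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1, n = len(a), len(pooled)
    w_obs = ranks[:n1].sum()
    mean_w = n1 * (n + 1) / 2.0
    obs_dev = abs(w_obs - mean_w)
    count = 0
    total = 0
    for comb in itertools.combinations(range(n), n1):
        total += 1
        w = ranks[list(comb)].sum()
        if abs(w - mean_w) >= obs_dev - 1e-12:
            count += 1
    return float(w_obs), count / total


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum W of ``a``, p).

    Uses the exact null distribution for combined n <= 25 without ties (full
    enumeration with midranks for combined n <= 14 when ties are present);
    otherwise the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    n = a.size + b.size
    has_ties = np.unique(np.concatenate([a, b])).size < n
    if n <= 25 and not has_ties:
        return _exact_ranksum_no_ties(a, b)
    if n <= 14 and has_ties:
        return _exact_ranksum_enumerate(a, b)
    res = sps.ranksums(a, b)
    ranks = sps.rankdata(np.concatenate([a, b]))
    return float(ranks[: a.size].sum()), float(res.pvalue)


def normality_gate_compare(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05,
    feature: dict | None = None,
) -> ComparisonResult:
    """Shapiro-Wilk-gated two-sample comparison.

    If both samples pass Shapiro-Wilk normality at ``alpha``, an independent
    two-sample t-test is used and groups are summarised as mean (SD);
    otherwise the Wilcoxon rank-sum test with median (IQR) summaries.
    Degenerate (zero-variance, identical) inputs return p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs at least 3 values")
    feature = feature or {}

    def _mean_sd(x):
        return f"{x.mean():.4g} ({x.std(ddof=1):.4g})"

    def _med_iqr(x):
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return f"{med:.4g} ({q1:.4g}-{q3:.4g})"

    if np.ptp(a) == 0 and np.ptp(b) == 0:
        warnings.warn("degenerate zero-variance samples; returning p = 1", stacklevel=2)
        return ComparisonResult(
            feature, "degenerate", 0.0, 1.0,
            summary_a=_mean_sd(a), summary_b=_mean_sd(b),
        )
    normal = (
        np.ptp(a) > 0 and np.ptp(b) > 0
        and sps.shapiro(a).pvalue > alpha
        and sps.shapiro(b).pvalue > alpha
    )
    if normal:
        res = sps.ttest_ind(a, b)
        return ComparisonResult(
            feature, "t", float(res.statistic), float(res.pvalue),
            summary_a=_mean_sd(a), summary_b=_mean_sd(b),
        )
    stat, p = wilcoxon_rank_sum(a, b)
    return ComparisonResult(
        feature, "wilcoxon", stat, p,
        summary_a=_med_iqr(a), summary_b=_med_iqr(b),
    )


def chi_square_counts(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Pearson chi-square test on a 2 x k contingency table, no continuity
    correction; returns (statistic, p)."""
    t = np.asarray(table)
    if t.ndim != 2 or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table must be a 2-d array of non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj(i) = min_{j >= i} (N * p(j) / j) over ascending-sorted p-values,
    clipped to 1 and returned in the original input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def fdr_scheme(results: Iterable[ComparisonResult], scheme: str) -> list[ComparisonResult]:
    """Apply BH-FDR within the correction families of the chosen scheme.

    ``per_band_across_electrodes``: one family per band, members are the 19
    electrodes (requires feature keys ``band`` and ``channel``).
    ``per_connection_across_bands``: one family per connection, members are
    the 5 bands (requires feature keys ``pair`` and ``band``).
    ``none``: leave ``p_fdr`` unset (used for the efficiency and small-world
    sweeps, which are reported uncorrected).
    """
    results = list(results)
    if scheme == "none":
        for r in results:
            r.p_fdr = None
        return results
    if scheme == "per_band_across_electrodes":
        group_key, member_key = "band", "channel"
    elif scheme == "per_connection_across_bands":
        group_key, member_key = "pair", "band"
    else:
        raise ValueError(f"unknown FDR scheme {scheme!r}")
    families: dict = {}
    for idx, r in enumerate(results):
        if group_key not in r.feature or member_key not in r.feature:
            raise KeyError(
                f"scheme {scheme!r} needs feature keys "
                f"{group_key!r} and {member_key!r}"
            )
        families.setdefault(r.feature[group_key], []).append(idx)
    for members in families.values():
        adj = bh_fdr([results[i].p_raw for i in members])
        for i, q in zip(members, adj):
            results[i].p_fdr = float(q)
    return results


def bootstrap_ci(
    x: Sequence[float],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean (``n_boot`` resamples with
    replacement); reproducible given ``seed``."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to bootstrap")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
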