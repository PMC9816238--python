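"""Statistical comparisons used in the degradation-SNV analysis.

Three tests cover the study's questions: a Mann-Whitney U rank test for PRV
differences between two storage times (or conditions), a one-way ANOVA for
PRV across all time points of a group, and a Pearson chi-square test on
count tables (e.g. spanning-deletion vs substitution changes between
matrices).  P-values are reported unadjusted; an optional
Benjamini-Hochberg helper is provided but applied nowhere by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

#: below this per-group size (and with no ties) the exact Mann-Whitney null
#: distribution is enumerated instead of the normal approximation
EXACT_MWU_MAX_N = 25


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    test: str
    n: tuple[int, ...]


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> TestResult:
    """Mann-Whitney U test with midrank ties.

    U is the rank-sum statistic for ``x``; the p-value comes from exact
    enumeration of rank assignments when both samples are small and tie-free,
    and from the tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    small = max(x.size, y.size) <= EXACT_MWU_MAX_N
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return TestResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        test=f"mann-whitney-u ({method})",
        n=(int(x.size), int(y.size)),
    )


def anova_oneway(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA: F = (SSB / df_between) / (SSW / df_within).

    Raises ValueError when both the between- and within-group variance are
    zero (F is undefined).
    """
    if isinstance(groups, Mapping):
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    n = sum(a.size for a in arrays)
    if n <= k:
        raise ValueError("total n must exceed the number of groups")
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n - k
    if ssw == 0 and ssb == 0:
        raise ValueError("all values identical: F undefined")
    if ssw == 0:
        return TestResult(float("inf"), 0.0, "anova-oneway", tuple(a.size for a in arrays))
    f = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return TestResult(float(f), p, "anova-oneway", tuple(a.size for a in arrays))


def chi_square_counts(
    table: Sequence[Sequence[float]] | np.ndarray, correction: bool = False
) -> TestResult:
    """Pearson chi-square test of independence on a 2 x k count table.

    No continuity correction by default; set ``correction=True`` to apply
    Yates' correction on a 2 x 2 table.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need a 2-dimensional table with >= 2 rows and columns")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total: expected counts undefined")
    res = sps.chi2_contingency(table, correction=correction)
    return TestResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        test="pearson-chi2" + (" (yates)" if correction else ""),
        n=(int(table.sum()),),
    )


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (not applied by default anywhere in the pipeline)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
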