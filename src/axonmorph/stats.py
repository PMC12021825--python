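"""Group and subregion statistics.

Morphometric distributions in EM sections are heavy-tailed and
non-normal; the module therefore screens with the Shapiro-Wilk test (as
a reported gate, never an automatic method switch) and compares groups
with the two-sided Mann-Whitney U (Wilcoxon rank-sum) test. Exact
permutation p-values are used for small tie-free samples, a tie- and
continuity-corrected normal approximation otherwise. No multiple-testing
correction is applied by default, matching the raw-p reporting style of
the underlying comparisons; Bonferroni/Benjamini-Hochberg adjustment is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "shapiro_wilk",
    "mann_whitney_u",
    "summarize",
    "relative_change",
    "compare_groups",
    "histogram",
    "adjust_pvalues",
]

#: exact-enumeration cutoff: total sample size at or below which the
#: Mann-Whitney p is computed by exact permutation (tie-free inputs)
EXACT_THRESHOLD = 12

SHAPIRO_N_MAX = 5000


@dataclass
class ComparisonResult:
    """One two-sample rank comparison."""

    metric: str
    group_a: str
    group_b: str
    stratum: str | None
    n_a: int
    n_b: int
    U: float
    z: float
    p: float
    median_a: float
    median_b: float
    direction: str  # "a>b", "a<b" or "a=b" by median
    method: str     # "exact" or "asymptotic"

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def shapiro_wilk(values, n_max: int = SHAPIRO_N_MAX, seed: int = 0):
    """Shapiro-Wilk normality test, subsampling very large vectors.

    The W statistic is undefined below n=3 and over-powered (and outside
    its validated range) at the 10^5-10^6 instance counts of whole
    sections, so vectors longer than ``n_max`` are subsampled without
    replacement with a fixed seed. The result is a gate message for the
    analyst; it never silently switches the downstream test.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) < 3:
        raise ValueError(f"Shapiro-Wilk requires n >= 3, got n={len(values)}")
    if np.ptp(values) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    if len(values) > n_max:
        rng = np.random.default_rng(seed)
        values = rng.choice(values, size=n_max, replace=False)
    W, p = sps.shapiro(values)
    return float(W), float(p)


def _rank_sum_z(x: np.ndarray, y: np.ndarray, U: float) -> float:
    """Tie- and continuity-corrected normal-approximation z for U."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 0.0
    mu = n1 * n2 / 2.0
    diff = U - mu
    cc = 0.5 * np.sign(diff)  # continuity correction toward the null
    return float((diff - cc) / np.sqrt(sigma2))


def mann_whitney_u(x, y, metric: str = "", group_a: str = "a",
                   group_b: str = "b", stratum: str | None = None,
                   exact_threshold: int = EXACT_THRESHOLD) -> ComparisonResult:
    """Two-sided Mann-Whitney U (Wilcoxon rank-sum) test.

    U is the statistic of ``x`` from midrank assignment (so
    ``U_x + U_y = n1*n2``). For tie-free samples with
    ``n1 + n2 <= exact_threshold`` the p-value is computed by exact
    permutation; otherwise by the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    use_exact = (len(x) + len(y) <= exact_threshold) and not has_ties
    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    U = float(res.statistic)
    z = _rank_sum_z(x, y, U)
    med_a, med_b = float(np.median(x)), float(np.median(y))
    if med_a > med_b:
        direction = "a>b"
    elif med_a < med_b:
        direction = "a<b"
    else:
        direction = "a=b"
    return ComparisonResult(
        metric=metric, group_a=group_a, group_b=group_b, stratum=stratum,
        n_a=len(x), n_b=len(y), U=U, z=z, p=float(min(res.pvalue, 1.0)),
        median_a=med_a, median_b=med_b, direction=direction, method=method,
    )


def summarize(values) -> dict:
    """Mean, sample SD (n-1), median and n of a vector.

    A singleton sample reports SD 0 with ``sd_defined=False``.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) == 0:
        raise ValueError("cannot summarize an empty vector")
    sd_defined = len(values) > 1
    return {
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if sd_defined else 0.0,
        "median": float(np.median(values)),
        "n": int(len(values)),
        "sd_defined": sd_defined,
    }


def relative_change(count_a: int, count_b: int) -> float:
    """Percent change of ``count_a`` relative to baseline ``count_b``.

    ``100 * (a - b) / b``; display at one decimal. The unrounded value is
    returned so that the reciprocal identity
    ``(1 + r_ab/100) * (1 + r_ba/100) = 1`` holds exactly.
    """
    if count_b == 0:
        raise ValueError("baseline count must be nonzero")
    return 100.0 * (count_a - count_b) / count_b


def compare_groups(tables: dict[str, pd.DataFrame], metrics: list[str],
                   strata: str | None = None) -> list[ComparisonResult]:
    """All pairwise rank-sum comparisons across groups (and subregions).

    For every metric: between-group comparisons on the pooled tables;
    when ``strata`` names a column (e.g. ``"subregion"``), additionally
    between-group comparisons within each stratum and, within each
    group, comparisons between every pair of strata.
    """
    for m in metrics:
        for name, t in tables.items():
            if m not in t.columns:
                raise KeyError(f"metric {m!r} missing from group {name!r}")
    names = list(tables)
    results: list[ComparisonResult] = []
    for m in metrics:
        for ga, gb in combinations(names, 2):
            results.append(mann_whitney_u(
                tables[ga][m], tables[gb][m], metric=m,
                group_a=ga, group_b=gb, stratum=None))
        if strata is None:
            continue
        levels: list[str] = sorted(
            set().union(*(set(t[strata].dropna().unique()) for t in tables.values())))
        # between groups, within each stratum
        for s in levels:
            for ga, gb in combinations(names, 2):
                xa = tables[ga].loc[tables[ga][strata] == s, m]
                xb = tables[gb].loc[tables[gb][strata] == s, m]
                if len(xa.dropna()) and len(xb.dropna()):
                    results.append(mann_whitney_u(
                        xa, xb, metric=m, group_a=ga, group_b=gb, stratum=s))
        # within each group, between strata
        for g in names:
            for sa, sb in combinations(levels, 2):
                xa = tables[g].loc[tables[g][strata] == sa, m]
                xb = tables[g].loc[tables[g][strata] == sb, m]
                if len(xa.dropna()) and len(xb.dropna()):
                    results.append(mann_whitney_u(
                        xa, xb, metric=m, group_a=f"{g}:{sa}",
                        group_b=f"{g}:{sb}", stratum=f"{g}"))
    return results


def histogram(values, bins="fd"):
    """Frequency histogram with a Freedman-Diaconis default bin policy.

    Returns (edges, counts); counts always sum to n. ``bins`` accepts
    anything ``numpy.histogram`` does (rule name, count, or edges).
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) == 0:
        raise ValueError("cannot histogram an empty vector")
    if np.ptp(values) == 0:
        # all-equal input: numpy's estimators degenerate; one unit-wide bin
        if isinstance(bins, str):
            bins = 1
    counts, edges = np.histogram(values, bins=bins)
    return edges, counts


def adjust_pvalues(results: list[ComparisonResult],
                   method: str = "bonferroni") -> list[float]:
    """Optional multiple-testing adjustment (off by default upstream).

    ``method`` is ``"bonferroni"`` or ``"bh"`` (Benjamini-Hochberg).
    Returns adjusted p-values in the order of ``results``.
    """
    p = np.array([r.p for r in results], dtype=float)
    m = len(p)
    if method == "bonferroni":
        return list(np.minimum(p * m, 1.0))
    if method == "bh":
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * m / (rank_idx + 1))
            adj[i] = running
        return list(np.minimum(adj, 1.0))
    raise ValueError(f"unknown adjustment method {method!r}")
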