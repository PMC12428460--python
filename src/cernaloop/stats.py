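"""Nonparametric test kernel used by every downstream stage.

The cohort analyses follow a nonparametric policy throughout (group
comparisons via Mann–Whitney / Kruskal–Wallis with Dunn's post hoc,
categorical association via the Fisher exact test, correlation via
Spearman's rank test), chosen after a normality pre-screen of the
expression data.  Routing every stage through this module keeps the
statistics auditable and swappable in one place.

Exactness policy
----------------
Small tie-free problems take an enumeration path (exact p-values); larger
or tied problems take the standard large-sample approximations with tie
and continuity corrections:

* Mann–Whitney: exact by rank-subset enumeration for n1+n2 <= 12 without
  ties; otherwise normal approximation with tie correction and (by
  default) continuity correction.
* Spearman: exact by full permutation enumeration for n <= 8 without
  ties; otherwise the t approximation with n-2 degrees of freedom.
* Fisher 2×2: always exact, two-sided by the minimum-likelihood rule.

Reported p-values are floored at ``P_FLOOR`` so that a vanishing p is
rendered "< 1e-300" rather than 0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.stats import chi2, hypergeom, norm, rankdata
from scipy.stats import t as t_dist

from .errors import UndefinedResultError

P_FLOOR = 1e-300
EXACT_MW_MAX_N = 12
EXACT_SPEARMAN_MAX_N = 8

ALTERNATIVES = ("two_sided", "greater", "less")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``exact`` is True only when the p-value comes from enumeration.
    ``estimate`` carries a test-specific effect estimate (e.g. the odds
    ratio for the Fisher test); NaN when not applicable.
    """

    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]
    exact: bool
    estimate: float = math.nan

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation outcome."""

    rho: float
    p_value: float
    n: int
    exact: bool = False

    def __post_init__(self) -> None:
        if abs(self.rho) > 1 + 1e-12:
            raise ValueError(f"|rho| > 1: {self.rho}")
        if self.n < 3:
            raise ValueError("correlation requires n >= 3")


def format_p(p: float) -> str:
    """Render a p-value for reports; a floored p prints as '< 1e-300'."""
    return "< 1e-300" if p <= P_FLOOR else f"{p:.4g}"


def _floor(p: float) -> float:
    return float(min(1.0, max(p, P_FLOOR)))


def _check_alternative(alternative: str) -> str:
    alt = alternative.replace("-", "_").replace("two.sided", "two_sided")
    if alt == "two sided":
        alt = "two_sided"
    if alt not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}, got {alternative!r}")
    return alt


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _mw_u_distribution(n1: int, n2: int) -> tuple[np.ndarray, int]:
    """Counts of U_x values over all C(n1+n2, n1) tie-free rank subsets."""
    n = n1 + n2
    offset = n1 * (n1 + 1) // 2
    counts = np.zeros(n1 * n2 + 1, dtype=np.int64)
    for combo in itertools.combinations(range(1, n + 1), n1):
        counts[sum(combo) - offset] += 1
    return counts, math.comb(n, n1)


def _mw_exact_p(u_x: float, n1: int, n2: int, alternative: str) -> float:
    counts, total = _mw_u_distribution(n1, n2)
    u = int(round(u_x))
    p_le = counts[: u + 1].sum() / total
    p_ge = counts[u:].sum() / total
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_le, p_ge))


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two_sided",
    continuity: bool = True,
) -> TestResult:
    """Unpaired two-sample Mann–Whitney test on U_x (rank-sum of ``x``).

    ``alternative='greater'`` tests whether ``x`` tends to exceed ``y``.
    Exact enumeration is used for n1+n2 <= 12 without ties; otherwise the
    normal approximation with tie correction and, unless ``continuity``
    is False, a 0.5 continuity correction.
    """
    alt = _check_alternative(alternative)
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size < 1 or ya.size < 1:
        raise ValueError("both samples must contain at least one value")
    n1, n2 = xa.size, ya.size
    pooled = np.concatenate([xa, ya])
    ranks = rankdata(pooled)
    u_x = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if n1 + n2 <= EXACT_MW_MAX_N and not has_ties:
        p = _mw_exact_p(u_x, n1, n2, alt)
        return TestResult(u_x, _floor(p), "mann_whitney", (n1, n2), exact=True)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # every pooled value identical
        return TestResult(u_x, 1.0, "mann_whitney", (n1, n2), exact=False)
    sigma = math.sqrt(sigma2)
    cc = 0.5 if continuity else 0.0

    if alt == "greater":
        z = (u_x - mu - cc) / sigma
        p = norm.sf(z)
    elif alt == "less":
        z = (u_x - mu + cc) / sigma
        p = norm.cdf(z)
    else:
        if u_x == mu:
            p = 1.0
        else:
            z = (abs(u_x - mu) - cc) / sigma
            p = 2.0 * norm.sf(z)
    return TestResult(u_x, _floor(p), "mann_whitney", (n1, n2), exact=False)


# ---------------------------------------------------------------------------
# Kruskal–Wallis and Dunn's post hoc
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal–Wallis H test (tie-corrected) across >= 3 groups."""
    if len(groups) < 3:
        raise ValueError("kruskal_wallis needs >= 3 groups; use mann_whitney for 2")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group must contain at least one value")
    sizes = [a.size for a in arrays]
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float((tie_counts**3 - tie_counts).sum()) / (n**3 - n)
    if correction == 0.0:  # all values identical
        return TestResult(0.0, 1.0, "kruskal_wallis", tuple(sizes), exact=False)
    start = 0
    h = 0.0
    for size in sizes:
        r_sum = ranks[start : start + size].sum()
        h += r_sum**2 / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    h /= correction
    p = chi2.sf(h, len(groups) - 1)
    return TestResult(float(h), _floor(p), "kruskal_wallis", tuple(sizes), exact=False)


def dunn_posthoc(
    groups: Sequence[Sequence[float]], adjust: str = "bonferroni"
) -> list[tuple[tuple[int, int], TestResult]]:
    """Dunn's pairwise z tests on pooled ranks after Kruskal–Wallis.

    Returns one ``((i, j), TestResult)`` per group pair, two-sided, with
    p-values adjusted across all pairs ('bonferroni' default, 'bh'
    available).
    """
    if adjust not in ("bonferroni", "bh"):
        raise ValueError("adjust must be 'bonferroni' or 'bh'")
    if len(groups) < 3:
        raise ValueError("dunn_posthoc needs >= 3 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group must contain at least one value")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float((tie_counts**3 - tie_counts).sum())
    var_base = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))

    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + a.size].mean())
        start += a.size

    pairs = list(itertools.combinations(range(len(arrays)), 2))
    zs, raw = [], []
    for i, j in pairs:
        se2 = var_base * (1.0 / arrays[i].size + 1.0 / arrays[j].size)
        if se2 <= 0:  # complete ties across the board
            zs.append(0.0)
            raw.append(1.0)
            continue
        z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(se2)
        zs.append(z)
        raw.append(2.0 * norm.sf(abs(z)))
    if adjust == "bonferroni":
        adjusted = [min(1.0, p * len(pairs)) for p in raw]
    else:
        adjusted = list(bh_adjust(raw))
    out = []
    for (i, j), z, p_adj in zip(pairs, zs, adjusted):
        out.append(
            (
                (i, j),
                TestResult(
                    float(z),
                    _floor(p_adj),
                    f"dunn_{adjust}",
                    (arrays[i].size, arrays[j].size),
                    exact=False,
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

def fisher_exact(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher exact test on a 2×2 table.

    The two-sided p sums hypergeometric probabilities (margins fixed) of
    every table whose probability does not exceed that of the observed
    table (minimum-likelihood rule).  The odds ratio is reported as the
    estimate (``inf`` and 0 allowed).
    """
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("fisher_exact expects a 2×2 table of non-negative integers")
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if min(r1, a + c, c + d, b + d) == 0 or r1 == n or c1 == n:
        raise UndefinedResultError(
            f"degenerate 2×2 table (zero margin): {[[a, b], [c, d]]}"
        )
    support = np.arange(max(0, c1 - (c + d)), min(r1, c1) + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-9)].sum())
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return TestResult(
        float(odds), _floor(min(1.0, p)), "fisher_exact", (r1, c + d), exact=True,
        estimate=float(odds),
    )


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Tie-aware Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of average ranks.  For n <= 8 without
    ties in either vector, the p-value is exact: the fraction of all n!
    pairings with |rho| >= |observed|.  Otherwise the t approximation
    with n-2 degrees of freedom is used.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must be paired (equal length)")
    n = xa.size
    if n < 3:
        raise UndefinedResultError("spearman requires n >= 3 pairs")
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise ValueError("spearman requires finite values")
    rx = rankdata(xa)
    ry = rankdata(ya)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedResultError("correlation undefined: zero variance in a vector")
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    denom = math.sqrt(float((cx**2).sum() * (cy**2).sum()))
    rho = float((cx * cy).sum() / denom)
    rho = max(-1.0, min(1.0, rho))

    tie_free = len(set(xa.tolist())) == n and len(set(ya.tolist())) == n
    if n <= EXACT_SPEARMAN_MAX_N and tie_free:
        perms = np.array(list(itertools.permutations(range(n))))
        rho_perm = (cy[perms] @ cx) / denom
        p = float((np.abs(rho_perm) >= abs(rho) - 1e-12).mean())
        return CorrelationResult(rho, _floor(p), n, exact=True)

    if 1.0 - rho**2 <= 0:
        return CorrelationResult(rho, P_FLOOR, n, exact=False)
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * t_dist.sf(abs(t), n - 2)
    return CorrelationResult(rho, _floor(p), n, exact=False)


# ---------------------------------------------------------------------------
# Effect sizes and multiplicity
# ---------------------------------------------------------------------------

def fc_between_medians(x_log2: Sequence[float], y_log2: Sequence[float]) -> float:
    """Linear-scale fold-change between group medians of log2 values.

    FC = 2^(median(x) - median(y)); ``x`` is the case group, ``y`` the
    reference.  With log2-scale input this is the ratio of the groups'
    median expression on the linear scale.
    """
    xa = np.asarray(x_log2, dtype=float)
    ya = np.asarray(y_log2, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both groups must be non-empty")
    return float(2.0 ** (np.median(xa) - np.median(ya)))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(ranked, 1.0)
    return out
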