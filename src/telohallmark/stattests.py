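"""Self-contained statistical kernel shared by all pipeline stages.

Exact tests, rank tests, correlation, Benjamini-Hochberg adjustment and
binary logistic regression, each returning a small result record.  Tail
conventions: ``greater`` means the *first* sample (or positive differences)
tends to larger values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

VALID_TAILS = ("two_sided", "greater", "less")

_SCIPY_ALT = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of a 2x2 cross-classification (rows = group, cols = trait)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("cells must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("degenerate table: all cells zero")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    tail: str
    method: str

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.p_value <= 1 + 1e-12):
            raise ValueError(f"p-value out of range: {self.p_value}")


@dataclass
class LogisticFit:
    coefficients: np.ndarray
    std_errors: np.ndarray
    odds_ratios: np.ndarray = field(init=False)
    ci95: np.ndarray = field(init=False)  # (k, 2) on the OR scale
    p_values: np.ndarray | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.std_errors = np.asarray(self.std_errors, dtype=float)
        with np.errstate(over="ignore"):
            self.odds_ratios = np.exp(self.coefficients)
            half = 1.959963984540054 * self.std_errors
            self.ci95 = np.exp(
                np.column_stack([self.coefficients - half, self.coefficients + half])
            )


def _check_tail(tail: str) -> str:
    if tail not in VALID_TAILS:
        raise ValueError(f"tail must be one of {VALID_TAILS}, got {tail!r}")
    return tail


def fisher_exact(table: ContingencyTable2x2, tail: str = "two_sided") -> TestResult:
    """Fisher's exact test on a 2x2 table.

    The two-sided p-value follows the point-probability convention: the sum
    of hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed that of the observed table (relative
    tie tolerance 1e-7).
    """
    _check_tail(tail)
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*np.asarray(table, dtype=int).ravel())
    arr = table.as_array()
    if tail == "two_sided":
        # scipy implements the point-probability method with the same
        # relative tolerance for ties
        res = stats.fisher_exact(arr, alternative="two-sided")
    else:
        res = stats.fisher_exact(arr, alternative=_SCIPY_ALT[tail])
    return TestResult(
        statistic=float(res.statistic),
        p_value=min(float(res.pvalue), 1.0),
        tail=tail,
        method="fisher_exact",
    )


def mann_whitney(
    x: Sequence[float], y: Sequence[float], tail: str = "two_sided"
) -> TestResult:
    """Mann-Whitney U-test of two independent samples.

    Exact p by enumeration when ``len(x)+len(y) <= 12`` and there are no
    ties; otherwise the normal approximation with tie and continuity
    corrections.  ``tail='greater'`` tests whether ``x`` tends larger.
    """
    _check_tail(tail)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (x.size + y.size <= 12) and not has_ties
    res = stats.mannwhitneyu(
        x,
        y,
        alternative=_SCIPY_ALT[tail],
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=min(float(res.pvalue), 1.0),
        tail=tail,
        method="mann_whitney_exact" if exact else "mann_whitney_normal",
    )


def _wilcoxon_exact(w: float, ranks: np.ndarray, tail: str) -> float:
    """Exact signed-rank p by enumerating all 2^n sign patterns.

    Midranks are kept, so tied magnitudes are handled exactly.
    """
    n = ranks.size
    totals = np.zeros(1)
    for r in ranks:
        totals = np.concatenate([totals, totals + r])
    m = totals.size
    eps = 1e-9
    p_ge = np.count_nonzero(totals >= w - eps) / m
    p_le = np.count_nonzero(totals <= w + eps) / m
    if tail == "greater":
        return p_ge
    if tail == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def wilcoxon_signed_rank(
    diffs: Sequence[float], tail: str = "two_sided"
) -> TestResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking.  Exact by sign-pattern
    enumeration for n <= 15 (tied magnitudes allowed), otherwise the normal
    approximation with continuity correction.  W is the positive-rank sum;
    ``tail='greater'`` tests a positive location shift.
    """
    _check_tail(tail)
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("degenerate: all differences zero")
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if d.size <= 15:
        p = _wilcoxon_exact(w, ranks, tail)
        method = "wilcoxon_exact"
    else:
        res = stats.wilcoxon(
            d,
            alternative=_SCIPY_ALT[tail],
            method="approx",
            correction=True,
            zero_method="wilcox",
        )
        # scipy reports min(W+, W-); we report W+ but reuse its p-value,
        # which is tail-consistent because scipy works from the signed d
        p = float(res.pvalue)
        method = "wilcoxon_normal"
    return TestResult(statistic=w, p_value=min(p, 1.0), tail=tail, method=method)


def pearson(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with two-sided p from the t-transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in an input")
    res = stats.pearsonr(x, y)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        tail="two_sided",
        method="pearson",
    )


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def logistic_fit(
    outcome: Sequence[int], covariates: np.ndarray, add_intercept: bool = True
) -> LogisticFit:
    """Binary logistic regression by maximum likelihood (IRLS / Newton).

    Wald 95% CIs on the odds-ratio scale.  Non-convergence, including
    complete separation, is reported through ``converged`` rather than
    raised.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if np.unique(y).size < 2:
        raise ValueError("outcome has a single class")
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    if y.size <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    k = X.shape[1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        converged = bool(res.mle_retvals.get("converged", False))
        se = np.asarray(res.bse, dtype=float)
        if not np.all(np.isfinite(se)) or np.max(np.abs(res.params)) > 1e3:
            converged = False
        return LogisticFit(
            coefficients=np.asarray(res.params),
            std_errors=se,
            p_values=np.asarray(res.pvalues),
            converged=converged,
        )
    except Exception:
        nan = np.full(k, np.nan)
        return LogisticFit(coefficients=nan, std_errors=nan, converged=False)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (used by the test-suite as the second
# route of every dual-route check; kept here so they are importable, but
# the pipeline never calls them)
# ---------------------------------------------------------------------------


def _hypergeom_pmf_table(a: int, r1: int, r2: int, c1: int) -> float:
    n = r1 + r2
    return float(
        stats.hypergeom.pmf(a, n, r1, c1)
    )


def fisher_exact_enumeration(table: ContingencyTable2x2, tail: str = "two_sided") -> float:
    """Brute-force Fisher p by enumerating all tables with fixed margins."""
    _check_tail(tail)
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {k: _hypergeom_pmf_table(k, r1, r2, c1) for k in range(lo, hi + 1)}
    p_obs = probs[a]
    if tail == "greater":
        return min(1.0, sum(v for k, v in probs.items() if k >= a))
    if tail == "less":
        return min(1.0, sum(v for k, v in probs.items() if k <= a))
    tol = 1e-7
    return min(1.0, sum(v for v in probs.values() if v <= p_obs * (1 + tol)))


def mann_whitney_enumeration(x, y, tail: str = "two_sided") -> float:
    """Exact Mann-Whitney p by full enumeration of group assignments."""
    _check_tail(tail)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx = x.size
    u_obs = float(ranks[:nx].sum() - nx * (nx + 1) / 2)
    us = []
    for idx in combinations(range(pooled.size), nx):
        rs = ranks[list(idx)].sum()
        us.append(rs - nx * (nx + 1) / 2)
    us = np.asarray(us)
    eps = 1e-9
    p_ge = np.mean(us >= u_obs - eps)
    p_le = np.mean(us <= u_obs + eps)
    if tail == "greater":
        return float(p_ge)
    if tail == "less":
        return float(p_le)
    return float(min(1.0, 2 * min(p_ge, p_le)))
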