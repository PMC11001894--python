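"""Statistical primitives used throughout the toolkit.

Every test here is implemented from first principles (exact enumeration or
the standard large-sample approximation) rather than delegating to a stats
package, so that each routine can be audited and checked against independent
oracles. Only distribution tail functions (normal, Student t) are taken from
scipy; the chi-square tail needed for Fisher's combined probability test has
a closed form for even degrees of freedom and is computed directly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "fisher_exact_2x2",
    "fisher_combine",
    "bh_adjust",
    "mann_whitney",
    "wilcoxon_signed_rank_one_sample",
    "t_test_unpaired",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    Attributes
    ----------
    statistic : float
        The test statistic (meaning depends on ``method``).
    p_value : float
        Two-sided p value in (0, 1].
    method : str
        Identifier of the procedure that produced the result.
    exact : bool
        True when an exact enumeration (rather than an asymptotic
        approximation) was used.
    """

    statistic: float
    p_value: float
    method: str
    exact: bool


# ---------------------------------------------------------------------------
# Fisher's exact test (2x2)
# ---------------------------------------------------------------------------

def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    The two-sided p value is the sum of hypergeometric point probabilities
    of all tables with the same margins whose probability does not exceed
    that of the observed table (with a small relative tolerance for ties).
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError("table cells must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("Fisher's exact test requires positive margins")
    n = r1 + r2

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    denom = _log_comb(n, c1)
    logp = np.array(
        [_log_comb(r1, x) + _log_comb(r2, c1 - x) - denom for x in range(lo, hi + 1)]
    )
    pmf = np.exp(logp)
    obs = pmf[a - lo]
    p = float(pmf[pmf <= obs * (1.0 + 1e-7)].sum())
    p = min(1.0, max(p, float(obs)))
    # odds ratio of the observed table as the statistic (inf/0 allowed)
    if b * c == 0:
        stat = math.inf if a * d > 0 else 0.0
    else:
        stat = (a * d) / (b * c)
    return TestResult(stat, p, "fisher_exact_2x2", True)


# ---------------------------------------------------------------------------
# Fisher's combined probability test
# ---------------------------------------------------------------------------

def fisher_combine(p_values: Sequence[float]) -> float:
    """Combine independent p values with Fisher's method.

    X2 = -2 * sum(ln p_i) is referred to a chi-square distribution with 2k
    degrees of freedom. For even df the survival function has the closed
    form exp(-x/2) * sum_{i<k} (x/2)^i / i!, evaluated in log space for
    numerical stability. A single p value is returned unchanged.
    """
    p_values = list(p_values)
    if not p_values:
        raise ValueError("need at least one p value")
    for p in p_values:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p values must lie in (0, 1], got {p!r}")
    k = len(p_values)
    if k == 1:
        return float(p_values[0])
    x = -2.0 * sum(math.log(p) for p in p_values)
    half = x / 2.0
    if half == 0.0:
        return 1.0
    # log-sum-exp over the k Poisson-like terms
    log_terms = [i * math.log(half) - math.lgamma(i + 1) for i in range(k)]
    m = max(log_terms)
    log_p = -half + m + math.log(sum(math.exp(t - m) for t in log_terms))
    return float(min(1.0, math.exp(log_p))) if log_p > -745 else 5e-324


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _rank(values: np.ndarray) -> np.ndarray:
    """Midranks (1-based), averaging over ties."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size, dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact by enumeration of all rank assignments when n_x + n_y <= 12 and
    there are no ties; otherwise a normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = _rank(combined)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    has_ties = np.unique(combined).size < combined.size

    if nx + ny <= 12 and not has_ties:
        # exact null distribution of U by enumerating which ranks go to x
        n = nx + ny
        total = 0
        le = 0
        ge = 0
        for idx in itertools.combinations(range(1, n + 1), nx):
            u = sum(idx) - nx * (nx + 1) / 2.0
            total += 1
            le += u <= u_x
            ge += u >= u_x
        p = min(1.0, 2.0 * min(le, ge) / total)
        return TestResult(u_x, p, "mann_whitney", True)

    n = nx + ny
    mean = nx * ny / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0 or u_x == mean:
        return TestResult(u_x, 1.0, "mann_whitney", False)
    z = (abs(u_x - mean) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * float(_sps.norm.sf(max(z, 0.0))))
    return TestResult(u_x, p, "mann_whitney", False)


# ---------------------------------------------------------------------------
# One-sample Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank_one_sample(
    values: Sequence[float], mu0: float = 0.0
) -> TestResult:
    """Two-sided one-sample Wilcoxon signed-rank test against ``mu0``.

    Zero differences are dropped. Exact (distribution of the positive-rank
    sum over all 2^n sign assignments, computed by dynamic programming) when
    n <= 25 with no tied magnitudes; otherwise normal approximation with tie
    correction and continuity correction.
    """
    d = np.asarray(values, dtype=float) - mu0
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    n = d.size
    absd = np.abs(d)
    ranks = _rank(absd)
    w_pos = float(ranks[d > 0].sum())
    has_ties = np.unique(absd).size < n

    if n <= 25 and not has_ties:
        # integer ranks 1..n; DP over achievable positive-rank sums
        max_w = n * (n + 1) // 2
        counts = np.zeros(max_w + 1, dtype=float)
        counts[0] = 1.0
        for r in range(1, n + 1):
            counts[r:] += counts[: max_w + 1 - r]
        total = counts.sum()
        w = int(round(w_pos))
        le = counts[: w + 1].sum()
        ge = counts[w:].sum()
        p = min(1.0, 2.0 * min(le, ge) / total)
        return TestResult(w_pos, p, "wilcoxon_signed_rank", True)

    mean = n * (n + 1) / 4.0
    _, counts = np.unique(absd, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float((counts**3 - counts).sum()) / 48.0
    if var <= 0 or w_pos == mean:
        return TestResult(w_pos, 1.0, "wilcoxon_signed_rank", False)
    z = (abs(w_pos - mean) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * float(_sps.norm.sf(max(z, 0.0))))
    return TestResult(w_pos, p, "wilcoxon_signed_rank", False)


# ---------------------------------------------------------------------------
# Unpaired t test
# ---------------------------------------------------------------------------

def t_test_unpaired(
    x: Sequence[float], y: Sequence[float], welch: bool = False
) -> TestResult:
    """Two-sided unpaired t test (Student pooled-variance; Welch optional)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two observations")
    nx, ny = x.size, y.size
    mx, my = x.mean(), y.mean()
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if welch:
        se2 = vx / nx + vy / ny
        if se2 == 0:
            return TestResult(0.0, 1.0, "t_test_welch", False)
        t = (mx - my) / math.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        method = "t_test_welch"
    else:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        if sp2 == 0:
            if mx == my:
                return TestResult(0.0, 1.0, "t_test_student", False)
            return TestResult(math.copysign(math.inf, mx - my), 5e-324, "t_test_student", False)
        t = (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))
        df = nx + ny - 2
        method = "t_test_student"
    p = min(1.0, 2.0 * float(_sps.t.sf(abs(t), df)))
    return TestResult(float(t), max(p, 5e-324), method, False)
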