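"""Exact small-sample statistics shared by every stage of the pipeline.

All enrichment tests in this package are one-sided (right tail): the
questions asked — is a protein bound more often by efficacious drugs, do two
diseases share more mode-of-action proteins than chance — are questions of
excess, never depletion.  Tail probabilities are clamped to ``P_FLOOR``
before any logarithm downstream so that p-value weights stay finite.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as _sps

from .exceptions import DomainError

#: Smallest p-value the package ever reports; keeps -log(p) finite.
P_FLOOR = 1e-320

#: Storey lambda grid used for pi0 estimation: 0.05, 0.10, ..., 0.95.
STOREY_LAMBDA = np.arange(0.05, 0.951, 0.05)

#: Below this family size the q-value routine falls back to plain BH.
STOREY_MIN_TESTS = 100


def hypergeom_right_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Parameters follow the sampling story: from a population of ``N`` items of
    which ``K`` are marked, draw ``n`` without replacement; ``X`` counts
    marked draws.  Raises :class:`DomainError` on infeasible margins.
    """
    if min(k, K, n, N) < 0:
        raise DomainError(f"negative hypergeometric argument: k={k} K={K} n={n} N={N}")
    if K > N or n > N:
        raise DomainError(f"margins exceed population: K={K}, n={n}, N={N}")
    if k > min(K, n):
        raise DomainError(f"overlap k={k} exceeds min(K={K}, n={n})")
    if k <= 0:
        return 1.0
    p = float(_sps.hypergeom.sf(k - 1, N, K, n))
    return min(1.0, max(p, P_FLOOR))


def hypergeom_right_tail_vec(k, K, n, N) -> np.ndarray:
    """Vectorised :func:`hypergeom_right_tail` (no per-element validation)."""
    k = np.asarray(k, dtype=np.int64)
    p = _sps.hypergeom.sf(k - 1, np.asarray(N), np.asarray(K), np.asarray(n))
    return np.clip(np.where(k <= 0, 1.0, p), P_FLOOR, 1.0)


def fisher_right_tail(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher exact p for a 2x2 table [[a, b], [c, d]].

    Right tail on the top-left cell with all margins fixed; equivalent to
    ``hypergeom_right_tail(a, a+c, a+b, a+b+c+d)``.  The degenerate all-zero
    table returns 1.0.
    """
    if min(a, b, c, d) < 0:
        raise DomainError(f"negative cell in 2x2 table: ({a}, {b}, {c}, {d})")
    N = a + b + c + d
    if N == 0:
        return 1.0
    return hypergeom_right_tail(a, a + c, a + b, N)


def qvalues(p) -> np.ndarray:
    """FDR q-values: Storey's method with a BH fallback.

    pi0 is estimated on the lambda grid 0.05..0.95 with a cubic-polynomial
    smoother evaluated at the largest lambda.  With fewer than
    ``STOREY_MIN_TESTS`` p-values, or when the smoothed estimate leaves
    (0, 1], the routine falls back to Benjamini-Hochberg (pi0 = 1).  The
    output preserves the input order and is monotone in p.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or p.min() < 0.0 or p.max() > 1.0:
        raise DomainError("p-values must lie in [0, 1]")

    m = p.size
    pi0 = 1.0
    if m >= STOREY_MIN_TESTS:
        pi0_lam = np.array([(p > lam).mean() / (1.0 - lam) for lam in STOREY_LAMBDA])
        coeffs = np.polyfit(STOREY_LAMBDA, pi0_lam, deg=3)
        est = float(np.polyval(coeffs, STOREY_LAMBDA[-1]))
        if 0.0 < est <= 1.0:
            pi0 = est

    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q = np.empty(m, dtype=float)
    q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    return np.clip(q, 0.0, 1.0)


def binom_right_tail(n: int, k: int, prob: float) -> float:
    """P(X >= k) for X ~ Binomial(n, prob), by exact term summation."""
    if not 0 <= k <= n:
        raise DomainError(f"threshold k={k} outside 0..{n}")
    if not 0.0 <= prob <= 1.0:
        raise DomainError(f"success probability {prob} outside [0, 1]")
    if k == 0:
        return 1.0
    if n <= 1000:
        total = 0.0
        for j in range(k, n + 1):
            total += math.comb(n, j) * prob**j * (1.0 - prob) ** (n - j)
        return min(1.0, total)
    return float(_sps.binom.sf(k - 1, n, prob))


def normal_right_tail(z: float) -> float:
    """Standard-normal survival function via erfc (relative error < 1e-12)."""
    if not math.isfinite(z):
        raise DomainError("z must be finite")
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson correlation with the two-sided t-test p-value (n-2 dof)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be equal-length 1-d vectors")
    if x.size < 3:
        raise DomainError("need at least 3 observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DomainError("correlation undefined for a constant vector")
    r, p = _sps.pearsonr(x, y)
    return float(r), float(p)
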