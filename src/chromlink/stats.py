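"""Overlap enrichment statistics: hypergeometric tail and Fisher's exact test.

The hypergeometric upper tail P(X >= k) is computed in log space (log-gamma
binomial coefficients with a log-sum-exp reduction), which stays accurate for
populations far beyond what direct factorial summation can handle. The
two-sided Fisher p-value uses the probability-ordering convention: the sum of
the probabilities of all tables (conditional on the margins) no more likely
than the observed one.
"""
from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp

from .models import OverlapTest

_REL_EPS = 1e-7  # tolerance when comparing table probabilities for the two-sided rule


def _log_binom(n, k) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _log_hypergeom_pmf(N: int, K: int, n: int, k: np.ndarray) -> np.ndarray:
    return _log_binom(K, k) + _log_binom(N - K, n - k) - _log_binom(N, n)


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: population size; K: marked items; n: draws; k: observed marked draws.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: N={N}, K={K}, n={n}")
    if k < 0:
        raise ValueError("k must be >= 0")
    k_max = min(K, n)
    if k > k_max:
        return 0.0
    k_min = max(0, n - (N - K))
    if k <= k_min:
        return 1.0
    ks = np.arange(k, k_max + 1)
    return float(min(1.0, np.exp(logsumexp(_log_hypergeom_pmf(N, K, n, ks)))))


def overlap_test(set_a, set_b, universe) -> OverlapTest:
    """Hypergeometric enrichment of the overlap of two gene sets.

    ``set_a`` plays the role of the drawn sample (e.g. differential genes),
    ``set_b`` the marked successes (e.g. factor-bound targets), within the
    expressed-gene ``universe``. One-sided upper tail: the test asks whether
    the overlap is larger than chance.
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    stray = (a | b) - u
    if stray:
        raise ValueError(f"sets contain members outside the universe: {sorted(stray)[:5]}")
    k = len(a & b)
    return OverlapTest(
        population_n=len(u), success_k=len(b), sample_n=len(a), observed=k,
        p_tail=hypergeom_tail(len(u), len(b), len(a), k),
    )


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 table.

    Conditional on the margins, sums P(table') over all tables whose
    probability is <= the observed table's (within a small relative
    tolerance). Degenerate margins give p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("negative cell counts")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    N = a + b + c + d
    row1, col1 = a + b, a + c
    if N == 0 or row1 == 0 or row1 == N or col1 == 0 or col1 == N:
        return 1.0
    k_min = max(0, row1 + col1 - N)
    k_max = min(row1, col1)
    ks = np.arange(k_min, k_max + 1)
    logp = _log_hypergeom_pmf(N, col1, row1, ks)
    log_obs = _log_hypergeom_pmf(N, col1, row1, np.array([a]))[0]
    keep = logp <= log_obs + np.log1p(_REL_EPS)
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))
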