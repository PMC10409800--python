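"""Shared fixtures and independent brute-force oracles.

The oracles deliberately take the dumbest correct path (full domination
matrices, exact binomial-coefficient sums) so they stay independent of the
implementations they check.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from chromlink.config import SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    """A miniature but complete study: 40 genes, 20 peaks, 2 replicates."""
    return SimulationConfig(
        seed=7,
        n_chroms=1,
        chrom_length=20_000_000,
        n_genes=40,
        n_peaks=20,
        frac_de=0.5,
        background_fragments=500,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


# ---------------------------------------------------------------------------
# oracles

def pareto_levels_bruteforce(pts: np.ndarray) -> np.ndarray:
    """O(n^2) non-dominated sorting via a full domination matrix, peeling
    one front at a time."""
    pts = np.asarray(pts, dtype=float)
    n = len(pts)
    x, y = pts[:, 0], pts[:, 1]
    dom = (
        (x[:, None] >= x[None, :]) & (y[:, None] >= y[None, :])
        & ((x[:, None] > x[None, :]) | (y[:, None] > y[None, :]))
    )
    levels = np.zeros(n, dtype=int)
    remaining = np.ones(n, dtype=bool)
    level = 0
    while remaining.any():
        level += 1
        nd = remaining & ~(dom & remaining[:, None]).any(axis=0)
        levels[nd] = level
        remaining &= ~nd
    return levels


def hypergeom_pmf_exact(N: int, K: int, n: int, k: int) -> float:
    """Exact binomial-coefficient ratio (integer arithmetic, then divide)."""
    if k < max(0, n - (N - K)) or k > min(K, n):
        return 0.0
    return math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)


def hypergeom_tail_enumeration(N: int, K: int, n: int, k: int) -> float:
    return sum(hypergeom_pmf_exact(N, K, n, j) for j in range(k, min(K, n) + 1))


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher by explicit enumeration of all tables with the
    observed margins, probability-ordering rule."""
    N, row1, col1 = a + b + c + d, a + b, a + c
    if N == 0 or row1 == 0 or row1 == N or col1 == 0 or col1 == N:
        return 1.0
    p_obs = hypergeom_pmf_exact(N, col1, row1, a)
    total = 0.0
    for k in range(max(0, row1 + col1 - N), min(row1, col1) + 1):
        p = hypergeom_pmf_exact(N, col1, row1, k)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(1.0, total)


def bh_reference(p: np.ndarray) -> np.ndarray:
    """Textbook step-up: adj_(i) = min_{j >= i} p_(j) * m / j, literal loops."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(
            min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0
        )
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def link_bruteforce(peaks: pd.DataFrame, genes, window: int) -> set[tuple[str, str]]:
    """All-pairs scan: (gene, peak) iff peak overlaps [TSS-w, TSS+w)."""
    pairs = set()
    for p in peaks.itertuples(index=False):
        for g in genes:
            if g.chrom != p.chrom:
                continue
            lo, hi = g.tss - window, g.tss + window
            if p.start < hi and p.end > lo:
                pairs.add((g.gene_id, p.peak_id))
    return pairs
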