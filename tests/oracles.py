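"""Independent oracles used by the test suite.

These are deliberately coded without reference to the package internals:
brute-force likelihood, exhaustive simplex grid search, a frequency-based
multi-locus FST estimator, exact permutation enumeration, and closed-form
Dirichlet moments.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

GRID_STEP = 0.005


def product_loglikelihood(q, genotypes, freqs) -> float:
    """Direct product of per-locus genotype probabilities, in log space.

    P(g=0) = (1-m)^2, P(g=1) = 2m(1-m), P(g=2) = m^2 with m the mixture
    frequency; missing loci (negative genotype) skipped.
    """
    total = 0.0
    for l, g in enumerate(genotypes):
        if g < 0:
            continue
        m = sum(q[k] * freqs[k][l] for k in range(len(q)))
        prob = {0: (1 - m) ** 2, 1: 2 * m * (1 - m), 2: m**2}[int(g)]
        total += math.log(prob)
    return total


def simplex_grid(step: float = GRID_STEP) -> np.ndarray:
    """All (a, b, 1-a-b) triples with a, b on a regular lattice."""
    n = round(1.0 / step)
    pts = []
    for i in range(n + 1):
        for j in range(n + 1 - i):
            pts.append((i * step, j * step, (n - i - j) * step))
    return np.asarray(pts)


def grid_search_loglik(genotypes, freqs, step: float = GRID_STEP):
    """Best grid point and its log-likelihood (vectorized product form)."""
    grid = simplex_grid(step)
    freqs = np.asarray(freqs, dtype=float)
    g = np.asarray(genotypes)
    used = g >= 0
    g = g[used].astype(float)
    m = np.clip(grid @ freqs[:, used], 1e-300, 1 - 1e-16)
    ll = np.where(g == 0, 2 * np.log1p(-m), 0.0)
    ll = np.where(g == 1, np.log(2 * m * (1 - m)), ll)
    ll = np.where(g == 2, 2 * np.log(m), ll)
    ll = ll.sum(axis=1)
    best = int(np.argmax(ll))
    return grid[best], float(ll[best])


def fst_from_frequencies(freqs) -> float:
    """Multi-locus moment estimator of FST from population frequencies.

    With K populations drawn around a common ancestral frequency, the
    across-population sample variance s^2 (n-1 denominator) estimates
    F p(1-p) and pbar(1-pbar) + s^2/K estimates p(1-p); the ratio of sums
    over loci estimates F (Weir-Cockerham style, frequencies known).
    """
    freqs = np.asarray(freqs, dtype=float)
    k = freqs.shape[0]
    s2 = freqs.var(axis=0, ddof=1)
    pbar = freqs.mean(axis=0)
    return float(s2.sum() / (pbar * (1 - pbar) + s2 / k).sum())


def exact_permutation_pvalue(xy_a, xy_b) -> tuple[float, float]:
    """Exact permutation p-value of the distance between group means.

    Enumerates every assignment of the pooled points into groups of the
    original sizes; returns (D_obs, p) with p the fraction of assignments
    whose distance is >= D_obs (the identity assignment is included).
    """
    a = np.asarray(xy_a, dtype=float)
    b = np.asarray(xy_b, dtype=float)
    pool = np.vstack([a, b])
    na, n = len(a), len(pool)
    d_obs = math.dist(a.mean(axis=0), b.mean(axis=0))
    count = total = 0
    for pick in combinations(range(n), na):
        mask = np.zeros(n, dtype=bool)
        mask[list(pick)] = True
        d = math.dist(pool[mask].mean(axis=0), pool[~mask].mean(axis=0))
        total += 1
        if d >= d_obs - 1e-12:
            count += 1
    return d_obs, count / total


def dirichlet_mean(alpha) -> np.ndarray:
    alpha = np.asarray(alpha, dtype=float)
    return alpha / alpha.sum()
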