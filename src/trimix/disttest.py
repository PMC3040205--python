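"""Randomization test of the distance between cohort mean-ancestry points.

Each cohort is reduced to the point (mean european, mean african); closure
makes this plane equivalent to the full composition. The statistic is the
Euclidean distance D between two cohorts' points. Its null distribution is
built by pooling the individuals of both cohorts and repeatedly
re-partitioning them at random into groups of the original sizes.

Individuals' (european, african) pairs are permuted jointly: shuffling the
two axes independently would break the simplex constraint and the joint
exchangeability null. An ``independent_axes`` switch exists for sensitivity
analysis only.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from ._rng import subseed, substream

__all__ = [
    "DistanceTestResult",
    "euclidean_distance",
    "randomization_test",
    "bonferroni_threshold",
    "pairwise_matrix",
]

DEFAULT_CYCLES = 10_000


@dataclass
class DistanceTestResult:
    """Outcome of one two-cohort randomization test."""

    cohort_a: str
    cohort_b: str
    D_obs: float
    p_value: float
    n_cycles: int
    seed: int
    alpha_adjusted: float
    significant: bool

    def __post_init__(self) -> None:
        if self.D_obs < 0:
            raise ValueError("distance cannot be negative")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p-value out of (0, 1]: {self.p_value}")
        if self.significant != (self.p_value < self.alpha_adjusted):
            raise ValueError("significance flag inconsistent with p-value and alpha")


def euclidean_distance(p1, p2) -> float:
    """sqrt((X1-X2)^2 + (Y1-Y2)^2)."""
    (x1, y1), (x2, y2) = p1, p2
    return float(np.hypot(x1 - x2, y1 - y2))


def _as_xy(sample) -> np.ndarray:
    """Coerce a sample (AncestryVector list or array-like) to (n, 2) of
    (european, african)."""
    rows = []
    for item in sample:
        q = getattr(item, "q", item)
        q = np.asarray(q, dtype=float)
        rows.append(q[:2])
    return np.asarray(rows, dtype=float).reshape(len(rows), 2)


def randomization_test(
    sample_a,
    sample_b,
    n_cycles: int = DEFAULT_CYCLES,
    seed: int = 0,
    alpha_adjusted: float = 0.05,
    labels: tuple[str, str] = ("A", "B"),
    independent_axes: bool = False,
) -> DistanceTestResult:
    """Monte Carlo permutation test of D between two cohorts' means.

    Each cycle re-partitions the pooled individuals into groups of the
    original sizes and recomputes D. The p-value uses the add-one
    estimator p = (1 + #{D_perm >= D_obs}) / (1 + n_cycles), which is never
    zero and gives a valid test; ties count toward the tail.
    """
    a = _as_xy(sample_a)
    b = _as_xy(sample_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")

    d_obs = euclidean_distance(a.mean(axis=0), b.mean(axis=0))

    pool = np.vstack([a, b])
    na, n = len(a), len(pool)
    rng = substream(seed, "randomization_test")
    exceed = 0
    # Chunked so the permutation index block stays small at large n_cycles.
    chunk = max(1, min(n_cycles, 2_000_000 // max(n, 1)))
    done = 0
    while done < n_cycles:
        c = min(chunk, n_cycles - done)
        idx = rng.permuted(np.tile(np.arange(n), (c, 1)), axis=1)
        if independent_axes:
            idx_y = rng.permuted(np.tile(np.arange(n), (c, 1)), axis=1)
            xa = pool[:, 0][idx[:, :na]].mean(axis=1)
            xb = pool[:, 0][idx[:, na:]].mean(axis=1)
            ya = pool[:, 1][idx_y[:, :na]].mean(axis=1)
            yb = pool[:, 1][idx_y[:, na:]].mean(axis=1)
            d_perm = np.hypot(xa - xb, ya - yb)
        else:
            ga = pool[idx[:, :na]].mean(axis=1)
            gb = pool[idx[:, na:]].mean(axis=1)
            d_perm = np.hypot(ga[:, 0] - gb[:, 0], ga[:, 1] - gb[:, 1])
        # ties count toward the tail; the 1e-12 slack keeps permutations
        # that reproduce the observed split from falling below D_obs by a
        # reordered-summation ulp
        exceed += int(np.sum(d_perm >= d_obs - 1e-12))
        done += c

    p = (1 + exceed) / (1 + n_cycles)
    return DistanceTestResult(
        cohort_a=labels[0],
        cohort_b=labels[1],
        D_obs=d_obs,
        p_value=p,
        n_cycles=n_cycles,
        seed=seed,
        alpha_adjusted=alpha_adjusted,
        significant=p < alpha_adjusted,
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m at full precision (0.05 over six
    comparisons is 0.00833..., conventionally reported as 0.008)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of comparisons must be >= 1, got {m}")
    return alpha / m


def pairwise_matrix(
    cohorts: list[tuple[str, list]],
    n_cycles: int = DEFAULT_CYCLES,
    seed: int = 0,
    alpha: float = 0.05,
    independent_axes: bool = False,
) -> tuple[list[DistanceTestResult], pd.DataFrame]:
    """Test every unordered pair of cohorts.

    Returns the per-pair results plus a square matrix with D above the
    diagonal and p below it. Significance uses the Bonferroni threshold for
    the number of pairs; each pair gets a seed derived from (seed, i, j) so
    a single pair can be re-run in isolation.
    """
    names = [name for name, _ in cohorts]
    if len(names) != len(set(names)):
        raise ValueError("duplicate cohort labels")
    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts")
    n_pairs = len(names) * (len(names) - 1) // 2
    alpha_adj = bonferroni_threshold(alpha, n_pairs)

    results = []
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for i, j in combinations(range(len(cohorts)), 2):
        pair_seed = subseed(seed, "pairwise", i, j)
        res = randomization_test(
            cohorts[i][1],
            cohorts[j][1],
            n_cycles=n_cycles,
            seed=pair_seed,
            alpha_adjusted=alpha_adj,
            labels=(names[i], names[j]),
            independent_axes=independent_axes,
        )
        results.append(res)
        mat.loc[names[i], names[j]] = res.D_obs
        mat.loc[names[j], names[i]] = res.p_value
    return results, mat
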