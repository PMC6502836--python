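"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package: segmentation by exhaustive
dynamic programming, and state-count selection by exhaustive enumeration of
contiguous partitions of sorted segment means.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def exhaustive_change_points(x: np.ndarray) -> np.ndarray:
    """Exact change points of a noiseless piecewise-constant series:
    every position where the value changes."""
    x = np.asarray(x, dtype=float)
    return np.flatnonzero(np.diff(x) != 0) + 1


def exhaustive_segmentation_rss(x: np.ndarray, n_segments: int):
    """Optimal segmentation into ``n_segments`` pieces by exhaustive search.

    Returns (change_points, rss).  Only feasible for short series.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    best = (None, np.inf)
    for cps in combinations(range(1, n), n_segments - 1):
        bounds = (0, *cps, n)
        rss = sum(float(np.sum((x[a:b] - x[a:b].mean()) ** 2))
                  for a, b in zip(bounds[:-1], bounds[1:]))
        if rss < best[1]:
            best = (np.asarray(cps, dtype=int), rss)
    return best


def exhaustive_mdl_k(pool, cost_fn) -> int:
    """State count minimizing ``cost_fn`` over *all* contiguous partitions of
    the sorted segment means (optimal 1-D groupings are contiguous).

    ``pool`` is a fretscape SegmentPool; ``cost_fn(pool, group_means,
    group_of_segment)`` is the description-length function under test.
    """
    order = np.argsort(-pool.means)
    m = pool.n_segments
    best_k, best_cost = None, np.inf
    for n_cuts in range(m):
        for cuts in combinations(range(1, m), n_cuts):
            bounds = (0, *cuts, m)
            group_sorted = np.empty(m, dtype=int)
            means = []
            for g, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
                idx = order[a:b]
                group_sorted[idx] = g
                means.append(np.average(pool.means[idx],
                                        weights=pool.counts[idx]))
            cost = cost_fn(pool, np.asarray(means), group_sorted)
            if cost < best_cost:
                best_cost, best_k = cost, n_cuts + 1
    return best_k
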