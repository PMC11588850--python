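"""Independent oracles used by the test suite.

The graph oracle derives every statistic from integer adjacency-matrix
powers: the number of length-L walks from s to t is (adj**L)[s, t]; the
shortest-path distance is the smallest L with a nonzero count, and at that
L every walk is a simple path, so the count equals the number of shortest
paths.  Nothing here calls networkx or the package's own graph code.
"""

from __future__ import annotations

import numpy as np


def distances_and_counts(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shortest-path distance and path-count matrices from walk counts.

    dist[s, t] = -1 when t is unreachable from s; dist[s, s] = 0.
    """
    n = adj.shape[0]
    adj = adj.astype(object)  # exact integer arithmetic, no overflow
    dist = -np.ones((n, n), dtype=int)
    sigma = np.zeros((n, n), dtype=object)
    np.fill_diagonal(dist, 0)
    np.fill_diagonal(sigma, 1)
    power = np.eye(n, dtype=object)
    for length in range(1, n):
        power = power @ adj
        newly = (dist == -1) & (power > 0)
        dist[newly] = length
        sigma[newly] = power[newly]
    return dist, sigma


def pair_connectivity(adj: np.ndarray) -> float:
    dist, _ = distances_and_counts(adj)
    n = adj.shape[0]
    off = ~np.eye(n, dtype=bool)
    return int(((dist >= 1) & off).sum()) / (n * (n - 1))


def removal_impact(adj: np.ndarray, v: int) -> tuple[float, float]:
    keep = [i for i in range(adj.shape[0]) if i != v]
    f0 = pair_connectivity(adj)
    f1 = pair_connectivity(adj[np.ix_(keep, keep)])
    return f1, 100.0 * (f0 - f1) / f0


def betweenness(adj: np.ndarray) -> np.ndarray:
    """Normalized directed betweenness from the distance/count matrices."""
    n = adj.shape[0]
    dist, sigma = distances_and_counts(adj)
    result = np.zeros(n)
    for v in range(n):
        total = 0.0
        for s in range(n):
            for t in range(n):
                if len({s, t, v}) < 3 or dist[s, t] < 1:
                    continue
                if dist[s, v] >= 0 and dist[v, t] >= 0 and dist[s, v] + dist[v, t] == dist[s, t]:
                    total += (sigma[s, v] * sigma[v, t]) / sigma[s, t]
        result[v] = total / ((n - 1) * (n - 2))
    return result


def through_fraction(adj: np.ndarray, v: int, mode: str) -> float | None:
    """Fraction of shortest s->t paths (s, t != v) passing through v.

    Returns None when no connected ordered pair avoids v.
    """
    n = adj.shape[0]
    dist, sigma = distances_and_counts(adj)
    n_pairs = n_through = 0
    total_paths = through_paths = 0
    for s in range(n):
        for t in range(n):
            if len({s, t, v}) < 3 or dist[s, t] < 1:
                continue
            n_pairs += 1
            total_paths += sigma[s, t]
            if dist[s, v] >= 0 and dist[v, t] >= 0 and dist[s, v] + dist[v, t] == dist[s, t]:
                n_through += 1
                through_paths += sigma[s, v] * sigma[v, t]
    if n_pairs == 0:
        return None
    if mode == "pair":
        return n_through / n_pairs
    return through_paths / total_paths


def random_digraph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    adj = (rng.random((n, n)) < p).astype(int)
    np.fill_diagonal(adj, 0)
    return adj
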