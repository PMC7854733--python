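"""Independent brute-force oracles used only by the tests.

These deliberately avoid the library's code paths: BFS shortest paths
by hand, direct evaluation of the wPLI formula, exhaustive set-partition
enumeration for modularity maximization.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bfs_distances(adj: np.ndarray, src: int) -> list[float]:
    """Unweighted shortest-path lengths from src (inf if unreachable)."""
    n = adj.shape[0]
    dist = [float("inf")] * n
    dist[src] = 0
    queue = deque([src])
    while queue:
        u = queue.popleft()
        for v in range(n):
            if adj[u, v] and dist[v] == float("inf"):
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def global_efficiency_bruteforce(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        d = bfs_distances(adj, i)
        for j in range(n):
            if j != i and d[j] != float("inf"):
                total += 1.0 / d[j]
    return total / (n * (n - 1))


def local_efficiency_bruteforce(adj: np.ndarray) -> float:
    n = adj.shape[0]
    vals = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        k = len(nb)
        if k < 2:
            vals.append(0.0)
            continue
        sub = adj[np.ix_(nb, nb)]
        total = 0.0
        for a in range(k):
            d = bfs_distances(sub, a)
            for b in range(k):
                if b != a and d[b] != float("inf"):
                    total += 1.0 / d[b]
        vals.append(total / (k * (k - 1)))
    return float(np.mean(vals))


def wpli_direct(imag_values: np.ndarray) -> float:
    """Direct evaluation of |E{|Im| sgn(Im)}| / E{|Im|} for one channel
    pair at one bin; imag_values is the per-epoch Im of the
    cross-spectrum."""
    num = abs(np.mean([abs(v) * np.sign(v) for v in imag_values]))
    den = np.mean([abs(v) for v in imag_values])
    return 0.0 if den == 0 else num / den


def set_partitions(n: int):
    """All set partitions of range(n) as label arrays (restricted
    growth strings)."""
    labels = [0] * n

    def rec(i: int, max_label: int):
        if i == n:
            yield np.array(labels)
            return
        for lab in range(max_label + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_label, lab))

    yield from rec(1, 0)


def modularity_onehot(adj: np.ndarray, labels: np.ndarray) -> float:
    """Vectorized Newman modularity via the one-hot module matrix;
    independent of the library's per-module loop."""
    two_m = adj.sum()
    k = labels.max() + 1
    onehot = np.eye(k)[labels]
    e = onehot.T @ adj @ onehot / two_m
    return float(np.trace(e) - (e.sum(axis=1) ** 2).sum())


def best_partition_exhaustive(adj: np.ndarray) -> tuple[np.ndarray, float]:
    best_q, best = -np.inf, None
    for labels in set_partitions(adj.shape[0]):
        q = modularity_onehot(adj, labels)
        if q > best_q:
            best_q, best = q, labels
    return best, best_q
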