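"""Independent brute-force oracles used to validate the implementation.

Each oracle computes its quantity by a different route than the package:
truncated series instead of Padé matrix exponentials, level-by-level path
counting instead of Brandes accumulation, Monte-Carlo walks instead of
linear solves, per-pair Kirchhoff solves instead of the vectorized
pseudo-inverse route, and exhaustive partition search instead of Louvain.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def expm_series(A: np.ndarray, terms: int = 30) -> np.ndarray:
    """Truncated Taylor series of the matrix exponential."""
    A = np.asarray(A, dtype=float)
    out = np.eye(A.shape[0])
    term = np.eye(A.shape[0])
    for k in range(1, terms + 1):
        term = term @ A / k
        out = out + term
    return out


def bfs_distances(A: np.ndarray, source: int) -> np.ndarray:
    n = A.shape[0]
    dist = np.full(n, -1)
    dist[source] = 0
    q = deque([source])
    while q:
        v = q.popleft()
        for u in np.flatnonzero(A[v] > 0):
            if dist[u] < 0:
                dist[u] = dist[v] + 1
                q.append(u)
    return dist


def betweenness_exhaustive(A: np.ndarray) -> np.ndarray:
    """Unnormalized shortest-path betweenness by explicit path counting.

    Shortest-path counts come from the dynamic programme
    g[s][v] = sum of g[s][u] over predecessors u of v on shortest paths,
    and pair-through counts from g_pq(i) = g[p][i] * g[i][q] when
    d(p,i) + d(i,q) == d(p,q).
    """
    n = A.shape[0]
    dist = np.array([bfs_distances(A, s) for s in range(n)])
    counts = np.zeros((n, n))
    for s in range(n):
        counts[s, s] = 1.0
        order = np.argsort(dist[s])
        for v in order:
            if v == s:
                continue
            preds = [u for u in np.flatnonzero(A[v] > 0)
                     if dist[s, u] == dist[s, v] - 1]
            counts[s, v] = sum(counts[s, u] for u in preds)
    bc = np.zeros(n)
    for p, q in itertools.combinations(range(n), 2):
        for i in range(n):
            if i in (p, q):
                continue
            if dist[p, i] + dist[i, q] == dist[p, q]:
                bc[i] += counts[p, i] * counts[i, q] / counts[p, q]
    return bc


def mfpt_monte_carlo(A: np.ndarray, n_walks: int = 20_000,
                     seed: int = 0, max_steps: int = 100_000) -> np.ndarray:
    """Mean first-passage times estimated by simulated random walks.

    H[j, i] is the average number of steps of ``n_walks`` independent walks
    started at j until they first hit i.
    """
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    P = A / A.sum(axis=1, keepdims=True)
    cumP = np.cumsum(P, axis=1)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            pos = np.full(n_walks, j)
            steps = np.zeros(n_walks)
            active = np.arange(n_walks)
            for _ in range(max_steps):
                u = rng.random(len(active))
                nxt = (u[:, None] > cumP[pos[active]]).sum(axis=1)
                pos[active] = nxt
                steps[active] += 1
                active = active[nxt != i]
                if len(active) == 0:
                    break
            H[j, i] = steps.mean()
    return H


def current_flow_betweenness_kirchhoff(A: np.ndarray,
                                       endpoint: float = 1.0) -> np.ndarray:
    """Current-flow betweenness by an explicit Kirchhoff solve per pair.

    For each pair the reduced Laplacian system (grounding the sink) is
    solved directly; interior throughput is half the absolute flow over
    incident edges and each endpoint contributes ``endpoint``.
    """
    n = A.shape[0]
    L = np.diag(A.sum(axis=1)) - A
    total = np.zeros(n)
    for p, q in itertools.combinations(range(n), 2):
        keep = [v for v in range(n) if v != q]
        b = np.zeros(n)
        b[p] = 1.0
        V = np.zeros(n)
        V[keep] = np.linalg.solve(L[np.ix_(keep, keep)], b[keep])
        for i in range(n):
            if i in (p, q):
                total[i] += endpoint
            else:
                total[i] += 0.5 * sum(
                    A[i, j] * abs(V[i] - V[j]) for j in np.flatnonzero(A[i] > 0)
                )
    return total / (0.5 * n * (n - 1))


def _set_partitions(items: list[int]):
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[first] + part[k]] + part[k + 1:]
        yield [[first]] + part


def best_modularity_exhaustive(A: np.ndarray) -> float:
    """Maximum Newman Q over every partition of the node set (tiny n only)."""
    n = A.shape[0]
    two_w = A.sum()
    s = A.sum(axis=1)
    B = A - np.outer(s, s) / two_w
    best = -np.inf
    for part in _set_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for m, block in enumerate(part):
            labels[block] = m
        same = labels[:, None] == labels[None, :]
        best = max(best, B[same].sum() / two_w)
    return float(best)


def random_connected_graph(n: int, p: float, rng: np.random.Generator,
                           max_tries: int = 500) -> np.ndarray:
    """Adjacency of a connected Erdős–Rényi draw (rejection sampling)."""
    for _ in range(max_tries):
        U = rng.random((n, n))
        A = np.triu((U < p).astype(float), 1)
        A = A + A.T
        if (bfs_distances(A, 0) >= 0).all() and A.sum() > 0:
            return A
    raise RuntimeError("no connected draw")
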