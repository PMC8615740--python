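"""Independent brute-force reference implementations used only by tests.

These deliberately mirror the definitions, not the package's optimized code
paths: a full O(N^2) template scan for sample entropy and Floyd-Warshall
shortest-path enumeration with path counting for graph metrics.
"""

from __future__ import annotations

import numpy as np


def sampen_naive(x, m: int = 2, r_factor: float = 0.15, r: float | None = None):
    """O(N^2) sample entropy: strict Chebyshev matching over N-m templates."""
    x = np.asarray(x, float)
    n = len(x)
    if r is None:
        r = r_factor * x.std()
    n_t = n - m
    emb_m = np.lib.stride_tricks.sliding_window_view(x, m)[:n_t]
    emb_m1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:n_t]
    b = a = 0
    for i in range(n_t):
        for j in range(i + 1, n_t):
            if np.abs(emb_m[i] - emb_m[j]).max() < r:
                b += 1
                if np.abs(emb_m1[i] - emb_m1[j]).max() < r:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)


def pearson_rows(M: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of rows, computed pair by pair."""
    n = M.shape[0]
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            xi, xj = M[i] - M[i].mean(), M[j] - M[j].mean()
            W[i, j] = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
    return W


def graph_metrics_bruteforce(W: np.ndarray, tol: float = 1e-9):
    """Degree/strength/density/normalized betweenness by exhaustive search.

    Distances are 1/|w|; shortest paths and their multiplicities come from
    Floyd-Warshall with path counting; betweenness of v sums, over ordered-
    free pairs s<t (s,t != v), the fraction of shortest s-t paths through v,
    normalized by (n-1)(n-2)/2.
    """
    n = W.shape[0]
    adj = np.abs(W) > 0
    degree = adj.sum(axis=1)
    strength = np.abs(W).sum(axis=1)
    n_edges = int(adj[np.triu_indices(n, 1)].sum())
    density = n_edges / (n * (n - 1) / 2)

    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and adj[i, j]:
                D[i, j] = 1.0 / abs(W[i, j])
    dist = D.copy()
    for k in range(n):
        dist = np.minimum(dist, dist[:, k][:, None] + dist[k][None, :])

    # sigma[s, v]: number of shortest s->v paths, by DP in order of distance
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        for v in sorted(range(n), key=lambda v: dist[s, v]):
            if v == s or not np.isfinite(dist[s, v]):
                continue
            for u in range(n):
                if adj[u, v] and abs(dist[s, u] + D[u, v] - dist[s, v]) <= tol:
                    sigma[s, v] += sigma[s, u]

    bc = np.zeros(n)
    for v in range(n):
        total = 0.0
        for s in range(n):
            for t in range(s + 1, n):
                if s == v or t == v or sigma[s, t] == 0:
                    continue
                if abs(dist[s, v] + dist[v, t] - dist[s, t]) <= tol:
                    total += sigma[s, v] * sigma[v, t] / sigma[s, t]
        bc[v] = total / ((n - 1) * (n - 2) / 2)
    return degree, strength, density, bc
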