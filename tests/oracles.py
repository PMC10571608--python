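"""Independent brute-force reference implementations for small graphs.

Deliberately naive and self-contained (no imports from graphpm's metric
code paths): Floyd-Warshall distances, exhaustive simple-path enumeration
for betweenness, direct triangle products for clustering.  Only feasible
for n <= ~8 nodes; used to cross-check the production metrics.
"""

from __future__ import annotations

import itertools

import numpy as np

TIE_RTOL = 1e-12


def lengths_from_weights(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    L = np.full((n, n), np.inf)
    for i in range(n):
        L[i, i] = 0.0
        for j in range(n):
            if i != j and w[i, j] > 0:
                L[i, j] = 1.0 / w[i, j]
    return L


def floyd_warshall(w: np.ndarray) -> np.ndarray:
    d = lengths_from_weights(w).copy()
    n = w.shape[0]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def global_efficiency(w: np.ndarray) -> float:
    d = floyd_warshall(w)
    n = w.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def characteristic_path_length(w: np.ndarray) -> tuple[float, bool]:
    d = floyd_warshall(w)
    n = w.shape[0]
    finite = [d[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i, j])]
    if not finite:
        raise ValueError("no connected pair")
    return float(np.mean(finite)), len(finite) == n * (n - 1)


def nodal_clustering(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n)
    wh = w / wmax
    out = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if w[i, j] > 0)
        if k < 2:
            continue
        s = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    s += (wh[i, j] * wh[i, h] * wh[j, h]) ** (1.0 / 3.0)
        out[i] = s / (k * (k - 1))
    return out


def nodal_local_efficiency(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbr = [j for j in range(n) if w[i, j] > 0]
        if len(nbr) < 2:
            continue
        sub = w[np.ix_(nbr, nbr)]
        out[i] = global_efficiency(sub)
    return out


def _all_simple_paths(w: np.ndarray, s: int, t: int):
    n = w.shape[0]
    stack = [(s, [s], 0.0)]
    while stack:
        node, path, dist = stack.pop()
        if node == t:
            yield path, dist
            continue
        for nxt in range(n):
            if w[node, nxt] > 0 and nxt not in path:
                stack.append((nxt, path + [nxt], dist + 1.0 / w[node, nxt]))


def nodal_betweenness(w: np.ndarray) -> np.ndarray:
    """Exhaustive geodesic enumeration with tie splitting, normalised by
    (n-1)(n-2); each unordered pair contributes once."""
    n = w.shape[0]
    credit = np.zeros(n)
    if n < 3:
        return credit
    for s, t in itertools.combinations(range(n), 2):
        paths = list(_all_simple_paths(w, s, t))
        if not paths:
            continue
        dmin = min(dist for _, dist in paths)
        geodesics = [p for p, dist in paths if dist <= dmin * (1 + TIE_RTOL) + TIE_RTOL]
        for p in geodesics:
            for interior in p[1:-1]:
                credit[interior] += 1.0 / len(geodesics)
    return credit / ((n - 1) * (n - 2))


def mse(observed, predicted) -> float:
    o = np.asarray(observed, float)
    p = np.asarray(predicted, float)
    ok = np.isfinite(o) & np.isfinite(p)
    return float(np.mean((o[ok] - p[ok]) ** 2))


def random_weighted_graph(rng: np.random.Generator, n: int, density: float = 0.5) -> np.ndarray:
    """Symmetric nonnegative weight matrix with continuous weights (ties
    between distinct geodesics have probability zero)."""
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                w[i, j] = w[j, i] = rng.uniform(0.1, 1.0)
    return w
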