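"""Independent brute-force oracles used only by the tests.

Everything here is written for transparency, not speed: exhaustive
enumeration and textbook formulas, deliberately sharing no code with the
package implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def oracle_clustering_onnela(w: np.ndarray) -> np.ndarray:
    """Per-node geometric-mean triangle clustering by direct enumeration."""
    n = w.shape[0]
    w_hat = w / w.max() if w.max() > 0 else w
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        total = 0.0
        for j, h in itertools.combinations(nbrs, 2):
            if w[j, h] > 0:
                total += (w_hat[i, j] * w_hat[i, h] * w_hat[j, h]) ** (1 / 3)
        out[i] = 2 * total / (k * (k - 1))
    return out


def oracle_distances(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by Floyd-Warshall on lengths 1/weight."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def oracle_lp(w: np.ndarray) -> float:
    d = oracle_distances(w)
    n = d.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals)) if vals else float("inf")


def oracle_eglob(w: np.ndarray) -> float:
    d = oracle_distances(w)
    n = d.shape[0]
    total = sum(1.0 / d[i, j] for i in range(n) for j in range(n)
                if i != j and np.isfinite(d[i, j]) and d[i, j] > 0)
    return total / (n * (n - 1))


def oracle_nodal_eff(w: np.ndarray) -> np.ndarray:
    d = oracle_distances(w)
    n = d.shape[0]
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(1.0 / d[i, j] for j in range(n)
                     if j != i and np.isfinite(d[i, j]) and d[i, j] > 0)
        out[i] /= (n - 1)
    return out


def oracle_eloc(w: np.ndarray) -> float:
    n = w.shape[0]
    vals = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        vals[i] = oracle_eglob(sub)
    return float(vals.mean())


def oracle_degree(w: np.ndarray) -> np.ndarray:
    return (w > 0).sum(axis=1)


def oracle_betweenness(w: np.ndarray) -> np.ndarray:
    """Betweenness by exhaustive simple-path enumeration (n <= ~9).

    For each ordered pair, every simple path is enumerated; the shortest
    length (sum of 1/weight) defines the geodesics, and each interior node
    of each geodesic receives 1/(number of geodesics). Each unordered pair
    is counted once.
    """
    n = w.shape[0]
    out = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = []

            def extend(node, visited, length):
                if node == t:
                    paths.append((length, tuple(visited)))
                    return
                for nxt in range(n):
                    if w[node, nxt] > 0 and nxt not in visited:
                        extend(nxt, visited + [nxt], length + 1.0 / w[node, nxt])

            extend(s, [s], 0.0)
            if not paths:
                continue
            best = min(p[0] for p in paths)
            geodesics = [p[1] for p in paths if p[0] <= best + 1e-12]
            for path in geodesics:
                for node in path[1:-1]:
                    out[node] += 1.0 / len(geodesics)
    return out


def oracle_auc(y, s) -> float:
    total = 0.0
    for k in range(len(y) - 1):
        total += (y[k] + y[k + 1]) * (s[k + 1] - s[k]) / 2.0
    return total


def exact_permutation_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-tailed permutation p by full enumeration of group splits."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    observed = abs(a.mean() - b.mean())
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), na):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        diff = abs(pooled[mask].mean() - pooled[~mask].mean())
        total += 1
        if diff >= observed - 1e-12:
            count += 1
    return count / total


def bh_by_hand(p: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up applied literally to its definition."""
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def union_find_components(n: int, edges: list[tuple[int, int]]
                          ) -> list[tuple[set, int]]:
    """(node set, edge count) per connected component with >= 1 edge."""
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        parent[find(i)] = find(j)
    comps: dict[int, set] = {}
    counts: dict[int, int] = {}
    for i, j in edges:
        root = find(i)
        comps.setdefault(root, set()).update((i, j))
        counts[root] = counts.get(root, 0) + 1
    return [(comps[r], counts[r]) for r in comps]


def random_weighted_graph(n: int, p_edge: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Symmetric nonnegative weight matrix with zero diagonal."""
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                w[i, j] = w[j, i] = rng.uniform(0.05, 1.0)
    return w
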