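"""Independent brute-force oracles used to validate graph measures.

Everything here is implemented with explicit loops and exhaustive
enumeration, deliberately avoiding the vectorized / library-backed code
paths of the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

INF = math.inf


def edge_lengths(m: np.ndarray, mode: str) -> np.ndarray:
    n = len(m)
    out = np.full((n, n), INF)
    for i in range(n):
        for j in range(n):
            if i != j and m[i, j] > 0:
                out[i, j] = 1.0 if mode == "binary" else 1.0 / m[i, j]
    return out


def floyd_warshall(m: np.ndarray, mode: str = "binary") -> np.ndarray:
    d = edge_lengths(m, mode)
    n = len(m)
    for i in range(n):
        d[i, i] = 0.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def triangle_clustering(a: np.ndarray) -> np.ndarray:
    """Per-node clustering by exhaustive triangle enumeration."""
    n = len(a)
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        closed = sum(1 for j, h in itertools.permutations(nbrs, 2) if a[j, h] > 0)
        out[i] = closed / (k * (k - 1))
    return out


def weighted_clustering(w: np.ndarray) -> np.ndarray:
    """Direct triple-loop evaluation of the cube-root triangle intensity."""
    n = len(w)
    mx = w.max()
    wn = w / mx if mx > 0 else w
    out = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if w[i, j] > 0)
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and h != j:
                    total += (wn[i, j] * wn[i, h] * wn[j, h]) ** (1.0 / 3.0)
        out[i] = 0.5 * total / (0.5 * k * (k - 1))
    return out


def transitivity(m: np.ndarray, mode: str = "binary") -> float:
    n = len(m)
    a = (m > 0).astype(float)
    mx = m.max()
    wn = m / mx if mx > 0 else m
    num = 0.0
    den = 0.0
    for i in range(n):
        k = a[i].sum()
        den += k * (k - 1)
        for j in range(n):
            for h in range(n):
                if len({i, j, h}) == 3:
                    if mode == "binary":
                        num += a[i, j] * a[i, h] * a[j, h]
                    else:
                        num += (wn[i, j] * wn[i, h] * wn[j, h]) ** (1.0 / 3.0)
    return num / den if den > 0 else 0.0


def _all_shortest_paths(m: np.ndarray, mode: str, h: int, j: int, d: np.ndarray) -> list[tuple]:
    """Exhaustive enumeration of all shortest simple paths from h to j."""
    lengths = edge_lengths(m, mode)
    target = d[h, j]
    paths: list[tuple] = []

    def extend(path: list[int], cur: float) -> None:
        u = path[-1]
        if u == j:
            if abs(cur - target) < 1e-9:
                paths.append(tuple(path))
            return
        for v in range(len(m)):
            if lengths[u, v] < INF and v not in path:
                if cur + lengths[u, v] + d[v, j] <= target + 1e-9:
                    extend(path + [v], cur + lengths[u, v])

    if np.isfinite(target):
        extend([h], 0.0)
    return paths


def betweenness(m: np.ndarray, mode: str = "binary") -> np.ndarray:
    """Normalized betweenness via exhaustive shortest-path enumeration."""
    n = len(m)
    d = floyd_warshall(m, mode)
    b = np.zeros(n)
    for h in range(n):
        for j in range(n):
            if h == j or not np.isfinite(d[h, j]):
                continue
            paths = _all_shortest_paths(m, mode, h, j, d)
            rho = len(paths)
            if rho == 0:
                continue
            for i in range(n):
                if i in (h, j):
                    continue
                through = sum(1 for p in paths if i in p)
                b[i] += through / rho
    return b / ((n - 1) * (n - 2))


def closeness(m: np.ndarray, mode: str = "binary") -> np.ndarray:
    """Literal double sum with subgraph shortest paths."""
    n = len(m)
    a = (m > 0).astype(float)
    out = np.zeros(n)
    for i in range(n):
        nbrs = [v for v in range(n) if a[i, v] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        sub = m[np.ix_(nbrs, nbrs)]
        d = floyd_warshall(sub, mode)
        total = 0.0
        for jx, j in enumerate(nbrs):
            for hx, hh in enumerate(nbrs):
                if j == hh:
                    continue
                inv = 1.0 / d[jx, hx] if np.isfinite(d[jx, hx]) and d[jx, hx] > 0 else 0.0
                if mode == "binary":
                    total += a[i, j] * a[i, hh] * inv
                else:
                    total += (m[i, j] * m[i, hh] * inv) ** (1.0 / 3.0)
        out[i] = total / (k * (k - 1))
    return out


def char_path_length(m: np.ndarray, mode: str = "binary") -> float:
    d = floyd_warshall(m, mode)
    vals = [d[i, j] for i in range(len(m)) for j in range(len(m))
            if i != j and np.isfinite(d[i, j])]
    return sum(vals) / len(vals)


def assortativity_bin(a: np.ndarray) -> float:
    """Pearson correlation over endpoint degrees counted in both directions."""
    n = len(a)
    deg = a.sum(axis=1)
    xs, ys = [], []
    for i in range(n):
        for j in range(n):
            if i != j and a[i, j] > 0:
                xs.append(deg[i])
                ys.append(deg[j])
    return float(np.corrcoef(xs, ys)[0, 1])


def assortativity_wei(w: np.ndarray) -> float:
    """w_ij-weighted correlation of endpoint strengths (explicit loops)."""
    n = len(w)
    s = w.sum(axis=1)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if w[i, j] > 0]
    wt = sum(w[i, j] for i, j in pairs)
    exy = sum(w[i, j] * s[i] * s[j] for i, j in pairs) / wt
    ex = sum(w[i, j] * (s[i] + s[j]) / 2 for i, j in pairs) / wt
    ex2 = sum(w[i, j] * (s[i] ** 2 + s[j] ** 2) / 2 for i, j in pairs) / wt
    return (exy - ex**2) / (ex2 - ex**2)


def rich_club_phi(a: np.ndarray) -> dict[int, float]:
    """Strip-and-count re-evaluation of phi(k)."""
    deg = a.sum(axis=1)
    out = {}
    for k in range(int(deg.max())):
        keep = [i for i in range(len(a)) if deg[i] > k]
        if len(keep) < 2:
            break
        e = sum(a[i, j] for ix, i in enumerate(keep) for j in keep[ix + 1:])
        out[k] = 2.0 * e / (len(keep) * (len(keep) - 1))
    return out


def k_core(a: np.ndarray, k: int) -> set[int]:
    """Iterative pruning."""
    alive = set(range(len(a)))
    changed = True
    while changed:
        changed = False
        for i in list(alive):
            deg = sum(1 for j in alive if j != i and a[i, j] > 0)
            if deg < k:
                alive.discard(i)
                changed = True
    return alive


def modularity(w: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Double-loop evaluation of Q(gamma)."""
    n = len(w)
    m2 = w.sum()
    k = w.sum(axis=1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += w[i, j] - gamma * k[i] * k[j] / m2
    return q / m2


def random_connected_graph(rng: np.random.Generator, n_min: int = 4, n_max: int = 7,
                           weighted: bool = False) -> np.ndarray:
    """ER graph, redrawn until connected; optionally with random weights."""
    from scipy.sparse.csgraph import connected_components

    while True:
        n = int(rng.integers(n_min, n_max + 1))
        p = rng.uniform(0.35, 0.8)
        tri = np.triu(rng.random((n, n)) < p, 1)
        a = (tri | tri.T).astype(float)
        if a.sum(axis=1).min() >= 1 and connected_components(a, directed=False)[0] == 1:
            break
    if weighted:
        wvals = np.triu(rng.uniform(0.5, 3.0, (n, n)), 1)
        w = a * (wvals + wvals.T)
        return (w + w.T) / 2
    return a
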