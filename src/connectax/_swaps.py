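"""Degree-preserving double-edge swaps on (possibly weighted) matrices."""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


def is_connected(adjacency: np.ndarray) -> bool:
    n_comp, _ = connected_components(csr_matrix(adjacency), directed=False)
    return n_comp == 1


def edge_swap(
    weights: np.ndarray,
    n_swaps: int,
    rng: np.random.Generator,
    max_attempt_factor: int = 50,
) -> tuple[np.ndarray, int]:
    """Perform up to ``n_swaps`` successful degree-preserving swaps.

    Each swap picks two edges (a,b), (c,d) with four distinct endpoints and
    rewires them to (a,d), (c,b) when neither target edge exists, carrying
    edge weights along.  Keeps the graph simple and every node's binary
    degree exact.  Returns the rewired matrix and the number of successful
    swaps.
    """
    w = weights.copy()
    ii, jj = np.triu_indices_from(w, k=1)
    present = w[ii, jj] > 0
    edges = np.stack([ii[present], jj[present]], axis=1)
    n_edges = len(edges)
    if n_edges < 2 or n_swaps <= 0:
        return w, 0
    done = 0
    attempts = 0
    cap = max_attempt_factor * max(n_swaps, 1)
    while done < n_swaps and attempts < cap:
        attempts += 1
        e1, e2 = rng.integers(n_edges, size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        if len({int(a), int(b), int(c), int(d)}) < 4:
            continue
        if w[a, d] != 0 or w[c, b] != 0:
            continue
        wab, wcd = w[a, b], w[c, d]
        w[a, b] = w[b, a] = 0.0
        w[c, d] = w[d, c] = 0.0
        w[a, d] = w[d, a] = wab
        w[c, b] = w[b, c] = wcd
        edges[e1] = (a, d)
        edges[e2] = (c, b)
        done += 1
    return w, done
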