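"""Binary and weighted graph measures and multiscale feature vectors.

Local measures (per node): degree/strength, clustering, betweenness,
closeness.  Global measures: characteristic path length, transitivity,
assortativity.  The full feature vector holds the mean and SD of each local
measure plus the global scalars: 8 + 8 + 3 + 3 = 22 entries.

Weighted path-based measures map weight to length via f(w) = 1/w.  Weighted
clustering and transitivity first rescale weights to [0, 1] by the global
maximum weight.  Closeness follows the neighbourhood-restricted inverse-
distance form verbatim (see each docstring).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from connectax.io import Connectome, binarize

logger = logging.getLogger("connectax.features")

#: canonical ordering of the 22 entries of the full feature vector
FEATURE_NAMES: list[str] = [
    "degree_bin_mean", "degree_bin_sd",
    "clustering_bin_mean", "clustering_bin_sd",
    "betweenness_bin_mean", "betweenness_bin_sd",
    "closeness_bin_mean", "closeness_bin_sd",
    "strength_wei_mean", "strength_wei_sd",
    "clustering_wei_mean", "clustering_wei_sd",
    "betweenness_wei_mean", "betweenness_wei_sd",
    "closeness_wei_mean", "closeness_wei_sd",
    "char_path_bin", "transitivity_bin", "assortativity_bin",
    "char_path_wei", "transitivity_wei", "assortativity_wei",
]

_SCALE = np.array(["local"] * 16 + ["global"] * 6, dtype=object)
_KIND = np.array(["binary"] * 8 + ["weighted"] * 8 + ["binary"] * 3 + ["weighted"] * 3, dtype=object)

SUBSETS = {
    "all", "local", "global", "binary", "weighted",
    "local-binary", "local-weighted", "global-binary", "global-weighted",
}


def subset_mask(subset: str = "all") -> np.ndarray:
    """Boolean mask over the 22 canonical features for a named subset.

    ``subset`` is one of ``all | local | global | binary | weighted`` or a
    hyphenated combination such as ``local-binary``.  Order of retained
    entries always follows :data:`FEATURE_NAMES`.
    """
    if subset not in SUBSETS:
        raise ValueError(f"unknown subset {subset!r}; choose from {sorted(SUBSETS)}")
    mask = np.ones(len(FEATURE_NAMES), dtype=bool)
    for part in subset.split("-"):
        if part == "all":
            continue
        if part in ("local", "global"):
            mask &= _SCALE == part
        else:
            mask &= _KIND == part
    return mask


# ---------------------------------------------------------------------------
# local measures
# ---------------------------------------------------------------------------

def degree_bin(adjacency: np.ndarray) -> np.ndarray:
    """k_i: number of connections of each node."""
    return np.asarray(adjacency, dtype=float).sum(axis=1)


def strength_wei(weights: np.ndarray) -> np.ndarray:
    """s_i: sum of connection weights of each node."""
    return np.asarray(weights, dtype=float).sum(axis=1)


def clustering_bin(adjacency: np.ndarray) -> np.ndarray:
    """c_i(A) = (A^3)_ii / (k_i (k_i - 1)); 0 where k_i < 2."""
    a = np.asarray(adjacency, dtype=float)
    k = a.sum(axis=1)
    tri = np.diagonal(a @ a @ a)
    denom = k * (k - 1)
    out = np.zeros_like(k)
    ok = denom > 0
    out[ok] = tri[ok] / denom[ok]
    return out


def clustering_wei(weights: np.ndarray) -> np.ndarray:
    """c_i(W) with cube-rooted, max-normalized weights; 0 where k_i < 2."""
    w = np.asarray(weights, dtype=float)
    mx = w.max()
    if mx > 0:
        w = w / mx
    k = degree_bin(binarize(w))
    cw = np.cbrt(w)
    tri = np.diagonal(cw @ cw @ cw)
    denom = k * (k - 1)
    out = np.zeros_like(k)
    ok = denom > 0
    out[ok] = tri[ok] / denom[ok]
    return out


def _length_matrix(weights: np.ndarray) -> np.ndarray:
    """Edge lengths f(w) = 1/w on existing edges, 0 (absent) elsewhere."""
    w = np.asarray(weights, dtype=float)
    lengths = np.zeros_like(w)
    nz = w > 0
    lengths[nz] = 1.0 / w[nz]
    return lengths


def shortest_paths(matrix: np.ndarray, mode: str = "binary") -> np.ndarray:
    """All-pairs shortest path lengths; inf for disconnected pairs.

    ``binary`` uses hop counts on the binarized matrix; ``weighted`` runs
    Dijkstra on lengths 1/w.
    """
    m = np.asarray(matrix, dtype=float)
    if mode == "binary":
        return _csgraph_shortest_path(csr_matrix(binarize(m)), method="D",
                                      directed=False, unweighted=True)
    if mode == "weighted":
        return _csgraph_shortest_path(csr_matrix(_length_matrix(m)), method="D", directed=False)
    raise ValueError(f"mode must be 'binary' or 'weighted', got {mode!r}")


def _igraph_from(matrix: np.ndarray, mode: str) -> tuple[ig.Graph, list[float] | None]:
    m = np.asarray(matrix, dtype=float)
    srcs, dsts = np.nonzero(np.triu(m, 1))
    g = ig.Graph(n=m.shape[0], edges=list(zip(srcs.tolist(), dsts.tolist())))
    if mode == "binary":
        return g, None
    return g, (1.0 / m[srcs, dsts]).tolist()


def betweenness(matrix: np.ndarray, mode: str = "binary") -> np.ndarray:
    """b_i: shortest-path betweenness, normalized by 1/((n-1)(n-2)).

    The sum runs over ordered node pairs h != j (both excluding i), i.e.
    twice the unordered count.
    """
    n = matrix.shape[0]
    if n < 3:
        return np.zeros(n)
    g, lengths = _igraph_from(matrix, mode)
    raw = np.array(g.betweenness(weights=lengths), dtype=float)
    return 2.0 * raw / ((n - 1) * (n - 2))


def closeness(matrix: np.ndarray, mode: str = "binary") -> np.ndarray:
    """Neighbourhood-restricted closeness e_i.

    For each node i with degree k_i >= 2, distances d_jh(N_i) are shortest
    paths computed on the subgraph induced by i's neighbours.  Binary:
    e_i = sum_{j != h in N_i} [d_jh(N_i)]^-1 / (k_i (k_i - 1)).  Weighted:
    the summand is (w_ij w_ih [d^w_jh(N_i)]^-1)^(1/3), with raw weights and
    inverse-weight path lengths.  Infinite distances contribute 0; nodes
    with k_i < 2 score 0.
    """
    m = np.asarray(matrix, dtype=float)
    a = binarize(m)
    n = m.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        k = len(nbrs)
        if k < 2:
            continue
        sub = m[np.ix_(nbrs, nbrs)]
        d = shortest_paths(sub, mode=mode)
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
        np.fill_diagonal(inv, 0.0)
        if mode == "binary":
            total = inv.sum()
        else:
            wij = m[i, nbrs]
            prod = np.outer(wij, wij) * inv
            total = np.cbrt(prod).sum()
        out[i] = total / (k * (k - 1))
    return out


# ---------------------------------------------------------------------------
# global measures
# ---------------------------------------------------------------------------

def char_path_length(matrix: np.ndarray, mode: str = "binary") -> float:
    """L: mean shortest path length over ordered node pairs (finite only)."""
    d = shortest_paths(matrix, mode=mode)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = d[off]
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("no finite off-diagonal distances")
    if not finite.all():
        logger.warning("disconnected pairs excluded from characteristic path length")
    return float(vals[finite].mean())


def transitivity(matrix: np.ndarray, mode: str = "binary") -> float:
    """T: ratio of closed triangles to potential triangles.

    Weighted mode uses cube-rooted, max-normalized weights in the numerator
    with binary degrees in the denominator.
    """
    m = np.asarray(matrix, dtype=float)
    k = degree_bin(binarize(m))
    denom = (k * (k - 1)).sum()
    if denom == 0:
        warnings.warn("transitivity undefined (no node with degree >= 2); returning 0")
        return 0.0
    if mode == "binary":
        a = binarize(m)
        num = np.trace(a @ a @ a)
    elif mode == "weighted":
        mx = m.max()
        cw = np.cbrt(m / mx) if mx > 0 else m
        num = np.trace(cw @ cw @ cw)
    else:
        raise ValueError(f"mode must be 'binary' or 'weighted', got {mode!r}")
    return float(num / denom)


def assortativity(matrix: np.ndarray, mode: str = "binary") -> float:
    """Degree (or strength) assortativity over the edge list.

    Binary: correlation of endpoint degrees (k_i, k_j) across links.
    Weighted: same correlation over endpoint strengths with each link's
    terms weighted by w_ij and sums normalized by the total link weight
    (which reduces to the link count, and hence the binary formula, when
    all weights are 1).  Regular graphs (zero variance) return NaN.
    """
    m = np.asarray(matrix, dtype=float)
    a = binarize(m)
    srcs, dsts = np.nonzero(np.triu(a, 1))
    n_links = len(srcs)
    if n_links < 2:
        raise ValueError("assortativity needs at least 2 links")
    if mode == "binary":
        x, y = degree_bin(a)[srcs], degree_bin(a)[dsts]
        w = np.ones(n_links)
    elif mode == "weighted":
        s = strength_wei(m)
        x, y = s[srcs], s[dsts]
        w = m[srcs, dsts]
    else:
        raise ValueError(f"mode must be 'binary' or 'weighted', got {mode!r}")
    inv_l = 1.0 / w.sum()
    num = inv_l * (w * x * y).sum() - (inv_l * (w * (x + y) / 2.0).sum()) ** 2
    den = inv_l * (w * (x**2 + y**2) / 2.0).sum() - (inv_l * (w * (x + y) / 2.0).sum()) ** 2
    if den <= 0 or not np.isfinite(den):
        warnings.warn("assortativity undefined (degree-regular graph); returning NaN")
        return float("nan")
    return float(num / den)


# ---------------------------------------------------------------------------
# feature vector assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    """A (possibly subset) multiscale feature vector for one connectome."""

    values: np.ndarray
    names: list[str]
    subset: str = "all"

    def __len__(self) -> int:
        return len(self.values)


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    return float(np.mean(x)), float(np.std(x))


def feature_vector(conn: Connectome, subset: str = "all") -> FeatureVector:
    """Assemble the 22-entry multiscale feature vector (then apply subset).

    Local measures contribute their mean and population SD.  An undefined
    assortativity (regular graph) is imputed as 0 so downstream cosine
    distances stay defined.
    """
    a = conn.adjacency
    w = conn.weights
    vals = []
    for x in (degree_bin(a), clustering_bin(a), betweenness(a, "binary"), closeness(a, "binary")):
        vals.extend(_mean_sd(x))
    for x in (strength_wei(w), clustering_wei(w), betweenness(w, "weighted"),
              closeness(w, "weighted")):
        vals.extend(_mean_sd(x))
    for mode, mat in (("binary", a), ("weighted", w)):
        r = assortativity(mat, mode)
        vals.extend([
            char_path_length(mat, mode),
            transitivity(mat, mode),
            0.0 if np.isnan(r) else r,
        ])
    # reorder: the loop above appended [Lb, Tb, rb, Lw, Tw, rw] after locals
    full = np.array(vals, dtype=float)
    mask = subset_mask(subset)
    names = [n for n, m in zip(FEATURE_NAMES, mask) if m]
    return FeatureVector(values=full[mask], names=names, subset=subset)
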