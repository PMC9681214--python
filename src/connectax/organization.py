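"""Conserved global organization: small-worldness, communities, rich clubs,
and four-way edge classification with per-order proportion summaries."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from connectax._swaps import edge_swap, is_connected
from connectax.features import char_path_length, clustering_bin, degree_bin
from connectax.io import Connectome, Dataset, binarize

logger = logging.getLogger("connectax.organization")

EDGE_AXES = ("modular", "hemispheric", "length", "richclub")
AXIS_LABELS = {
    "modular": ("intra", "inter"),
    "hemispheric": ("intra", "inter"),
    "length": ("short", "medium", "long"),
    "richclub": ("rich-club", "feeder", "peripheral"),
}


@dataclass
class SmallWorldResult:
    gamma: float  # C / C_rand
    lam: float    # L / L_rand
    s: float      # gamma / lam
    c: float
    l: float
    c_rand: float
    l_rand: float
    n_null: int


@dataclass
class Partition:
    """A consensus community partition with its modularity score."""

    labels: np.ndarray  # contiguous community ids from 0
    q_value: float
    gamma_res: float
    n_runs: int

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1


@dataclass
class RichClubProfile:
    k_levels: np.ndarray
    phi: np.ndarray
    phi_norm: np.ndarray
    p_values: np.ndarray
    n_null: int
    selected_k: int | None
    rich_nodes: set[int] = field(default_factory=set)
    hub_threshold: float = 0.0


@dataclass
class EdgeClassification:
    """Per-edge labels on the four classification axes."""

    edges: pd.DataFrame  # columns: i, j, modular, hemispheric, length, richclub

    def proportions(self, axis: str) -> dict[str, float]:
        if axis not in EDGE_AXES:
            raise ValueError(f"axis must be one of {EDGE_AXES}")
        counts = self.edges[axis].value_counts()
        total = len(self.edges)
        return {lab: counts.get(lab, 0) / total for lab in AXIS_LABELS[axis]}


# ---------------------------------------------------------------------------
# null models & small-worldness
# ---------------------------------------------------------------------------

def rewire_null(
    adjacency: np.ndarray,
    n_swaps_per_edge: int = 10,
    seed: int | np.random.Generator | None = None,
    require_connected: bool = True,
    max_retries: int = 20,
) -> np.ndarray:
    """Degree-preserving randomization via repeated double-edge swaps.

    Attempts ``n_swaps_per_edge * E`` successful swaps; if the result must be
    connected the whole rewiring is retried (bounded) until it is.
    """
    a = binarize(adjacency)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = a.shape[0]
    n_edges = int(a.sum() / 2)
    if n_edges == n * (n - 1) // 2:
        return a.copy()  # complete graph: degree sequence admits no rewiring
    target = n_swaps_per_edge * n_edges
    for _ in range(max_retries):
        b, done = edge_swap(a, target, rng)
        if done == 0 and target > 0:
            raise RuntimeError("rewiring stalled: no feasible swaps")
        if not require_connected or is_connected(b):
            return b
    raise RuntimeError("could not produce a connected rewired graph")


def small_worldness(
    conn: Connectome | np.ndarray, n_null: int = 1000, seed: int | None = None
) -> SmallWorldResult:
    """Small-world index S = gamma / lambda against degree-preserving nulls.

    C is the mean binary clustering coefficient, L the binary characteristic
    path length; C_rand and L_rand are ensemble means over ``n_null``
    rewired graphs.
    """
    a = conn.adjacency if isinstance(conn, Connectome) else binarize(conn)
    rng = np.random.default_rng(seed)
    c = float(clustering_bin(a).mean())
    l = char_path_length(a, "binary")
    cs, ls = [], []
    for _ in range(n_null):
        b = rewire_null(a, seed=rng)
        cs.append(clustering_bin(b).mean())
        ls.append(char_path_length(b, "binary"))
    c_rand = float(np.mean(cs))
    l_rand = float(np.mean(ls))
    gamma = c / c_rand
    lam = l / l_rand
    return SmallWorldResult(
        gamma=gamma, lam=lam, s=gamma / lam, c=c, l=l,
        c_rand=c_rand, l_rand=l_rand, n_null=n_null,
    )


# ---------------------------------------------------------------------------
# community detection
# ---------------------------------------------------------------------------

def modularity(weights: np.ndarray, labels: np.ndarray, gamma_res: float = 1.0) -> float:
    """Q(gamma) = 1/2m sum_ij [W_ij - gamma k_i k_j / 2m] delta(c_i, c_j)."""
    w = np.asarray(weights, dtype=float)
    labels = np.asarray(labels)
    m2 = w.sum()
    if m2 == 0:
        raise ValueError("empty graph has no modularity")
    k = w.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    b = w - gamma_res * np.outer(k, k) / m2
    return float(b[same].sum() / m2)


def _louvain_labels(g: nx.Graph, gamma_res: float, seed: int) -> np.ndarray:
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=gamma_res, seed=int(seed)
    )
    labels = np.empty(g.number_of_nodes(), dtype=int)
    for c_id, nodes in enumerate(comms):
        for v in nodes:
            labels[v] = c_id
    return labels


def _agreement(parts: list[np.ndarray]) -> np.ndarray:
    n = len(parts[0])
    acc = np.zeros((n, n))
    for p in parts:
        acc += p[:, None] == p[None, :]
    return acc / len(parts)


def _null_agreement(parts: list[np.ndarray]) -> float:
    """Expected co-assignment of two distinct nodes under label permutation."""
    n = len(parts[0])
    probs = []
    for p in parts:
        _, sizes = np.unique(p, return_counts=True)
        probs.append((sizes * (sizes - 1)).sum() / (n * (n - 1)))
    return float(np.mean(probs))


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Canonical contiguous ids by first occurrence, so label-permuted
    versions of the same partition compare equal."""
    seen: dict = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        out[i] = seen.setdefault(lab, len(seen))
    return out


def louvain_consensus(
    conn: Connectome | np.ndarray,
    gamma_res: float = 1.0,
    n_runs: int = 250,
    seed: int | None = None,
    use_weights: bool = True,
    max_consensus_iter: int = 50,
) -> Partition:
    """Consensus partition over ``n_runs`` Louvain maximizations of Q(gamma).

    The node-pair agreement matrix is thresholded at its permutation-null
    level and re-clustered until all runs coincide.  The returned Q is the
    direct evaluation of Q(gamma) on the original matrix.
    """
    w = conn.weights if isinstance(conn, Connectome) else np.asarray(conn, dtype=float)
    if not use_weights:
        w = binarize(w)
    rng = np.random.default_rng(seed)
    g = nx.from_numpy_array(w)
    parts = [_louvain_labels(g, gamma_res, rng.integers(2**31)) for _ in range(n_runs)]
    for _ in range(max_consensus_iter):
        first = parts[0]
        if all(np.array_equal(_relabel_contiguous(p), _relabel_contiguous(first)) for p in parts):
            labels = _relabel_contiguous(first)
            return Partition(
                labels=labels,
                q_value=modularity(w, labels, gamma_res),
                gamma_res=gamma_res,
                n_runs=n_runs,
            )
        ag = _agreement(parts)
        tau = _null_agreement(parts)
        ag = np.where(ag > tau, ag, 0.0)
        np.fill_diagonal(ag, 0.0)
        g_cons = nx.from_numpy_array(ag)
        parts = [_louvain_labels(g_cons, 1.0, rng.integers(2**31)) for _ in range(n_runs)]
    raise RuntimeError("consensus clustering did not converge")


# ---------------------------------------------------------------------------
# rich club
# ---------------------------------------------------------------------------

def rich_club_coefficient(adjacency: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """phi(k) = 2 E_{>k} / (N_{>k} (N_{>k} - 1)) for every k with N_{>k} >= 2.

    Nodes with degree <= k are stripped; phi is the density of the surviving
    subgraph.  Returns (k_levels, phi).
    """
    a = binarize(adjacency)
    deg = degree_bin(a)
    ks, phis = [], []
    for k in range(int(deg.max())):
        mask = deg > k
        n_k = int(mask.sum())
        if n_k < 2:
            break
        e_k = a[np.ix_(mask, mask)].sum() / 2.0
        ks.append(k)
        phis.append(2.0 * e_k / (n_k * (n_k - 1)))
    return np.array(ks, dtype=int), np.array(phis, dtype=float)


def k_core_nodes(adjacency: np.ndarray, k: int) -> set[int]:
    """Members of the k-core (iterative pruning of nodes with degree < k)."""
    a = binarize(adjacency).copy()
    alive = np.ones(a.shape[0], dtype=bool)
    while True:
        deg = a[np.ix_(alive, alive)].sum(axis=1)
        drop = deg < k
        if not drop.any() or not alive.any():
            break
        idx = np.flatnonzero(alive)[drop]
        alive[idx] = False
    return set(np.flatnonzero(alive).tolist())


def rich_club(
    conn: Connectome | np.ndarray,
    n_null: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> RichClubProfile:
    """Rich-club detection with degree-preserving nulls and permutation test.

    phi_norm(k) = phi(k) / mean null phi(k); one-sided permutation p-values
    per k.  The selected level is the k with the maximum significant
    phi_norm > 1 (ties resolved toward larger k).  Rich-club nodes are hubs
    (degree > mean + 1 SD) that also belong to the selected kth-core, with
    kth-core membership taken as degree >= k (see also
    :func:`k_core_nodes` for the iterative-pruning core).
    """
    a = conn.adjacency if isinstance(conn, Connectome) else binarize(conn)
    rng = np.random.default_rng(seed)
    ks, phi = rich_club_coefficient(a)
    null_phi = np.full((n_null, len(ks)), np.nan)
    for r in range(n_null):
        b = rewire_null(a, seed=rng)
        _, phi_b = rich_club_coefficient(b)
        m = min(len(phi_b), len(ks))
        null_phi[r, :m] = phi_b[:m]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        null_mean = np.nanmean(null_phi, axis=0)
    phi_norm = np.where(null_mean > 0, phi / null_mean, np.nan)
    # one-sided permutation p: fraction of nulls with phi at least as large
    n_valid = np.sum(~np.isnan(null_phi), axis=0)
    exceed = np.nansum(null_phi >= phi[None, :], axis=0)
    p_values = (1.0 + exceed) / (1.0 + n_valid)

    deg = degree_bin(a)
    hub_threshold = float(deg.mean() + deg.std())
    candidates = np.flatnonzero((phi_norm > 1.0) & (p_values < alpha))
    if len(candidates) == 0:
        warnings.warn("no significant rich-club level found; empty rich club")
        selected_k = None
        rich_nodes: set[int] = set()
    else:
        best = phi_norm[candidates].max()
        selected_k = int(ks[candidates[phi_norm[candidates] == best].max()])
        hubs = set(np.flatnonzero(deg > hub_threshold).tolist())
        rich_nodes = hubs & set(np.flatnonzero(deg >= selected_k).tolist())
    return RichClubProfile(
        k_levels=ks, phi=phi, phi_norm=phi_norm, p_values=p_values,
        n_null=n_null, selected_k=selected_k, rich_nodes=rich_nodes,
        hub_threshold=hub_threshold,
    )


# ---------------------------------------------------------------------------
# edge classification
# ---------------------------------------------------------------------------

def classify_edges(conn: Connectome, partition: Partition, rc: RichClubProfile) -> EdgeClassification:
    """Label every edge on the modular / hemispheric / length / rich-club axes.

    Edge length is the Euclidean distance between node centroids as a
    percentage of the maximum distance over all node pairs: short <= 25%,
    medium (25%, 75%], long > 75%.
    """
    a = conn.adjacency
    iu, ju = np.nonzero(np.triu(a, 1))
    coords = conn.node_coords
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    max_d = dist.max()
    if max_d == 0:
        raise ValueError("degenerate coordinates: all nodes coincide")
    pct = 100.0 * dist[iu, ju] / max_d
    length = np.where(pct <= 25.0, "short", np.where(pct <= 75.0, "medium", "long"))
    labels = partition.labels
    modular = np.where(labels[iu] == labels[ju], "intra", "inter")
    hemi = np.where(conn.node_hemisphere[iu] == conn.node_hemisphere[ju], "intra", "inter")
    in_rc_i = np.isin(iu, list(rc.rich_nodes))
    in_rc_j = np.isin(ju, list(rc.rich_nodes))
    n_rc = in_rc_i.astype(int) + in_rc_j.astype(int)
    richclub = np.where(n_rc == 2, "rich-club", np.where(n_rc == 1, "feeder", "peripheral"))
    df = pd.DataFrame(
        {
            "i": iu, "j": ju,
            "modular": modular, "hemispheric": hemi,
            "length": length, "richclub": richclub,
            "length_pct": pct,
        }
    )
    return EdgeClassification(edges=df)


def edge_class_proportions(
    dataset: Dataset, classifications: dict[str, EdgeClassification]
) -> pd.DataFrame:
    """Per-order mean edge-class proportions with t-based 95% CIs.

    ``classifications`` maps species_id -> EdgeClassification.  Returns a
    tidy frame with columns order, axis, label, mean, ci_low, ci_high,
    n_species.
    """
    records = []
    for sp_id, cls in classifications.items():
        order = dataset.species.order_of(sp_id)
        for axis in EDGE_AXES:
            for lab, frac in cls.proportions(axis).items():
                records.append({"species_id": sp_id, "order": order, "axis": axis,
                                "label": lab, "proportion": frac})
    df = pd.DataFrame(records)
    rows = []
    for (order, axis, lab), grp in df.groupby(["order", "axis", "label"], sort=False):
        vals = grp["proportion"].to_numpy()
        n = len(vals)
        mean = vals.mean()
        if n > 1 and vals.std(ddof=1) > 0:
            half = stats.t.ppf(0.975, n - 1) * vals.std(ddof=1) / np.sqrt(n)
        else:
            half = 0.0
        rows.append({"order": order, "axis": axis, "label": lab, "mean": mean,
                     "ci_low": mean - half, "ci_high": mean + half, "n_species": n})
    return pd.DataFrame(rows)
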