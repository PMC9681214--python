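"""Synthetic taxonomies of connectomes.

Each taxonomic order gets an *archetype*: a bilateral stochastic-block-model
graph with an order-specific module count and connection density, two
lateralized Gaussian coordinate clouds, and distance-dependent log-normal
weights.  Species within an order are degree-preserving perturbations of the
archetype; replicas add smaller perturbations on top of their species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from connectax._swaps import edge_swap, is_connected
from connectax.io import Connectome, Dataset, SpeciesTable

logger = logging.getLogger("connectax.synth")


@dataclass
class TaxonomySpec:
    """Parameters of a synthetic taxonomy of connectomes.

    Species of one order are perturbations of a single per-order archetype,
    so by construction within-order divergence (``within_order_rewire``)
    stays below between-order architectural divergence.
    """

    n_orders: int = 6
    species_per_order: int | list[int] = 5
    n_nodes: int = 200
    #: per-order binary density targets are evenly spaced over this range
    density_range: tuple[float, float] = (0.08, 0.25)
    #: per-order intra-hemispheric module counts cycle over this inclusive range
    module_range: tuple[int, int] = (2, 7)
    #: ratio of within-module to between-module connection probability
    within_between_ratio: float = 8.0
    #: probability that a homotopic node pair is connected
    homotopic_p: float = 0.8
    #: random inter-hemispheric connection probability, relative to p_out
    cross_p_scale: float = 0.5
    #: fraction of edges rewired (degree-preserving) per species
    within_order_rewire: float = 0.05
    #: multiplicative log-normal weight jitter (sigma) per species; sized so
    #: weighted features carry real within-order variation and order
    #: differentiation is dominated by local (not global) features
    species_weight_jitter: float = 0.5
    #: coordinate jitter (sd, same units as coords) per species
    coord_jitter: float = 0.02
    #: replica noise: fraction of edges rewired and weight jitter sigma
    replica_rewire: float = 0.02
    replica_weight_jitter: float = 0.05
    #: species_id -> number of scans (default 1 for unlisted species)
    replicas: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes % 2 != 0:
            raise ValueError("n_nodes must be even (two equal hemispheres)")
        if not 0.0 <= self.within_order_rewire <= 1.0:
            raise ValueError("within_order_rewire must be in [0, 1]")
        if not 0.0 <= self.replica_rewire <= 1.0:
            raise ValueError("replica_rewire must be in [0, 1]")

    def species_counts(self) -> list[int]:
        if isinstance(self.species_per_order, int):
            return [self.species_per_order] * self.n_orders
        counts = list(self.species_per_order)
        if len(counts) != self.n_orders:
            raise ValueError("species_per_order list length must equal n_orders")
        return counts

    def order_density(self, order_index: int) -> float:
        lo, hi = self.density_range
        if self.n_orders == 1:
            return (lo + hi) / 2.0
        return float(np.linspace(lo, hi, self.n_orders)[order_index])

    def order_modules(self, order_index: int) -> int:
        lo, hi = self.module_range
        return lo + order_index % (hi - lo + 1)


def _rng_for(spec: TaxonomySpec, *key: int) -> np.random.Generator:
    """Deterministic substream derived from the master seed and an index key."""
    return np.random.default_rng(np.random.SeedSequence([spec.seed, *key]))


def _module_labels(h: int, n_modules: int) -> np.ndarray:
    return np.sort(np.arange(h) % n_modules)


def _coords(spec: TaxonomySpec, modules: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Two mirrored Gaussian clouds; module-specific sub-clusters in y/z."""
    h = spec.n_nodes // 2
    n_modules = modules.max() + 1
    angles = 2 * np.pi * np.arange(n_modules) / n_modules
    centers = np.stack([0.6 * np.cos(angles), 0.6 * np.sin(angles)], axis=1)
    left = np.empty((h, 3))
    left[:, 0] = -1.0 + 0.15 * rng.standard_normal(h)
    left[:, 1:] = centers[modules] + 0.2 * rng.standard_normal((h, 2))
    right = left.copy()
    right[:, 0] = -left[:, 0]
    right[:, 1:] += 0.05 * rng.standard_normal((h, 2))
    return np.vstack([left, right])


def _weights_for(adj: np.ndarray, coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Log-normal weights, larger for spatially closer node pairs."""
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    scale = dist[adj > 0].mean() if adj.any() else 1.0
    base = np.exp(0.5 * rng.standard_normal(adj.shape))
    base = np.triu(base, 1)
    base = base + base.T
    w = adj * 100.0 * base * np.exp(-dist / scale)
    return (w + w.T) / 2.0


def generate_archetype(
    order_index: int, spec: TaxonomySpec, rng: np.random.Generator | None = None
) -> Connectome:
    """Build the order-level archetype connectome (connected, bilateral)."""
    if rng is None:
        rng = _rng_for(spec, 0, order_index)
    n = spec.n_nodes
    h = n // 2
    n_modules = spec.order_modules(order_index)
    density = spec.order_density(order_index)
    modules = _module_labels(h, n_modules)
    same_module = modules[:, None] == modules[None, :]

    # edge budget -> block probabilities
    total_pairs = n * (n - 1) / 2
    e_target = density * total_pairs
    e_homotopic = spec.homotopic_p * h
    pairs_within = np.triu(same_module, 1).sum()
    pairs_between = h * (h - 1) / 2 - pairs_within
    cross_pairs = h * h - h
    rho = spec.within_between_ratio
    denom = 2 * (pairs_within * rho + pairs_between) + cross_pairs * spec.cross_p_scale
    p_out = max(e_target - e_homotopic, 0.0) / denom
    p_in = min(rho * p_out, 1.0)
    p_out = min(p_out, 1.0)
    p_cross = min(spec.cross_p_scale * p_out, 1.0)

    for attempt in range(50):
        adj = np.zeros((n, n))
        # intra-hemispheric SBM, identical block structure in both hemispheres
        for off in (0, h):
            p_block = np.where(same_module, p_in, p_out)
            tri = np.triu(rng.random((h, h)) < p_block, 1)
            block = tri | tri.T
            adj[off : off + h, off : off + h] = block
        # inter-hemispheric: homotopic + random
        hom = rng.random(h) < spec.homotopic_p
        adj[np.arange(h)[hom], np.arange(h)[hom] + h] = 1
        cross = rng.random((h, h)) < p_cross
        np.fill_diagonal(cross, False)
        adj[:h, h:] = np.maximum(adj[:h, h:], cross)
        adj = np.maximum(adj, adj.T)
        np.fill_diagonal(adj, 0)
        if is_connected(adj) and adj.sum(1).min() >= 1:
            break
    else:
        raise RuntimeError(f"could not generate a connected archetype for order {order_index}")

    coords = _coords(spec, modules, rng)
    weights = _weights_for(adj, coords, rng)
    hemis = np.array(["L"] * h + ["R"] * h, dtype=object)
    return Connectome(
        species_id=f"order{order_index}_archetype",
        sample_id=f"order{order_index}_archetype",
        weights=weights,
        node_hemisphere=hemis,
        node_coords=coords,
    )


def generate_species(
    archetype: Connectome,
    spec: TaxonomySpec,
    rng: np.random.Generator,
    rewire_frac: float | None = None,
    weight_jitter: float | None = None,
) -> Connectome:
    """Perturb an archetype into a species-level connectome.

    Rewires ``rewire_frac`` of the edges with degree-preserving swaps (binary
    degree sequence preserved exactly) and jitters weights multiplicatively.
    """
    if rewire_frac is None:
        rewire_frac = spec.within_order_rewire
    if weight_jitter is None:
        weight_jitter = spec.species_weight_jitter
    if not 0.0 <= rewire_frac <= 1.0:
        raise ValueError("rewire fraction must be in [0, 1]")
    n_edges = int(archetype.adjacency.sum() / 2)
    n_swaps = int(round(rewire_frac * n_edges / 2.0))
    w = archetype.weights
    for attempt in range(50):
        sub = np.random.default_rng(rng.integers(2**63))
        cand, _ = edge_swap(w, n_swaps, sub) if n_swaps > 0 else (w.copy(), 0)
        if is_connected(cand > 0):
            w_new = cand
            break
    else:
        raise RuntimeError("could not keep the graph connected while rewiring")
    if weight_jitter > 0:
        jitter = np.exp(weight_jitter * rng.standard_normal(w_new.shape))
        jitter = np.triu(jitter, 1)
        jitter = jitter + jitter.T
        w_new = w_new * jitter
    coords = archetype.node_coords
    if spec.coord_jitter > 0:
        coords = coords + spec.coord_jitter * rng.standard_normal(coords.shape)
    return Connectome(
        species_id=archetype.species_id,
        sample_id=archetype.sample_id,
        weights=w_new,
        node_hemisphere=archetype.node_hemisphere.copy(),
        node_coords=coords,
    )


def generate_dataset(spec: TaxonomySpec) -> Dataset:
    """Generate the full synthetic taxonomy; deterministic given ``spec.seed``."""
    counts = spec.species_counts()
    connectomes: dict[str, Connectome] = {}
    rows = []
    for o in range(spec.n_orders):
        archetype = generate_archetype(o, spec)
        order_name = f"order{o}"
        superorder = f"superorder{o % 2}"
        for s in range(counts[o]):
            species_id = f"{order_name}_sp{s}"
            sp_rng = _rng_for(spec, 1, o, s)
            base = generate_species(archetype, spec, sp_rng)
            n_reps = max(1, spec.replicas.get(species_id, 1))
            for rep in range(n_reps):
                sample_id = f"{species_id}_r{rep}"
                if rep == 0:
                    conn = base
                else:
                    rep_rng = _rng_for(spec, 2, o, s, rep)
                    conn = generate_species(
                        base,
                        spec,
                        rep_rng,
                        rewire_frac=spec.replica_rewire,
                        weight_jitter=spec.replica_weight_jitter,
                    )
                conn = Connectome(
                    species_id=species_id,
                    sample_id=sample_id,
                    weights=conn.weights,
                    node_hemisphere=conn.node_hemisphere,
                    node_coords=conn.node_coords,
                )
                connectomes[sample_id] = conn
                rows.append(
                    {
                        "species_id": species_id,
                        "order": order_name,
                        "superorder": superorder,
                        "sample_id": sample_id,
                    }
                )
    table = SpeciesTable(pd.DataFrame(rows))
    logger.info(
        "generated synthetic taxonomy: %d orders, %d species, %d samples",
        spec.n_orders, len(table), len(connectomes),
    )
    return Dataset(connectomes=connectomes, species=table, parcellation_size=spec.n_nodes)
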