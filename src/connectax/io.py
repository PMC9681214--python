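"""Data model and file I/O for connectomes, species tables, and datasets.

File conventions
----------------
* connectivity matrix: CSV, N x N numeric, no header, row per node
* node metadata: TSV with header ``node_id  hemisphere  x  y  z``
* species manifest: TSV with header
  ``species_id  order  superorder  sample_id  matrix_path  metadata_path``
  (paths relative to the manifest's directory)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("connectax.io")

#: relative asymmetry below which an input matrix is silently symmetrized
SYMMETRY_RTOL = 1e-8

MANIFEST_COLUMNS = ["species_id", "order", "superorder", "sample_id", "matrix_path", "metadata_path"]
METADATA_COLUMNS = ["node_id", "hemisphere", "x", "y", "z"]


def binarize(weights: np.ndarray) -> np.ndarray:
    """Indicator matrix: 1 where ``weights > 0``, else 0 (float array)."""
    return (np.asarray(weights) > 0).astype(float)


@dataclass
class Connectome:
    """A single scan's weighted undirected brain network plus node metadata.

    ``weights`` must be square, symmetric, nonnegative, with a zero diagonal.
    ``adjacency`` is derived (``weights > 0``) and never stored independently.
    """

    species_id: str
    sample_id: str
    weights: np.ndarray
    node_hemisphere: np.ndarray
    node_coords: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.node_hemisphere = np.asarray(self.node_hemisphere, dtype=object)
        self.node_coords = np.asarray(self.node_coords, dtype=float)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        n = w.shape[0]
        if np.any(w < 0):
            raise ValueError("negative weight in connectivity matrix")
        if np.any(np.diag(w) != 0):
            raise ValueError("nonzero diagonal in connectivity matrix")
        if not np.array_equal(w, w.T):
            raise ValueError("weights not symmetric")
        if self.node_hemisphere.shape != (n,):
            raise ValueError("node_hemisphere length mismatch")
        bad = set(self.node_hemisphere) - {"L", "R"}
        if bad:
            raise ValueError(f"hemisphere labels must be 'L'/'R', got {sorted(bad)}")
        if self.node_coords.shape != (n, 3):
            raise ValueError("node_coords must be (n, 3)")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def adjacency(self) -> np.ndarray:
        return binarize(self.weights)

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def copy(self) -> "Connectome":
        return Connectome(
            species_id=self.species_id,
            sample_id=self.sample_id,
            weights=self.weights.copy(),
            node_hemisphere=self.node_hemisphere.copy(),
            node_coords=self.node_coords.copy(),
        )


class SpeciesTable:
    """Species-level metadata: taxonomic order/superorder and sample ids."""

    def __init__(self, rows: pd.DataFrame):
        required = {"species_id", "order", "superorder", "sample_id"}
        missing = required - set(rows.columns)
        if missing:
            raise ValueError(f"species table missing columns {sorted(missing)}")
        if rows["sample_id"].duplicated().any():
            dup = rows.loc[rows["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        per_species = rows.groupby("species_id")["order"].nunique()
        if (per_species > 1).any():
            raise ValueError("a species maps to more than one order")
        if rows["order"].isna().any() or (rows["order"] == "").any():
            raise ValueError("unlabeled taxonomic order")
        self._rows = rows.reset_index(drop=True)

    @property
    def rows(self) -> pd.DataFrame:
        return self._rows

    @property
    def species_ids(self) -> list[str]:
        return list(dict.fromkeys(self._rows["species_id"]))

    @property
    def sample_ids(self) -> list[str]:
        return list(self._rows["sample_id"])

    @property
    def orders(self) -> list[str]:
        return list(dict.fromkeys(self._rows["order"]))

    def order_of(self, species_id: str) -> str:
        sub = self._rows.loc[self._rows["species_id"] == species_id, "order"]
        if sub.empty:
            raise KeyError(species_id)
        return sub.iloc[0]

    def species_of_sample(self, sample_id: str) -> str:
        sub = self._rows.loc[self._rows["sample_id"] == sample_id, "species_id"]
        if sub.empty:
            raise KeyError(sample_id)
        return sub.iloc[0]

    def samples_of_species(self, species_id: str) -> list[str]:
        return list(self._rows.loc[self._rows["species_id"] == species_id, "sample_id"])

    def species_per_order(self) -> dict[str, int]:
        return self._rows.groupby("order")["species_id"].nunique().to_dict()

    def subset(self, orders: Iterable[str]) -> "SpeciesTable":
        keep = set(orders)
        return SpeciesTable(self._rows[self._rows["order"].isin(keep)].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.species_ids)


@dataclass
class Dataset:
    """A collection of connectomes sharing a parcellation, plus species metadata."""

    connectomes: dict[str, Connectome]
    species: SpeciesTable
    parcellation_size: int = 200

    def __post_init__(self) -> None:
        for sid, conn in self.connectomes.items():
            if conn.n_nodes != self.parcellation_size:
                raise ValueError(
                    f"sample {sid!r} has {conn.n_nodes} nodes, expected {self.parcellation_size}"
                )
        missing = set(self.species.sample_ids) - set(self.connectomes)
        if missing:
            raise ValueError(f"manifest samples without connectomes: {sorted(missing)[:5]}")
        extra = set(self.connectomes) - set(self.species.sample_ids)
        if extra:
            raise ValueError(f"connectomes not in manifest: {sorted(extra)[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.connectomes)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def connectome_for_sample(self, sample_id: str) -> Connectome:
        return self.connectomes[sample_id]

    def one_sample_per_species(self) -> bool:
        return all(len(self.species.samples_of_species(s)) == 1 for s in self.species.species_ids)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_connectome(
    matrix_path: str | Path,
    metadata_path: str | Path,
    species_id: str = "",
    sample_id: str = "",
) -> Connectome:
    """Read a CSV connectivity matrix and TSV node metadata into a Connectome.

    Mild asymmetry (relative max deviation below ``SYMMETRY_RTOL``) is
    symmetrized as ``(M + M.T) / 2``; larger asymmetry is an error.  Every
    node must end up with degree >= 1.
    """
    matrix_path = Path(matrix_path)
    metadata_path = Path(metadata_path)
    m = np.loadtxt(matrix_path, delimiter=",", ndmin=2)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{matrix_path}: non-square matrix {m.shape}")
    if np.any(m < 0):
        raise ValueError(f"{matrix_path}: negative weight")
    asym = np.abs(m - m.T).max()
    scale = np.abs(m).max() or 1.0
    if asym > 0:
        if asym > SYMMETRY_RTOL * scale:
            raise ValueError(f"{matrix_path}: asymmetry {asym:g} above tolerance")
        m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"node_id": str},
                       float_precision="round_trip")
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"{metadata_path}: missing columns {sorted(missing)}")
    if len(meta) != m.shape[0]:
        raise ValueError(
            f"{metadata_path}: {len(meta)} metadata rows for {m.shape[0]} matrix rows"
        )
    conn = Connectome(
        species_id=species_id or matrix_path.stem,
        sample_id=sample_id or matrix_path.stem,
        weights=m,
        node_hemisphere=meta["hemisphere"].to_numpy(dtype=object),
        node_coords=meta[["x", "y", "z"]].to_numpy(dtype=float),
    )
    if np.any(conn.degrees < 1):
        raise ValueError(f"{matrix_path}: isolated node (degree 0) after loading")
    return conn


def write_connectome(conn: Connectome, matrix_path: str | Path, metadata_path: str | Path) -> None:
    """Write matrix CSV + metadata TSV; round-trips float64 weights exactly."""
    matrix_path = Path(matrix_path)
    metadata_path = Path(metadata_path)
    matrix_path.parent.mkdir(parents=True, exist_ok=True)
    metadata_path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(matrix_path, conn.weights, delimiter=",", fmt="%.17g")
    meta = pd.DataFrame(
        {
            "node_id": [f"n{i}" for i in range(conn.n_nodes)],
            "hemisphere": conn.node_hemisphere,
            "x": conn.node_coords[:, 0],
            "y": conn.node_coords[:, 1],
            "z": conn.node_coords[:, 2],
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False, float_format="%.17g")


def load_dataset(manifest_path: str | Path, parcellation_size: int | None = None) -> Dataset:
    """Load all connectomes listed in a manifest TSV.

    All samples must share one node count; if ``parcellation_size`` is given
    it is enforced, otherwise it is inferred from the first sample.
    """
    manifest_path = Path(manifest_path)
    rows = pd.read_csv(manifest_path, sep="\t", dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(rows.columns)
    if missing:
        raise ValueError(f"{manifest_path}: missing manifest columns {sorted(missing)}")
    table = SpeciesTable(rows[["species_id", "order", "superorder", "sample_id"]])
    base = manifest_path.parent
    connectomes: dict[str, Connectome] = {}
    for rec in rows.itertuples(index=False):
        conn = read_connectome(
            base / rec.matrix_path,
            base / rec.metadata_path,
            species_id=rec.species_id,
            sample_id=rec.sample_id,
        )
        if parcellation_size is None:
            parcellation_size = conn.n_nodes
        if conn.n_nodes != parcellation_size:
            raise ValueError(
                f"sample {rec.sample_id!r}: {conn.n_nodes} nodes, expected {parcellation_size}"
            )
        connectomes[rec.sample_id] = conn
    if not connectomes:
        raise ValueError(f"{manifest_path}: empty manifest")
    ds = Dataset(connectomes=connectomes, species=table, parcellation_size=int(parcellation_size))
    logger.info(
        "loaded dataset: %d samples, %d species, %d orders",
        ds.n_samples, ds.n_species, len(table.orders),
    )
    return ds


def write_dataset(dataset: Dataset, out_dir: str | Path) -> Path:
    """Write all connectomes plus a manifest TSV under ``out_dir``.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    (out_dir / "matrices").mkdir(parents=True, exist_ok=True)
    (out_dir / "metadata").mkdir(parents=True, exist_ok=True)
    records = []
    for rec in dataset.species.rows.itertuples(index=False):
        conn = dataset.connectomes[rec.sample_id]
        mpath = f"matrices/{rec.sample_id}.csv"
        dpath = f"metadata/{rec.sample_id}.tsv"
        write_connectome(conn, out_dir / mpath, out_dir / dpath)
        records.append(
            {
                "species_id": rec.species_id,
                "order": rec.order,
                "superorder": rec.superorder,
                "sample_id": rec.sample_id,
                "matrix_path": mpath,
                "metadata_path": dpath,
            }
        )
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(records, columns=MANIFEST_COLUMNS).to_csv(manifest, sep="\t", index=False)
    return manifest


def filter_orders(dataset: Dataset, min_species: int = 5) -> Dataset:
    """Keep only taxonomic orders with at least ``min_species`` distinct species."""
    if min_species < 1:
        raise ValueError("min_species must be >= 1")
    counts = dataset.species.species_per_order()
    keep = [o for o, c in counts.items() if c >= min_species]
    drop = sorted(set(counts) - set(keep))
    for o in drop:
        logger.info("excluding order %r (%d species < %d)", o, counts[o], min_species)
    if not keep:
        raise ValueError("no orders left after filtering")
    table = dataset.species.subset(keep)
    kept_samples = set(table.sample_ids)
    conns = {sid: c for sid, c in dataset.connectomes.items() if sid in kept_samples}
    out = Dataset(connectomes=conns, species=table, parcellation_size=dataset.parcellation_size)
    logger.info(
        "retained %d orders, %d species, %d samples", len(keep), out.n_species, out.n_samples
    )
    return out
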