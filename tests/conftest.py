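import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from connectax import Connectome, TaxonomySpec, generate_dataset


def make_connectome(weights, species_id="sp", sample_id="s0", coords=None, hemis=None):
    """Wrap a raw weight matrix in a Connectome with default metadata."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    if coords is None:
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(n, 3))
    if hemis is None:
        hemis = np.array(["L"] * (n // 2) + ["R"] * (n - n // 2), dtype=object)
    return Connectome(species_id=species_id, sample_id=sample_id, weights=w,
                      node_hemisphere=np.asarray(hemis, dtype=object), node_coords=coords)


@pytest.fixture(scope="session")
def small_spec():
    """3 orders x 3 species at 60 nodes; one species has 2 extra replicas."""
    return TaxonomySpec(
        n_orders=3,
        species_per_order=3,
        n_nodes=60,
        density_range=(0.12, 0.25),
        replicas={"order0_sp0": 3},
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# -- canonical toy graphs ---------------------------------------------------

@pytest.fixture
def triangle():
    return np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)


@pytest.fixture
def path3():
    return np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)


@pytest.fixture
def star4():
    a = np.zeros((4, 4))
    a[0, 1:] = 1
    a[1:, 0] = 1
    return a


def complete_graph(n):
    a = np.ones((n, n)) - np.eye(n)
    return a
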