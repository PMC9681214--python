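import numpy as np
import pandas as pd
import pytest

from connectax import (
    DistanceMatrix,
    cohens_d,
    compare_samples,
    density_control,
    distance_matrix,
    distances_from_table,
    hierarchical_cluster,
    intra_inter_compare,
    mds_embed,
    network_density,
    order_block_summary,
    resample_replicas,
    sample_vectors,
    split_intra_inter,
    topological_distance,
)
from connectax.features import feature_vector
from conftest import complete_graph


def _dm(labels, values, **kw):
    return DistanceMatrix(labels=labels, values=np.asarray(values, float),
                          metric=kw.pop("metric", "spectral"), **kw)


class TestDistanceMatrixType:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            _dm(["a", "b"], [[0, 1], [2, 0]])

    def test_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            _dm(["a", "b"], [[1, 0], [0, 0]])


class TestTopologicalDistance:
    def test_identity_and_symmetry(self, small_dataset):
        conns = list(small_dataset.connectomes.values())
        fa = feature_vector(conns[0])
        fb = feature_vector(conns[1])
        ctx = np.vstack([feature_vector(c).values for c in conns[:5]])
        assert topological_distance(fa, fa, ctx) == pytest.approx(0.0, abs=1e-12)
        assert topological_distance(fa, fb, ctx) == pytest.approx(
            topological_distance(fb, fa, ctx))

    def test_opposite_sign_z_vectors(self):
        """Two species with standardized columns +/-1: same signs -> 0, opposite -> 2."""
        from connectax.features import FeatureVector

        a = FeatureVector(values=np.array([1.0, 2.0, 3.0]), names=list("abc"))
        b = FeatureVector(values=np.array([0.0, 0.0, 0.0]), names=list("abc"))
        ctx = np.vstack([a.values, b.values])
        # z-scored columns give exactly +1 for a, -1 for b in every column
        assert topological_distance(a, a, ctx) == pytest.approx(0.0, abs=1e-12)
        assert topological_distance(a, b, ctx) == pytest.approx(2.0, abs=1e-12)

    def test_subset_mismatch_rejected(self, small_dataset):
        conn = next(iter(small_dataset.connectomes.values()))
        fa = feature_vector(conn, subset="local")
        fb = feature_vector(conn, subset="global")
        with pytest.raises(ValueError, match="subset"):
            topological_distance(fa, fb, np.zeros((2, 3)))


class TestDistanceMatrixBuild:
    def test_duplicate_species_zero_distance(self, small_dataset):
        import copy

        from connectax.io import Dataset, SpeciesTable

        base = small_dataset.connectomes["order1_sp0_r0"]
        rows = []
        conns = {}
        for i in range(3):
            sp = f"dup{i}"
            sid = f"{sp}_r0"
            c = copy.deepcopy(base)
            c.species_id, c.sample_id = sp, sid
            conns[sid] = c
            rows.append({"species_id": sp, "order": f"o{i % 2}", "superorder": "s",
                         "sample_id": sid})
        ds = Dataset(connectomes=conns, species=SpeciesTable(pd.DataFrame(rows)),
                     parcellation_size=base.n_nodes)
        dm = distance_matrix(ds, "spectral")
        np.testing.assert_allclose(dm.values, 0.0, atol=1e-12)

    def test_replicated_dataset_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="one sample per species"):
            distance_matrix(small_dataset, "spectral")

    def test_intra_blocks_smaller(self, small_dataset):
        dm = resample_replicas(small_dataset, "spectral", n_iter=20, seed=0)
        intra, inter = split_intra_inter(dm, small_dataset.species)
        assert intra.mean() < inter.mean()


class TestResampleReplicas:
    def test_no_replicas_equals_single_shot(self):
        from connectax import TaxonomySpec, generate_dataset

        ds = generate_dataset(TaxonomySpec(n_orders=2, species_per_order=3,
                                           n_nodes=40, seed=5))
        for metric in ("spectral", "topological"):
            single = distance_matrix(ds, metric)
            avg = resample_replicas(ds, metric, n_iter=50, seed=1)
            np.testing.assert_allclose(avg.values, single.values, atol=1e-12)

    def test_deterministic_given_seed(self, small_dataset):
        a = resample_replicas(small_dataset, "spectral", n_iter=30, seed=9)
        b = resample_replicas(small_dataset, "spectral", n_iter=30, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_average_lies_between_replica_extremes(self, small_dataset):
        ds = small_dataset
        # order0_sp0 has 3 replicas: distances to another species must average
        other = "order2_sp1"
        per_replica = []
        vecs = sample_vectors(ds, "spectral")
        from connectax.spectral import cosine_distance

        other_vec = vecs.loc[ds.species.samples_of_species(other)[0]].to_numpy()
        for sid in ds.species.samples_of_species("order0_sp0"):
            per_replica.append(cosine_distance(vecs.loc[sid].to_numpy(), other_vec))
        dm = resample_replicas(ds, "spectral", n_iter=400, seed=2)
        i = dm.labels.index("order0_sp0")
        j = dm.labels.index(other)
        assert min(per_replica) - 1e-12 <= dm.values[i, j] <= max(per_replica) + 1e-12

    def test_convergence_across_seeds(self, small_dataset):
        mats = [resample_replicas(small_dataset, "spectral", n_iter=500, seed=s).values
                for s in range(3)]
        spread = np.std(mats, axis=0)
        assert spread.max() < 0.005


class TestCompareSamples:
    def test_perfect_separation(self):
        res = compare_samples(np.zeros(3), np.ones(3))
        assert res.cles == 100.0
        assert np.isinf(res.cohen_d) and res.cohen_d > 0

    def test_cles_exhaustive_counting(self):
        intra = np.array([1.0, 2.0, 3.0])
        inter = np.array([2.0, 3.0, 4.0])
        res = compare_samples(intra, inter)
        # brute force: count inter>intra pairs + half ties
        wins = sum(1.0 for a in inter for b in intra if a > b)
        ties = sum(0.5 for a in inter for b in intra if a == b)
        assert res.u_stat == pytest.approx(wins + ties)
        assert res.cles == pytest.approx(100 * (wins + ties) / 9)

    def test_cles_matches_brute_force_random(self, rng):
        for _ in range(20):
            intra = rng.integers(0, 6, size=rng.integers(2, 8)).astype(float)
            inter = rng.integers(0, 6, size=rng.integers(2, 8)).astype(float)
            res = compare_samples(intra, inter)
            brute = (sum(1.0 for a in inter for b in intra if a > b)
                     + sum(0.5 for a in inter for b in intra if a == b))
            assert res.cles == pytest.approx(100 * brute / (len(intra) * len(inter)))

    def test_cohens_d_pooled_formula(self, rng):
        inter = rng.normal(1, 1, 30)
        intra = rng.normal(0, 2, 20)
        s_pool = np.sqrt(((len(inter) - 1) * inter.var(ddof=1)
                          + (len(intra) - 1) * intra.var(ddof=1))
                         / (len(inter) + len(intra) - 2))
        assert cohens_d(inter, intra) == pytest.approx(
            (inter.mean() - intra.mean()) / s_pool)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_samples(np.array([1.0]), np.array([1.0, 2.0]))


class TestOrderBlockSummary:
    def test_hand_computed_medians(self):
        labels = ["a1", "a2", "b1", "b2"]
        v = np.array([
            [0.0, 0.1, 0.5, 0.7],
            [0.1, 0.0, 0.6, 0.8],
            [0.5, 0.6, 0.0, 0.2],
            [0.7, 0.8, 0.2, 0.0],
        ])
        dm = _dm(labels, v)
        rows = pd.DataFrame({
            "species_id": labels, "order": ["A", "A", "B", "B"],
            "superorder": ["s"] * 4, "sample_id": [f"{x}_r0" for x in labels],
        })
        from connectax.io import SpeciesTable

        table = SpeciesTable(rows)
        out = order_block_summary(dm, table)
        assert out.loc["A", "A"] == pytest.approx(0.1)
        assert out.loc["B", "B"] == pytest.approx(0.2)
        assert out.loc["A", "B"] == pytest.approx(np.median([0.5, 0.7, 0.6, 0.8]))
        np.testing.assert_allclose(out.values, out.values.T)

    def test_synthetic_diagonal_smaller(self, small_dataset):
        dm = resample_replicas(small_dataset, "spectral", n_iter=20, seed=0)
        out = order_block_summary(dm, small_dataset.species)
        diag = np.diag(out.values)
        off = out.values[~np.eye(len(out), dtype=bool)]
        assert diag.mean() < off.mean()


class TestDensityControl:
    def test_exact_linear(self, rng):
        x = rng.uniform(0.05, 0.3, 40)
        df = pd.DataFrame({"f": 2 * x + 1})
        out, info = density_control(df, x)
        assert info.loc["f", "model"] == "linear"
        assert info.loc["f", "r_squared"] == pytest.approx(1.0)
        np.testing.assert_allclose(out["f"], 0.0, atol=1e-10)

    def test_independent_feature_unchanged(self, rng):
        x = rng.uniform(0.05, 0.3, 60)
        y = rng.normal(size=60)
        df = pd.DataFrame({"f": y})
        out, info = density_control(df, x)
        if not info.loc["f", "controlled"]:
            np.testing.assert_array_equal(out["f"], df["f"])

    def test_exponential_selected(self, rng):
        x = rng.uniform(0.0, 1.0, 50)
        y = np.exp(3 * x) + 0.01 * rng.normal(size=50)
        df = pd.DataFrame({"f": y})
        out, info = density_control(df, x)
        assert info.loc["f", "model"] == "exponential"
        assert info.loc["f", "controlled"]
        assert out["f"].std() < 0.02 * df["f"].std()

    def test_residual_correlation_below_threshold(self, rng):
        x = rng.uniform(0.05, 0.3, 80)
        df = pd.DataFrame({
            "lin": 5 * x + rng.normal(scale=0.05, size=80),
            "exp": np.exp(4 * x) + rng.normal(scale=0.1, size=80),
        })
        out, info = density_control(df, x)
        for col in df.columns:
            assert info.loc[col, "controlled"]
            assert abs(np.corrcoef(out[col], x)[0, 1]) < 0.1

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            density_control(pd.DataFrame({"f": [1.0, 2.0]}), np.array([0.1, 0.2]))


class TestNetworkDensity:
    def test_complete(self):
        assert network_density(complete_graph(4)) == 1.0

    def test_path4(self):
        a = np.zeros((4, 4))
        for i in range(3):
            a[i, i + 1] = a[i + 1, i] = 1
        assert network_density(a) == pytest.approx(0.5)

    def test_empty(self):
        assert network_density(np.zeros((5, 5))) == 0.0


class TestEmbeddings:
    def test_equilateral_triangle(self):
        dm = _dm(["a", "b", "c"], (np.ones((3, 3)) - np.eye(3)) * 0.5)
        coords, stress = mds_embed(dm, seed=0)
        d = np.linalg.norm(coords.to_numpy()[:, None] - coords.to_numpy()[None], axis=-1)
        off = d[np.triu_indices(3, 1)]
        np.testing.assert_allclose(off, off[0], atol=1e-6)

    def test_duplicates_coincide(self):
        v = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]], dtype=float)
        dm = _dm(["a", "b", "c"], v)
        coords, _ = mds_embed(dm, seed=0)
        assert np.linalg.norm(coords.loc["a"] - coords.loc["b"]) < 1e-6

    def test_two_cluster_structure(self):
        v = np.full((6, 6), 1.0)
        v[:3, :3] = 0.1
        v[3:, 3:] = 0.1
        np.fill_diagonal(v, 0.0)
        dm = _dm(list("abcdef"), v)
        coords, _ = mds_embed(dm, seed=1)
        x = coords.to_numpy()
        within = np.linalg.norm(x[0] - x[1])
        between = np.linalg.norm(x[0] - x[4])
        assert between > within

    def test_deterministic(self, small_dataset):
        dm = resample_replicas(small_dataset, "spectral", n_iter=5, seed=0)
        c1, s1 = mds_embed(dm, seed=3)
        c2, s2 = mds_embed(dm, seed=3)
        np.testing.assert_array_equal(c1.to_numpy(), c2.to_numpy())
        assert s1 == s2


class TestHierarchicalCluster:
    def test_two_group_recovery(self):
        v = np.full((6, 6), 1.0)
        v[:3, :3] = 0.1
        v[3:, 3:] = 0.1
        np.fill_diagonal(v, 0.0)
        dm = _dm(list("abcdef"), v)
        z = hierarchical_cluster(dm)
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(z, t=2, criterion="maxclust")
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_identical_merge_at_zero(self):
        v = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]], dtype=float)
        z = hierarchical_cluster(_dm(["a", "b", "c"], v))
        assert z[0, 2] == 0.0

    def test_monotone_heights(self, small_dataset):
        dm = resample_replicas(small_dataset, "spectral", n_iter=5, seed=0)
        z = hierarchical_cluster(dm)
        heights = z[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)
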