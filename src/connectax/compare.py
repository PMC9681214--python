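"""Inter-species distance matrices, taxon comparisons, and embeddings.

Builds species x species distance matrices from eigenspectra or feature
vectors, averages them over replica resampling, splits the pairwise
distances into intra- vs inter-order samples, and tests the difference with
Welch's t (Cohen's d) and Mann-Whitney U (common-language effect size).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.optimize import curve_fit
from scipy.spatial.distance import squareform
from sklearn.manifold import smacof

from connectax.features import FEATURE_NAMES, FeatureVector, feature_vector, subset_mask
from connectax.io import Dataset, SpeciesTable, binarize
from connectax.spectral import cosine_distance, smooth_spectrum, spectrum

logger = logging.getLogger("connectax.compare")

METRICS = ("spectral", "topological")


@dataclass
class DistanceMatrix:
    """Symmetric species-by-species distances with provenance."""

    labels: list[str]
    values: np.ndarray
    metric: str
    subset: str = "all"
    n_iter: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if np.abs(v - v.T).max() > 1e-12:
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be 0")
        self.values = (v + v.T) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class TaxonComparison:
    """Intra- vs inter-order distance samples plus test statistics."""

    intra: np.ndarray
    inter: np.ndarray
    t_stat: float
    t_pvalue: float
    cohen_d: float
    u_stat: float
    u_pvalue: float
    cles: float  # percent, in [0, 100]

    def summary(self) -> str:
        return (
            f"intra: n={len(self.intra)} mean={self.intra.mean():.4f} "
            f"median={np.median(self.intra):.4f}\n"
            f"inter: n={len(self.inter)} mean={self.inter.mean():.4f} "
            f"median={np.median(self.inter):.4f}\n"
            f"Welch t={self.t_stat:.4f} p={self.t_pvalue:.3g} Cohen's d={self.cohen_d:.4f}\n"
            f"Mann-Whitney U={self.u_stat:.1f} p={self.u_pvalue:.3g} CLES={self.cles:.2f}%"
        )


# ---------------------------------------------------------------------------
# per-sample vectors
# ---------------------------------------------------------------------------

def network_density(adjacency: np.ndarray) -> float:
    """2 E / (N (N - 1))."""
    a = binarize(adjacency)
    n = a.shape[0]
    if n < 2:
        return 0.0
    return float(a.sum() / (n * (n - 1)))


def sample_vectors(
    dataset: Dataset, metric: str, subset: str = "all", use_smoothed: bool = False
) -> pd.DataFrame:
    """One comparison vector per sample: eigenvalues or topological features."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    rows = {}
    for sid in dataset.species.sample_ids:
        conn = dataset.connectomes[sid]
        if metric == "spectral":
            prof = spectrum(conn)
            if use_smoothed:
                prof = smooth_spectrum(prof)
                rows[sid] = prof.density
            else:
                rows[sid] = prof.eigenvalues
        else:
            rows[sid] = feature_vector(conn, subset=subset).values
    df = pd.DataFrame.from_dict(rows, orient="index")
    if metric == "topological":
        df.columns = [n for n, m in zip(FEATURE_NAMES, subset_mask(subset)) if m]
    return df


def _standardize_columns(x: np.ndarray) -> np.ndarray:
    """Z-score columns; zero-variance columns are dropped with a warning."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance feature column(s)")
    if not keep.any():
        raise ValueError("all feature columns have zero variance")
    return (x[:, keep] - mu[keep]) / sd[keep]


def _pairwise_cosine(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero vector has no cosine distance")
    u = x / norms[:, None]
    d = 1.0 - u @ u.T
    np.fill_diagonal(d, 0.0)
    return np.maximum((d + d.T) / 2.0, 0.0)


def topological_distance(
    a: FeatureVector, b: FeatureVector, context: np.ndarray | pd.DataFrame, standardize: bool = True
) -> float:
    """1 - cosine similarity between two feature vectors.

    ``context`` holds all species' vectors (rows) for the current iteration;
    by default each feature column is z-scored across the context before the
    cosine is taken.
    """
    if a.subset != b.subset:
        raise ValueError("feature vectors use different subsets")
    ctx = np.asarray(context, dtype=float)
    va, vb = a.values, b.values
    if standardize:
        mu = ctx.mean(axis=0)
        sd = ctx.std(axis=0)
        keep = sd > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} zero-variance feature column(s)")
        va = (va[keep] - mu[keep]) / sd[keep]
        vb = (vb[keep] - mu[keep]) / sd[keep]
    return cosine_distance(va, vb)


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

def distances_from_table(
    table: pd.DataFrame,
    metric: str = "topological",
    subset: str = "all",
    standardize: bool = True,
) -> DistanceMatrix:
    """Distance matrix from a precomputed per-species vector table.

    For topological tables with all 22 columns, a feature ``subset`` may be
    applied by name before standardization.  Avoids recomputing graph
    measures when several subsets of one dataset are compared.
    """
    x = table.to_numpy(dtype=float)
    if metric == "topological" and subset != "all":
        if list(table.columns) != FEATURE_NAMES:
            raise ValueError("subsetting requires the full 22-column feature table")
        x = x[:, subset_mask(subset)]
    if metric == "topological" and standardize and x.shape[0] > 1:
        x = _standardize_columns(x)
    d = _pairwise_cosine(x)
    if metric == "spectral":
        d = np.clip(d, 0.0, 1.0)
    return DistanceMatrix(labels=list(table.index), values=d, metric=metric, subset=subset)


def distance_matrix(
    dataset: Dataset,
    metric: str = "spectral",
    subset: str = "all",
    standardize: bool = True,
    use_smoothed: bool = False,
) -> DistanceMatrix:
    """Species-by-species distances for a dataset with one sample per species."""
    if not dataset.one_sample_per_species():
        raise ValueError("distance_matrix expects one sample per species; "
                         "use resample_replicas for datasets with replicas")
    vecs = sample_vectors(dataset, metric, subset=subset, use_smoothed=use_smoothed)
    species_ids = dataset.species.species_ids
    order = [dataset.species.samples_of_species(s)[0] for s in species_ids]
    x = vecs.loc[order].to_numpy(dtype=float)
    if metric == "topological" and standardize and x.shape[0] > 1:
        x = _standardize_columns(x)
    d = _pairwise_cosine(x)
    if metric == "spectral":
        d = np.clip(d, 0.0, 1.0)
    return DistanceMatrix(labels=species_ids, values=d, metric=metric, subset=subset)


def resample_replicas(
    dataset: Dataset,
    metric: str = "spectral",
    subset: str = "all",
    n_iter: int = 10000,
    seed: int | None = None,
    standardize: bool = True,
    use_smoothed: bool = False,
) -> DistanceMatrix:
    """Average distance matrix over random single-scan-per-species draws.

    Each iteration samples one scan per species uniformly and computes the
    full distance matrix; the result is the element-wise mean over
    iterations.  Deterministic given ``seed``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    vecs = sample_vectors(dataset, metric, subset=subset, use_smoothed=use_smoothed)
    species_ids = dataset.species.species_ids
    sample_index = {sid: i for i, sid in enumerate(vecs.index)}
    groups = [
        np.array([sample_index[s] for s in dataset.species.samples_of_species(sp)])
        for sp in species_ids
    ]
    x_all = vecs.to_numpy(dtype=float)
    needs_context = metric == "topological" and standardize
    if not needs_context:
        # vectors are fixed per sample, so precompute all pairwise distances
        full = _pairwise_cosine(x_all)
        if metric == "spectral":
            full = np.clip(full, 0.0, 1.0)
    acc = np.zeros((len(species_ids), len(species_ids)))
    for _ in range(n_iter):
        picks = np.array([g[rng.integers(len(g))] for g in groups])
        if needs_context:
            x = _standardize_columns(x_all[picks])
            acc += _pairwise_cosine(x)
        else:
            acc += full[np.ix_(picks, picks)]
    d = acc / n_iter
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(
        labels=species_ids, values=d, metric=metric, subset=subset, n_iter=n_iter, seed=seed
    )


# ---------------------------------------------------------------------------
# intra vs inter order statistics
# ---------------------------------------------------------------------------

def cohens_d(inter: np.ndarray, intra: np.ndarray) -> float:
    """(mean_inter - mean_intra) / df-weighted pooled SD.

    Returns a signed infinity sentinel when both groups have zero variance
    but different means (perfect separation).
    """
    inter = np.asarray(inter, dtype=float)
    intra = np.asarray(intra, dtype=float)
    n1, n2 = len(inter), len(intra)
    v1 = inter.var(ddof=1) if n1 > 1 else 0.0
    v2 = intra.var(ddof=1) if n2 > 1 else 0.0
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    diff = inter.mean() - intra.mean()
    if pooled == 0:
        return float(np.sign(diff) * np.inf) if diff != 0 else 0.0
    return float(diff / np.sqrt(pooled))


def compare_samples(intra: np.ndarray, inter: np.ndarray) -> TaxonComparison:
    """Welch's t + Cohen's d and Mann-Whitney U + CLES for two samples.

    CLES = 100 U / (n1 n2) where U counts (inter > intra) pairs with
    half-weight for ties.
    """
    intra = np.asarray(intra, dtype=float)
    inter = np.asarray(inter, dtype=float)
    if len(intra) < 2 or len(inter) < 2:
        raise ValueError("need at least 2 intra and 2 inter values")
    with np.errstate(all="ignore"):
        t_res = stats.ttest_ind(inter, intra, equal_var=False)
        u_res = stats.mannwhitneyu(inter, intra, alternative="two-sided")
    cles = 100.0 * float(u_res.statistic) / (len(inter) * len(intra))
    return TaxonComparison(
        intra=intra,
        inter=inter,
        t_stat=float(t_res.statistic),
        t_pvalue=float(t_res.pvalue),
        cohen_d=cohens_d(inter, intra),
        u_stat=float(u_res.statistic),
        u_pvalue=float(u_res.pvalue),
        cles=cles,
    )


def split_intra_inter(dm: DistanceMatrix, species: SpeciesTable) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle distances split by same-order vs different-order pairs."""
    orders = np.array([species.order_of(s) for s in dm.labels], dtype=object)
    iu, ju = np.triu_indices(len(dm.labels), k=1)
    same = orders[iu] == orders[ju]
    vals = dm.values[iu, ju]
    return vals[same], vals[~same]


def intra_inter_compare(dm: DistanceMatrix, species: SpeciesTable) -> TaxonComparison:
    """Welch's t + Cohen's d and Mann-Whitney U + CLES on intra vs inter pairs.

    Positive d and CLES > 50% mean inter-order distances exceed intra-order
    distances.  CLES = 100 U / (n1 n2) with U counting (inter > intra) pairs
    and half-weight ties.
    """
    intra, inter = split_intra_inter(dm, species)
    return compare_samples(intra, inter)


def order_block_summary(dm: DistanceMatrix, species: SpeciesTable) -> pd.DataFrame:
    """Order-by-order matrix of median pairwise distances.

    Diagonal entries are within-order medians; off-diagonal entries are the
    medians over species pairs spanning the two orders.
    """
    orders = np.array([species.order_of(s) for s in dm.labels], dtype=object)
    uniq = list(dict.fromkeys(orders))
    out = pd.DataFrame(np.nan, index=uniq, columns=uniq, dtype=float)
    for a_i, oa in enumerate(uniq):
        for ob in uniq[a_i:]:
            ia = np.flatnonzero(orders == oa)
            ib = np.flatnonzero(orders == ob)
            if oa == ob:
                if len(ia) < 2:
                    continue
                iu, ju = np.triu_indices(len(ia), k=1)
                vals = dm.values[ia[iu], ia[ju]]
            else:
                vals = dm.values[np.ix_(ia, ib)].ravel()
            med = float(np.median(vals))
            out.loc[oa, ob] = med
            out.loc[ob, oa] = med
    return out


# ---------------------------------------------------------------------------
# density control
# ---------------------------------------------------------------------------

def _r_squared(y: np.ndarray, resid: np.ndarray) -> float:
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    return float(1.0 - (resid**2).sum() / ss_tot)


def _fit_linear(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    a, b = np.polyfit(x, y, 1)
    resid = y - (a * x + b)
    return resid, _r_squared(y, resid)


def _fit_exponential(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    def model(x, a, b, c):
        return a * np.exp(b * x) + c

    span = np.ptp(y) or 1.0
    c0 = y.min() - 0.05 * span
    z = np.maximum(y - c0, 1e-12 * span)
    b0, loga0 = np.polyfit(x, np.log(z), 1)
    p0 = [np.exp(loga0), b0, c0]
    popt, _ = curve_fit(model, x, y, p0=p0, maxfev=5000)
    resid = y - model(x, *popt)
    return resid, _r_squared(y, resid)


def density_control(
    feature_table: pd.DataFrame,
    densities: np.ndarray | pd.Series,
    r2_threshold: float = 0.1,
    exp_margin: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Residualize density-dependent features.

    For each feature column, fit linear (y = a x + b) and exponential
    (y = a e^{bx} + c) models against density and keep the better fit; if
    its R^2 exceeds ``r2_threshold`` the column is replaced by residuals,
    otherwise left unchanged.  Because the 3-parameter exponential nearly
    nests the linear model, it is only preferred when it improves R^2 by
    more than ``exp_margin``.  Returns (residualized table, per-feature
    info with columns model, r_squared, controlled).
    """
    x = np.asarray(densities, dtype=float)
    if len(x) != len(feature_table):
        raise ValueError("densities length must match feature table rows")
    if len(x) < 3:
        raise ValueError("need at least 3 samples to fit density models")
    out = feature_table.copy()
    info_rows = []
    for col in feature_table.columns:
        y = feature_table[col].to_numpy(dtype=float)
        resid_lin, r2_lin = _fit_linear(x, y)
        try:
            resid_exp, r2_exp = _fit_exponential(x, y)
        except (RuntimeError, ValueError):
            logger.warning("exponential fit failed for %r; falling back to linear", col)
            resid_exp, r2_exp = resid_lin, -np.inf
        if r2_exp > r2_lin + exp_margin:
            model, r2, resid = "exponential", r2_exp, resid_exp
        else:
            model, r2, resid = "linear", r2_lin, resid_lin
        controlled = r2 > r2_threshold
        if controlled:
            out[col] = resid
        info_rows.append({"feature": col, "model": model, "r_squared": r2,
                          "controlled": controlled})
    return out, pd.DataFrame(info_rows).set_index("feature")


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

def _classical_mds(d: np.ndarray, n_dims: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:n_dims]
    lam = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(lam)[None, :]


def mds_embed(
    dm: DistanceMatrix, n_dims: int = 2, seed: int | None = None
) -> tuple[pd.DataFrame, float]:
    """Metric MDS of a distance matrix: classical init + stress majorization.

    Returns (coordinates indexed by species, final raw stress).
    """
    init = _classical_mds(dm.values, n_dims)
    coords, stress = smacof(
        dm.values, n_components=n_dims, init=init, n_init=1,
        random_state=seed, normalized_stress=False,
    )
    df = pd.DataFrame(coords, index=dm.labels, columns=[f"dim{i+1}" for i in range(n_dims)])
    return df, float(stress)


def hierarchical_cluster(dm: DistanceMatrix, method: str = "average") -> np.ndarray:
    """Agglomerative clustering linkage matrix (scipy format)."""
    condensed = squareform(dm.values, checks=False)
    return _scipy_linkage(condensed, method=method)
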