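"""Normalized Laplacian eigenspectra and the spectral distance.

The normalized Laplacian is L = I - D^-1 A on the binarized matrix; all its
eigenvalues lie in [0, 2] and it is unitarily equivalent to the symmetric
form I - D^-1/2 A D^-1/2, which is what the eigensolver actually factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from connectax.io import Connectome, binarize


@dataclass
class SpectralProfile:
    """Sorted normalized-Laplacian eigenvalues, optionally kernel-smoothed."""

    eigenvalues: np.ndarray
    grid: np.ndarray | None = None
    density: np.ndarray | None = None
    sigma: float | None = None

    @property
    def n_grid(self) -> int:
        return 0 if self.grid is None else len(self.grid)


def normalized_laplacian(adjacency: np.ndarray) -> np.ndarray:
    """L = I - D^-1 A: 1 on the diagonal, -1/deg(i) at edges (i, j)."""
    a = binarize(adjacency)
    deg = a.sum(axis=1)
    if np.any(deg == 0):
        raise ValueError("isolated node: normalized Laplacian undefined")
    return np.eye(a.shape[0]) - a / deg[:, None]


def spectrum(conn: Connectome | np.ndarray) -> SpectralProfile:
    """Ascending eigenvalues of the normalized Laplacian.

    Solved on the symmetric form D^-1/2 (D - A) D^-1/2 for numerical
    stability; the spectrum is identical to L = I - D^-1 A.
    """
    a = conn.adjacency if isinstance(conn, Connectome) else binarize(conn)
    deg = a.sum(axis=1)
    if np.any(deg == 0):
        raise ValueError("isolated node: normalized Laplacian undefined")
    inv_sqrt = 1.0 / np.sqrt(deg)
    lsym = np.eye(a.shape[0]) - (inv_sqrt[:, None] * a * inv_sqrt[None, :])
    lsym = (lsym + lsym.T) / 2.0
    vals = eigh(lsym, eigvals_only=True)
    return SpectralProfile(eigenvalues=np.sort(vals))


def smooth_spectrum(
    profile: SpectralProfile, sigma: float = 0.015, step: float = 0.001
) -> SpectralProfile:
    """Gaussian-kernel density of the eigenvalue spectrum on [0, 2).

    The grid is the half-open arange(0, 2, step) — exactly 2000 points at
    the default step.  The density is renormalized to unit trapezoid area.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if step <= 0:
        raise ValueError("step must be > 0")
    lam = np.asarray(profile.eigenvalues, dtype=float)
    if lam.size == 0:
        raise ValueError("empty eigenvalue vector")
    grid = np.arange(0.0, 2.0, step)
    diff = grid[:, None] - lam[None, :]
    dens = (np.exp(-(diff**2) / (2.0 * sigma**2)) / np.sqrt(2.0 * np.pi * sigma**2)).sum(axis=1)
    area = np.trapezoid(dens, grid)
    if area > 0:
        dens = dens / area
    return SpectralProfile(eigenvalues=lam, grid=grid, density=dens, sigma=sigma)


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cosine similarity; in [0, 1] for nonnegative vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"vector length mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero vector has no cosine distance")
    d = 1.0 - float(u @ v) / (nu * nv)
    return 0.0 if -1e-12 < d < 0.0 else float(d)  # clamp rounding noise


def spectral_distance(a: SpectralProfile, b: SpectralProfile, use_smoothed: bool = False) -> float:
    """1 - cosine similarity of two eigenvalue profiles.

    Default compares the raw ascending eigenvalue vectors; ``use_smoothed``
    compares the Gaussian-smoothed densities instead (same grid required).
    """
    if use_smoothed:
        if a.density is None or b.density is None:
            raise ValueError("profiles lack smoothed densities; call smooth_spectrum first")
        return cosine_distance(a.density, b.density)
    return cosine_distance(a.eigenvalues, b.eigenvalues)
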