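"""Clustering and reconstruction of sparsely sampled spectro-microscopy maps.

A spectro-microscopy scan is a (ny, nx, energy) stack: one spectrum per
pixel.  Under sparse sampling each pixel only carries the few energies of
a sampling plan, so the reconstruction is not done pixel by pixel.
Instead, pixels with similar sampled vectors are grouped by k-means; each
cluster's center (the exact mean of its members, which improves the
signal-to-noise ratio by statistical averaging) is then treated as one
measurement column and expanded to a full spectrum through the reduced
basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .deim_sampling import SamplingPlan, reconstruct, solve_coefficients
from .reduced_basis import ReducedBasis
from .spectra_core import DegeneracyError, EnergyGrid

__all__ = [
    "SpectroMap",
    "SparseStack",
    "ClusterResult",
    "sample_map",
    "cluster_pixels",
    "silhouette",
    "reconstruct_map_spectra",
    "save_map",
    "load_map",
    "save_clusters",
]


@dataclass(eq=False)
class SpectroMap:
    """Fully sampled (ny, nx, m) stack, optionally with simulation truth."""

    data: np.ndarray
    grid: EnergyGrid
    truth: dict | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3 or d.shape[2] != len(self.grid):
            raise ValueError("stack must be (ny, nx, m) with m matching the grid")
        if not np.all(np.isfinite(d)):
            raise ValueError("stack contains non-finite values")
        self.data = d

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]


@dataclass(eq=False)
class SparseStack:
    """Sparsely sampled (ny, nx, s) stack tied to its sampling plan."""

    data: np.ndarray
    plan: SamplingPlan

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3 or d.shape[2] != self.plan.s:
            raise ValueError("sparse stack depth must match the plan length")
        self.data = d

    @property
    def pixels(self) -> np.ndarray:
        """Pixels flattened to an (ny*nx, s) matrix."""
        return self.data.reshape(-1, self.data.shape[2])


@dataclass(eq=False)
class ClusterResult:
    """k-means grouping of sampled pixel vectors.

    ``centers`` are the exact per-cluster means of the member pixels (in
    the raw, unnormalized sampled space), recomputed after the fit.
    """

    labels: np.ndarray
    centers: np.ndarray
    K: int
    seed: int
    inertia: float = np.nan
    silhouette: float | None = None


def sample_map(spectro_map: SpectroMap, plan: SamplingPlan,
               noise_level: float = 0.0, noise_model: str = "uniform",
               scale_ref: float = 1.0, seed: int | None = None) -> SparseStack:
    """Simulated acquisition: slice the stack at the plan energies.

    Optional per-point noise emulates a real sparse measurement.
    """
    if np.any(plan.indices >= len(spectro_map.grid)):
        raise ValueError("plan index out of range for this map's grid")
    data = spectro_map.data[:, :, plan.indices].copy()
    if noise_level > 0:
        from .synthetic_spectra import _noise_array
        rng = np.random.default_rng(seed)
        data += _noise_array(data.shape, noise_level, noise_model,
                             scale_ref, rng)
    return SparseStack(data=data, plan=plan)


def cluster_pixels(stack: SparseStack, K: int, n_restarts: int = 10,
                   seed: int = 0, normalize: bool = False,
                   compute_silhouette: bool = False,
                   silhouette_sample_size: int | None = 2000) -> ClusterResult:
    """Group sampled pixel vectors into ``K`` clusters with k-means.

    ``n_restarts`` independent initializations are run from the given seed
    and the best fit (lowest within-cluster sum of squares) is kept, so the
    result is reproducible.  ``normalize`` optionally scales each pixel
    vector to unit norm first, for thickness-dominated maps; centers are
    always reported in the raw space as exact member means.
    """
    X = stack.pixels
    npix = X.shape[0]
    if not 1 <= K <= npix:
        raise ValueError(f"K={K} outside [1, {npix}]")
    n_distinct = np.unique(X, axis=0).shape[0]
    if K > n_distinct:
        raise DegeneracyError(
            f"K={K} exceeds the {n_distinct} distinct pixel vectors")
    fit_X = X
    if normalize:
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        fit_X = np.divide(X, norms, out=np.zeros_like(X), where=norms > 0)
    km = KMeans(n_clusters=K, n_init=n_restarts,
                random_state=int(seed) % (2**32))
    labels = km.fit_predict(fit_X)
    centers = np.vstack([X[labels == c].mean(axis=0) for c in range(K)])
    result = ClusterResult(labels=labels.reshape(stack.data.shape[:2]),
                           centers=centers, K=K, seed=int(seed),
                           inertia=float(km.inertia_))
    if compute_silhouette and K >= 2:
        result.silhouette = silhouette(stack, result.labels,
                                       sample_size=silhouette_sample_size,
                                       seed=seed)
    return result


def silhouette(stack: SparseStack, labels: np.ndarray,
               sample_size: int | None = None, seed: int = 0) -> float:
    """Mean silhouette coefficient of a labeling (Euclidean distance).

    Advisory diagnostic for choosing the cluster count; requires at least
    two nonempty clusters.
    """
    lab = np.asarray(labels).ravel()
    uniq = np.unique(lab)
    if uniq.size < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    return float(silhouette_score(stack.pixels, lab,
                                  sample_size=sample_size,
                                  random_state=int(seed) % (2**32)))


def reconstruct_map_spectra(result: ClusterResult, basis: ReducedBasis,
                            plan: SamplingPlan) -> np.ndarray:
    """Expand each cluster center into a full spectrum via the basis.

    Returns an (m, K) matrix whose columns are the reconstructed XANES
    spectra of the clusters.
    """
    if result.centers.shape[1] != plan.s:
        raise ValueError("cluster centers do not match the plan length")
    coeffs = solve_coefficients(basis, plan, result.centers.T)
    return reconstruct(basis, coeffs)


# ---------------------------------------------------------------------------
# HDF5 stack I/O

def save_map(spectro_map: SpectroMap, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("stack")
        g.create_dataset("data", data=spectro_map.data)
        g.create_dataset("energies", data=spectro_map.grid.energies)
        if spectro_map.truth is not None:
            t = f.create_group("truth")
            t.create_dataset("labels", data=spectro_map.truth["labels"])
            t.create_dataset("weights", data=spectro_map.truth["weights"])


def load_map(path) -> SpectroMap:
    with h5py.File(path, "r") as f:
        truth = None
        if "truth" in f:
            truth = {"labels": f["truth/labels"][...],
                     "weights": f["truth/weights"][...]}
        return SpectroMap(data=f["stack/data"][...],
                          grid=EnergyGrid(f["stack/energies"][...]),
                          truth=truth)


def save_clusters(result: ClusterResult, path, png_path=None) -> None:
    """Write cluster labels/centers to HDF5 and, optionally, a PNG preview."""
    with h5py.File(path, "w") as f:
        g = f.create_group("clusters")
        g.create_dataset("labels", data=result.labels)
        g.create_dataset("centers", data=result.centers)
        g.attrs["K"] = int(result.K)
        g.attrs["seed"] = int(result.seed)
        g.attrs["inertia"] = float(result.inertia)
        if result.silhouette is not None:
            g.attrs["silhouette"] = float(result.silhouette)
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(5, 5))
        im = ax.imshow(result.labels, interpolation="nearest", cmap="tab10")
        fig.colorbar(im, ax=ax, label="cluster")
        ax.set_xlabel("x (pixel)")
        ax.set_ylabel("y (pixel)")
        fig.savefig(png_path, dpi=120, bbox_inches="tight")
        plt.close(fig)
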