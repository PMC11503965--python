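"""Reduced (POD/PCA) bases of spectral libraries and rank selection.

The prior description of a system — a library ``A`` of reference spectra
and background variants — is compressed by a thin SVD, ``A = U S V^T``.
The leading left singular vectors ``U_k`` span the states the experiment
is expected to encounter; everything downstream (sampling-point selection
and reconstruction) lives in that subspace.  Right singular vectors are
computed but deliberately not retained: only the energy-side basis is
needed for sampling design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np

from .spectra_core import EnergyGrid, SpectralLibrary

__all__ = [
    "ReducedBasis",
    "compute_basis",
    "explained_variance",
    "select_rank",
    "numerical_rank",
    "save_basis",
    "load_basis",
]


@dataclass(eq=False)
class ReducedBasis:
    """Truncated left singular vectors of a spectral library.

    ``U`` has orthonormal columns ordered by decreasing singular value;
    ``k`` is the truncation rank actually used by sampling design (defaults
    to all retained columns).  If ``centering == "mean"`` the column mean
    was removed before the SVD and is stored for reconstruction.
    """

    grid: EnergyGrid
    U: np.ndarray
    singular_values: np.ndarray
    explained_variance_ratio: np.ndarray
    k: int
    centering: str = "none"
    mean: np.ndarray | None = None
    n_columns: int = 0  # number of library columns the basis was built from

    def __post_init__(self) -> None:
        if self.U.shape[0] != len(self.grid):
            raise ValueError("U row count must match the grid")
        if self.U.shape[1] != self.singular_values.size:
            raise ValueError("one singular value per basis column required")
        tol = 1e-12 * (self.singular_values[0] if self.singular_values.size else 1.0)
        if np.any(np.diff(self.singular_values) > tol):
            raise ValueError("singular values must be nonincreasing")
        if not 1 <= self.k <= self.U.shape[1]:
            raise ValueError("truncation rank out of range")
        if self.centering == "mean" and self.mean is None:
            raise ValueError("mean-centered basis must carry its mean vector")

    @property
    def l(self) -> int:  # noqa: E743 - established notation for n. of modes
        return self.U.shape[1]

    @property
    def Uk(self) -> np.ndarray:
        return self.U[:, : self.k]


def compute_basis(lib: SpectralLibrary, centering: str = "none") -> ReducedBasis:
    """Thin SVD of a (optionally mean-centered) library.

    ``centering="none"`` is the default: a flat/offset direction in the
    library already plays the role of the mean, and a plain SVD keeps the
    components interpretable as spectra.  ``centering="mean"`` removes the
    column mean first (classical PCA); the retained mode count then drops
    by one since centering annihilates one direction.

    Each basis vector's sign is fixed so that its largest-magnitude entry
    is positive, removing the SVD sign ambiguity that would otherwise make
    downstream greedy selection machine-dependent in tie cases.
    """
    if centering not in ("none", "mean"):
        raise ValueError(f"unknown centering {centering!r}")
    a = lib.matrix
    if not np.all(np.isfinite(a)):
        raise ValueError("library contains non-finite entries")
    m, n = a.shape
    mean = None
    if centering == "mean":
        mean = a.mean(axis=1)
        a = a - mean[:, None]
        l = max(1, min(m, n - 1)) if n > 1 else 1
    else:
        l = min(m, n)
    u, s, _vt = np.linalg.svd(a, full_matrices=False)
    u, s = u[:, :l], s[:l]
    # sign convention: largest-|entry| of each column is positive
    for i in range(u.shape[1]):
        j = int(np.argmax(np.abs(u[:, i])))
        if u[j, i] < 0:
            u[:, i] = -u[:, i]
    total = float(np.sum(s**2))
    ratios = s**2 / total if total > 0 else np.zeros_like(s)
    return ReducedBasis(grid=lib.grid, U=u, singular_values=s,
                        explained_variance_ratio=ratios, k=l,
                        centering=centering, mean=mean, n_columns=n)


def explained_variance(basis: ReducedBasis) -> np.ndarray:
    """Fraction of library variance per component: sigma_i^2 / sum sigma^2."""
    s2 = basis.singular_values**2
    total = float(s2.sum())
    return s2 / total if total > 0 else np.zeros_like(s2)


def _rank_from_singular_values(s: np.ndarray, rel_tol: float) -> int:
    if s.size == 0 or s[0] == 0:
        return 0
    return int(np.count_nonzero(s > rel_tol * s[0]))


def select_rank(basis: ReducedBasis, method: str, param=None) -> int:
    """Choose the truncation rank ``k``.

    ``count``               returns ``param`` (e.g. the assumed number of
                            chemical states, or the number of standards);
    ``variance_threshold``  smallest k with cumulative explained-variance
                            ratio >= param;
    ``elbow``               sharpest bend (most negative second difference)
                            of the log explained-variance curve, ties to
                            the smallest k;
    ``auto`` / ``rank``     all components above the numerical noise floor,
                            i.e. singular values > max(m, n) * eps * sigma_1
                            (or > param * sigma_1 when param is given).

    ``auto`` is what the end-to-end design pipeline uses by default: it
    keeps every component that is not pure round-off, which is the right
    reading of "capture all non-negligible variance" when the library
    deliberately contains a near-zero flat state whose variance share is
    tiny but whose direction is still needed for interpolation.
    """
    ratios = basis.explained_variance_ratio
    l = basis.l
    if method == "count":
        k = int(param)
        if not 1 <= k <= l:
            raise ValueError(f"requested rank {k} outside [1, {l}]")
        return k
    if method == "variance_threshold":
        tau = float(param)
        if not 0 < tau <= 1:
            raise ValueError("variance threshold must lie in (0, 1]")
        cum = np.cumsum(ratios)
        hits = np.nonzero(cum >= tau - 1e-15)[0]
        return int(hits[0]) + 1 if hits.size else l
    if method == "elbow":
        logr = np.log10(np.maximum(ratios, 1e-300))
        padded = np.concatenate([[logr[0]], logr, [logr[-1]]])
        d2 = padded[2:] - 2 * padded[1:-1] + padded[:-2]
        return int(np.argmin(d2)) + 1
    if method in ("auto", "rank"):
        s = basis.singular_values
        rel_tol = (max(len(basis.grid), max(basis.n_columns, l))
                   * np.finfo(float).eps if param is None else float(param))
        return max(1, _rank_from_singular_values(s, rel_tol))
    raise ValueError(f"unknown rank-selection method {method!r}")


def numerical_rank(lib, rel_tol: float = 1e-8) -> int:
    """Count singular values above ``rel_tol * sigma_1``.

    Accepts a :class:`SpectralLibrary` or a plain 2-D array.
    """
    a = lib.matrix if isinstance(lib, SpectralLibrary) else np.asarray(lib, float)
    if not np.all(np.isfinite(a)):
        raise ValueError("matrix contains non-finite entries")
    s = np.linalg.svd(a, compute_uv=False)
    return _rank_from_singular_values(s, rel_tol)


def save_basis(basis: ReducedBasis, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("basis")
        g.create_dataset("U", data=basis.U)
        g.create_dataset("singular_values", data=basis.singular_values)
        g.create_dataset("energies", data=basis.grid.energies)
        if basis.mean is not None:
            g.create_dataset("mean", data=basis.mean)
        g.attrs["centering"] = basis.centering
        g.attrs["k"] = int(basis.k)
        g.attrs["n_columns"] = int(basis.n_columns)


def load_basis(path) -> ReducedBasis:
    with h5py.File(path, "r") as f:
        g = f["basis"]
        s = g["singular_values"][...]
        total = float(np.sum(s**2))
        return ReducedBasis(
            grid=EnergyGrid(g["energies"][...]),
            U=g["U"][...],
            singular_values=s,
            explained_variance_ratio=s**2 / total if total > 0 else 0 * s,
            k=int(g.attrs["k"]),
            centering=str(g.attrs["centering"]),
            mean=g["mean"][...] if "mean" in g else None,
            n_columns=int(g.attrs.get("n_columns", 0)),
        )
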