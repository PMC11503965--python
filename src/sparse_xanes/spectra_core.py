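"""Spectrum and spectral-library containers plus text/CSV/HDF5 I/O.

Every downstream stage (basis construction, sampling-point selection, map
reconstruction) operates on a shared energy axis, so this module owns the
grid bookkeeping: parsing two-column XAS text, linear regridding with a
hard no-extrapolation rule, and assembling libraries whose columns are
spectra on a common grid.  A library is simply an ``m x n`` matrix whose
rows index energy and whose columns index spectra (reference standards,
background variants, or pixels of a scan).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ExtrapolationError",
    "WindowError",
    "ConfigurationError",
    "DegeneracyError",
    "EnergyGrid",
    "Spectrum",
    "SpectralLibrary",
    "load_spectrum",
    "save_spectrum",
    "regrid",
    "build_library",
    "edge_step_estimate",
    "save_library_csv",
    "load_library_csv",
    "save_library_hdf5",
    "load_library_hdf5",
]


class ParseError(ValueError):
    """A spectrum file could not be parsed."""


class ExtrapolationError(ValueError):
    """A regrid target lies outside the source energy range."""


class WindowError(ValueError):
    """An edge-step averaging window contains no grid points."""


class ConfigurationError(ValueError):
    """A configuration object is internally inconsistent."""


class DegeneracyError(RuntimeError):
    """A linear system inside an algorithm became singular."""


@dataclass(eq=False)
class EnergyGrid:
    """A strictly increasing, finite energy axis in eV."""

    energies: np.ndarray

    def __post_init__(self) -> None:
        e = np.atleast_1d(np.asarray(self.energies, dtype=float))
        if e.ndim != 1 or e.size < 2:
            raise ValueError("energy grid needs at least two points")
        if not np.all(np.isfinite(e)):
            raise ValueError("energy grid contains non-finite values")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing")
        self.energies = e

    def __len__(self) -> int:
        return int(self.energies.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.energies[0]), float(self.energies[-1])

    def is_uniform(self, rtol: float = 1e-9) -> bool:
        d = np.diff(self.energies)
        return bool(np.all(np.abs(d - d[0]) <= rtol * abs(d[0])))

    @property
    def step(self) -> float:
        """Grid step in eV; only meaningful for uniform grids."""
        return float(self.energies[1] - self.energies[0])


@dataclass(eq=False)
class Spectrum:
    """A single spectrum (absorption, fluorescence ratio or phase) on a grid."""

    grid: EnergyGrid
    values: np.ndarray
    label: str = ""
    edge_energy: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != len(self.grid):
            raise ValueError("values length must match the energy grid")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum contains non-finite values")
        self.values = v


@dataclass(eq=False)
class SpectralLibrary:
    """An ``m x n`` matrix of spectra sharing one energy grid.

    Columns are individual spectra; ``labels`` names them.  ``signal_type``
    distinguishes absorption-like libraries from phase libraries produced
    by the Kramers-Kronig transform.
    """

    grid: EnergyGrid
    matrix: np.ndarray
    labels: list[str] = field(default_factory=list)
    edge_energy: float | None = None
    signal_type: str = "absorption"

    def __post_init__(self) -> None:
        a = np.asarray(self.matrix, dtype=float)
        if a.ndim == 1:
            a = a[:, None]
        if a.shape[0] != len(self.grid):
            raise ValueError("matrix row count must match the energy grid")
        if a.shape[1] < 1:
            raise ValueError("library needs at least one column")
        if not np.all(np.isfinite(a)):
            raise ValueError("library contains non-finite values")
        if not self.labels:
            self.labels = [f"col{j}" for j in range(a.shape[1])]
        if len(self.labels) != a.shape[1]:
            raise ValueError("one label per column is required")
        self.matrix = a
        self.labels = [str(s) for s in self.labels]

    @property
    def m(self) -> int:
        return self.matrix.shape[0]

    @property
    def n(self) -> int:
        return self.matrix.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.matrix[:, j]

    def spectrum(self, j: int) -> Spectrum:
        return Spectrum(self.grid, self.matrix[:, j].copy(),
                        label=self.labels[j], edge_energy=self.edge_energy)


# ---------------------------------------------------------------------------
# text I/O

def _read_lines(source) -> tuple[list[str], str]:
    if hasattr(source, "read"):
        return source.read().splitlines(), getattr(source, "name", "<stream>")
    return Path(source).read_text().splitlines(), str(source)


def load_spectrum(source, dialect: str = "two_column", label: str = "",
                  edge_energy: float | None = None) -> Spectrum:
    """Read a two-column (energy eV, value) text spectrum.

    Comment lines start with ``#`` (XDI-style header keys such as
    ``element.edge`` live in comments and are ignored).  The ``two_column``
    dialect requires exactly two fields per data row; ``xdi_like`` tolerates
    extra trailing columns and keeps the first two.  Rows are sorted by
    energy on load and duplicate energies are rejected.
    """
    if dialect not in ("two_column", "xdi_like"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lines, name = _read_lines(source)
    rows: list[tuple[float, float]] = []
    for lineno, raw in enumerate(lines, start=1):
        s = raw.strip()
        if not s or s.startswith("#"):
            continue
        fields = s.replace(",", " ").split()
        if len(fields) < 2 or (dialect == "two_column" and len(fields) != 2):
            raise ParseError(f"{name}: malformed row at line {lineno}: {raw!r}")
        try:
            rows.append((float(fields[0]), float(fields[1])))
        except ValueError as exc:
            raise ParseError(
                f"{name}: non-numeric entry at line {lineno}: {raw!r}") from exc
    if len(rows) < 2:
        raise ParseError(f"{name}: fewer than two data rows")
    arr = np.array(sorted(rows, key=lambda t: t[0]), dtype=float)
    e, v = arr[:, 0], arr[:, 1]
    if np.any(np.diff(e) == 0):
        dup = e[:-1][np.diff(e) == 0][0]
        raise ParseError(f"{name}: duplicate energy {dup:g} eV")
    if not label:
        label = Path(name).stem if name != "<stream>" else ""
    return Spectrum(EnergyGrid(e), v, label=label, edge_energy=edge_energy)


def save_spectrum(spec: Spectrum, target) -> None:
    """Write a spectrum as two-column text at full double precision."""
    header = f"# {spec.label}\n"
    if spec.edge_energy is not None:
        header += f"# edge_energy: {spec.edge_energy!r}\n"
    body = "\n".join(f"{e:.17g} {v:.17g}"
                     for e, v in zip(spec.grid.energies, spec.values))
    text = header + body + "\n"
    if hasattr(target, "write"):
        target.write(text)
    else:
        Path(target).write_text(text)


# ---------------------------------------------------------------------------
# regridding and library assembly

def regrid(spec: Spectrum, grid: EnergyGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid``.

    Extrapolation is refused: a grid point outside the source range raises
    :class:`ExtrapolationError` rather than fabricating pre/post-edge tails.
    """
    lo, hi = spec.grid.span
    glo, ghi = grid.span
    if glo < lo or ghi > hi:
        raise ExtrapolationError(
            f"target grid [{glo:g}, {ghi:g}] eV exceeds source range "
            f"[{lo:g}, {hi:g}] eV")
    v = np.interp(grid.energies, spec.grid.energies, spec.values)
    return Spectrum(grid, v, label=spec.label, edge_energy=spec.edge_energy)


def build_library(spectra: Sequence[Spectrum], grid: EnergyGrid | None = None,
                  add_flat: bool = False, flat_value: float = 1e-8,
                  edge_energy: float | None = None) -> SpectralLibrary:
    """Assemble spectra (regridded onto a common axis) into a library.

    With ``add_flat`` a constant column at ``flat_value`` (default 1e-8, a
    near-zero background state) is appended as the LAST column so the
    ordering of the real standards is unperturbed.
    """
    if len(spectra) == 0:
        raise ValueError("cannot build a library from an empty spectrum list")
    if grid is None:
        grid = spectra[0].grid
    cols = [regrid(s, grid).values for s in spectra]
    labels = [s.label or f"col{j}" for j, s in enumerate(spectra)]
    if add_flat:
        cols.append(np.full(len(grid), float(flat_value)))
        labels.append("flat")
    if edge_energy is None:
        edge_energy = next((s.edge_energy for s in spectra
                            if s.edge_energy is not None), None)
    return SpectralLibrary(grid, np.column_stack(cols), labels=labels,
                           edge_energy=edge_energy)


def edge_step_estimate(spec: Spectrum, edge_energy: float | None = None,
                       window: float = 20.0) -> float:
    """Edge-jump estimate: mean(post-edge) - mean(pre-edge).

    Averages the signal more than ``window`` eV above and below the edge.
    This is the natural amplitude scale for noise and background models;
    it is not a substitute for full XAS normalisation.
    """
    e0 = spec.edge_energy if edge_energy is None else float(edge_energy)
    if e0 is None:
        raise ValueError("edge_energy is required (not set on the spectrum)")
    lo, hi = spec.grid.span
    if not (lo < e0 < hi):
        raise ValueError(f"edge energy {e0:g} eV not inside grid range")
    e = spec.grid.energies
    pre = spec.values[e < e0 - window]
    post = spec.values[e > e0 + window]
    if pre.size == 0 or post.size == 0:
        raise WindowError(
            f"no grid points beyond +/-{window:g} eV of the edge")
    return float(post.mean() - pre.mean())


# ---------------------------------------------------------------------------
# library serialization

def save_library_csv(lib: SpectralLibrary, path) -> None:
    """CSV with an ``energy_ev`` column followed by one column per spectrum."""
    df = pd.DataFrame(lib.matrix, columns=lib.labels)
    df.insert(0, "energy_ev", lib.grid.energies)
    df.to_csv(path, index=False, float_format="%.17g")


def load_library_csv(path, edge_energy: float | None = None,
                     signal_type: str = "absorption") -> SpectralLibrary:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected an energy column plus spectra")
    e = df.iloc[:, 0].to_numpy(dtype=float)
    return SpectralLibrary(EnergyGrid(e), df.iloc[:, 1:].to_numpy(dtype=float),
                           labels=list(df.columns[1:]), edge_energy=edge_energy,
                           signal_type=signal_type)


def save_library_hdf5(lib: SpectralLibrary, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("library")
        g.create_dataset("matrix", data=lib.matrix)
        g.create_dataset("energies", data=lib.grid.energies)
        g.create_dataset("labels", data=np.array(lib.labels, dtype=object),
                         dtype=h5py.string_dtype())
        g.attrs["signal_type"] = lib.signal_type
        if lib.edge_energy is not None:
            g.attrs["edge_energy"] = float(lib.edge_energy)


def load_library_hdf5(path) -> SpectralLibrary:
    with h5py.File(path, "r") as f:
        g = f["library"]
        edge = float(g.attrs["edge_energy"]) if "edge_energy" in g.attrs else None
        return SpectralLibrary(
            EnergyGrid(g["energies"][...]),
            g["matrix"][...],
            labels=[s.decode() if isinstance(s, bytes) else str(s)
                    for s in g["labels"][...]],
            edge_energy=edge,
            signal_type=str(g.attrs.get("signal_type", "absorption")),
        )
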