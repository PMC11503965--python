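"""Discrete Kramers-Kronig transform of absorption spectra to phase spectra.

Phase-contrast techniques (ptychography) measure the dispersive part of
the refractive index, which is linked to absorption by the Kramers-Kronig
principal-value integral

    chi'(E) = (2/pi) P int_0^inf  E' chi''(E') / (E'^2 - E^2)  dE'.

The principal-value singularity is handled with the Maclaurin
(alternating-point) rule: the integrand is summed only at grid points an
odd offset away from the evaluation point, with weight 2h.  The kernel
never lands on its pole, so no explicit singularity treatment is needed,
and the rule is second-order accurate in the grid step.

Finite measurement windows are handled by subtracting the straight line
through the spectrum's two end values before transforming (equivalent to
treating the out-of-window signal as a slowly varying baseline whose
dispersive response is not of interest here).  Outputs are therefore
defined up to the kernel's scale and that baseline; shapes, linearity and
relative amplitudes are what the sampling design consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_core import EnergyGrid, SpectralLibrary, Spectrum, regrid

__all__ = [
    "PhaseSpectrum",
    "kk_transform",
    "build_phase_library",
]


@dataclass(eq=False)
class PhaseSpectrum:
    """Dispersive (phase-like) spectrum on a uniform energy grid."""

    grid: EnergyGrid
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if not self.grid.is_uniform(rtol=1e-9):
            raise ValueError("phase spectra require a uniform energy grid")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.grid),):
            raise ValueError("values length must match the grid")
        if not np.all(np.isfinite(v)):
            raise ValueError("phase spectrum contains non-finite values")
        self.values = v


def _kk_matrix(energies: np.ndarray) -> np.ndarray:
    """Dense Maclaurin-rule kernel: out = (2/pi) * K @ values * 2h."""
    e = energies
    h = e[1] - e[0]
    idx = np.arange(e.size)
    odd = ((idx[None, :] - idx[:, None]) % 2) == 1
    denom = e[None, :] ** 2 - e[:, None] ** 2
    denom_safe = np.where(odd, denom, 1.0)
    kern = np.where(odd, e[None, :] / denom_safe, 0.0)
    return (2.0 / np.pi) * 2.0 * h * kern


def kk_transform(spec: Spectrum, detrend: bool = True) -> PhaseSpectrum:
    """Transform an absorption spectrum to its dispersive partner.

    The spectrum must already live on a uniform, strictly positive energy
    grid (use :func:`sparse_xanes.spectra_core.regrid` first otherwise).
    With ``detrend`` (default) the line through the two end values is
    removed first, which suppresses window-truncation artifacts from the
    edge step; the operation remains linear in the input.
    """
    if not spec.grid.is_uniform(rtol=1e-9):
        raise ValueError(
            "Kramers-Kronig transform requires a uniform grid; regrid the "
            "spectrum onto a uniform energy axis first")
    e = spec.grid.energies
    if e[0] <= 0:
        raise ValueError("energies must be strictly positive")
    f = spec.values.astype(float).copy()
    if detrend:
        f = f - (f[0] + (f[-1] - f[0]) * (e - e[0]) / (e[-1] - e[0]))
    out = _kk_matrix(e) @ f
    return PhaseSpectrum(spec.grid, out, label=spec.label)


def uniform_grid_like(grid: EnergyGrid, step: float | None = None) -> EnergyGrid:
    """A uniform grid spanning the same range, at ``step`` (default: finest)."""
    lo, hi = grid.span
    if step is None:
        step = float(np.min(np.diff(grid.energies)))
    n = int(np.floor((hi - lo) / step)) + 1
    return EnergyGrid(np.linspace(lo, lo + (n - 1) * step, n))


def build_phase_library(standards: SpectralLibrary, step: float | None = None,
                        detrend: bool = True) -> SpectralLibrary:
    """Transform every library column to a phase spectrum.

    Non-uniform libraries are first resampled onto a uniform grid covering
    the same range (at the finest native step unless ``step`` is given).
    Background variants intended for phase-sampling design should be
    generated on the absorption spectra BEFORE calling this, so that the
    transform sees the drifted absorption, mirroring how a background
    enters a real phase measurement.
    """
    if standards.grid.is_uniform(rtol=1e-9) and step is None:
        grid = standards.grid
        matrix = standards.matrix
    else:
        grid = uniform_grid_like(standards.grid, step)
        matrix = np.column_stack([
            regrid(standards.spectrum(j), grid).values
            for j in range(standards.n)
        ])
    kernel = _kk_matrix(grid.energies)
    e = grid.energies
    cols = []
    for j in range(matrix.shape[1]):
        f = matrix[:, j].copy()
        if detrend:
            f = f - (f[0] + (f[-1] - f[0]) * (e - e[0]) / (e[-1] - e[0]))
        cols.append(kernel @ f)
    return SpectralLibrary(grid, np.column_stack(cols),
                           labels=list(standards.labels),
                           edge_energy=standards.edge_energy,
                           signal_type="phase")
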