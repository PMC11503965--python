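"""Synthetic XANES standards, noise models, and phantom image stacks.

The generator emulates Fe K-edge-like near-edge spectra: an arctangent edge
step broadened by the core-hole lifetime, Gaussian near-edge features
(white line, pre-edge peaks), and exponentially damped post-edge
oscillations standing in for fine structure.  It exists so that the whole
sampling-design pipeline — basis construction, point selection, clustering,
reconstruction — is exercisable end to end without any measured data, while
keeping the statistical structure (low-rank spectral families, bounded
noise, piecewise energy grids) that the method actually relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spectra_core import (
    ConfigurationError,
    EnergyGrid,
    SpectralLibrary,
    Spectrum,
    build_library,
    edge_step_estimate,
)

__all__ = [
    "FE_K_EDGE_EV",
    "StandardParams",
    "PhantomRegion",
    "PhantomLayout",
    "make_energy_grid",
    "synthesize_standard",
    "random_standard_params",
    "default_standards_library",
    "add_noise",
    "make_phantom_map",
    "band_layout",
]

FE_K_EDGE_EV = 7112.0


@dataclass(eq=False)
class StandardParams:
    """Parameters of one synthetic XANES standard.

    ``features`` are Gaussians (center eV, amplitude, sigma eV); the white
    line and pre-edge peaks of real standards.  ``oscillations`` are damped
    sinusoids (period eV, amplitude, decay eV) applied above the edge only.
    """

    edge_energy: float = FE_K_EDGE_EV
    step: float = 1.0
    lifetime_width: float = 1.4
    features: tuple = ()
    oscillations: tuple = ()
    label: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("edge step must be positive")
        if self.lifetime_width <= 0:
            raise ValueError("lifetime width must be positive")
        for _, _, sigma in self.features:
            if sigma <= 0:
                raise ValueError("feature sigma must be positive")
        for period, _, decay in self.oscillations:
            if period <= 0 or decay <= 0:
                raise ValueError("oscillation period and decay must be positive")


def make_energy_grid(edge_energy: float = FE_K_EDGE_EV,
                     pre: tuple[float, float] = (-150.0, 10.0),
                     near: tuple[float, float, float] = (-20.0, 30.0, 0.5),
                     post: tuple[float, float, float] = (250.0, 1.0, 1.15),
                     ) -> EnergyGrid:
    """Piecewise XANES energy grid around an absorption edge.

    ``pre = (start offset, step)``: coarse uniform sampling up to the
    near-edge window.  ``near = (start, stop, step)``: fine uniform sampling
    across the edge.  ``post = (stop offset, initial step, growth)``:
    geometrically growing steps out to the end of the scan.  All offsets are
    relative to ``edge_energy``.  The defaults mirror a typical Fe K-edge
    scan: 10 eV pre-edge steps, 0.5 eV steps from -20 to +30 eV about the
    edge, then steps growing by 15% out to +250 eV.
    """
    pre_start, pre_step = map(float, pre)
    near_start, near_stop, near_step = map(float, near)
    post_stop, post_step0, growth = map(float, post)
    if not (pre_start < near_start < near_stop < post_stop):
        raise ConfigurationError("grid segments overlap or are out of order")
    if pre_step <= 0 or near_step <= 0 or post_step0 <= 0:
        raise ConfigurationError("grid steps must be positive")
    if growth < 1:
        raise ConfigurationError("post-edge growth factor must be >= 1")
    n_near = int(round((near_stop - near_start) / near_step))
    if abs(near_start + n_near * near_step - near_stop) > 1e-6 * near_step:
        raise ConfigurationError("near-edge window is not a multiple of its step")

    offsets: list[float] = []
    o = pre_start
    while o < near_start - 1e-9:
        offsets.append(o)
        o += pre_step
    offsets.extend(near_start + i * near_step for i in range(n_near + 1))
    step = post_step0
    o = near_stop + step
    while o <= post_stop + 1e-9:
        offsets.append(o)
        step *= growth
        o += step
    return EnergyGrid(edge_energy + np.asarray(offsets))


def synthesize_standard(params: StandardParams, grid: EnergyGrid) -> Spectrum:
    """Evaluate the analytic standard model on a grid (deterministic).

    value(E) = step * (1/2 + atan((E - E0)/Gamma)/pi)
             + sum of Gaussian features
             + [E > E0] * sum of amp * exp(-(E-E0)/decay) * sin(2 pi (E-E0)/period)
    """
    e = grid.energies
    x = e - params.edge_energy
    v = params.step * (0.5 + np.arctan(x / params.lifetime_width) / np.pi)
    for center, amp, sigma in params.features:
        v = v + amp * np.exp(-0.5 * ((e - center) / sigma) ** 2)
    post = x > 0
    for period, amp, decay in params.oscillations:
        v = v + post * amp * np.exp(-np.clip(x, 0, None) / decay) \
            * np.sin(2 * np.pi * x / period)
    return Spectrum(grid, v, label=params.label or f"std{params.seed}",
                    edge_energy=params.edge_energy)


def random_standard_params(n: int, edge_energy: float = FE_K_EDGE_EV,
                           seed: int = 0) -> list[StandardParams]:
    """Draw ``n`` randomized but realistic standards around one edge.

    Edge positions shift by a few eV between compounds (oxidation-state
    chemical shift); features concentrate in the near-edge window, and
    damped oscillations model post-edge structure.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        n_feat = int(rng.integers(2, 5))
        features = tuple(
            (edge_energy + rng.uniform(-8.0, 35.0),
             rng.uniform(0.05, 0.35),
             rng.uniform(1.5, 5.0))
            for _ in range(n_feat)
        )
        n_osc = int(rng.integers(1, 3))
        oscillations = tuple(
            (rng.uniform(20.0, 60.0), rng.uniform(0.02, 0.08),
             rng.uniform(30.0, 120.0))
            for _ in range(n_osc)
        )
        out.append(StandardParams(
            edge_energy=edge_energy + rng.uniform(-3.0, 5.0),
            step=rng.uniform(0.6, 1.2),
            lifetime_width=rng.uniform(1.0, 2.0),
            features=features,
            oscillations=oscillations,
            label=f"std{i:02d}",
            seed=seed,
        ))
    return out


def default_standards_library(n_standards: int = 12,
                              edge_energy: float = FE_K_EDGE_EV,
                              seed: int = 0,
                              grid: EnergyGrid | None = None,
                              add_flat: bool = True,
                              flat_value: float = 1e-8) -> SpectralLibrary:
    """The canonical fixture: 12 randomized standards plus a flat 1e-8 column.

    Mirrors a reference dictionary of measured standards augmented with a
    near-zero background state, for a total of 13 columns by default.
    """
    if grid is None:
        grid = make_energy_grid(edge_energy)
    params = random_standard_params(n_standards, edge_energy, seed)
    spectra = [synthesize_standard(p, grid) for p in params]
    return build_library(spectra, grid, add_flat=add_flat,
                         flat_value=flat_value, edge_energy=edge_energy)


def add_noise(spec: Spectrum, level: float, model: str = "uniform",
              scale_ref: float | None = None, seed: int | None = None) -> Spectrum:
    """Add reproducible noise scaled to a reference amplitude.

    ``uniform`` adds i.i.d. Uniform(-level, +level) * scale_ref per point
    (a "+/- level" amplitude bound); ``gaussian`` adds N(0, (level/2)^2 *
    scale_ref^2).  ``scale_ref`` defaults to the spectrum's edge-step
    estimate when an edge energy is known, otherwise 1.
    """
    if level < 0:
        raise ValueError("noise level must be non-negative")
    if model not in ("uniform", "gaussian"):
        raise ValueError(f"unknown noise model {model!r}")
    if scale_ref is None:
        scale_ref = (edge_step_estimate(spec)
                     if spec.edge_energy is not None else 1.0)
    if scale_ref <= 0:
        raise ValueError("scale_ref must be positive")
    if level == 0:
        return Spectrum(spec.grid, spec.values.copy(), label=spec.label,
                        edge_energy=spec.edge_energy)
    rng = np.random.default_rng(seed)
    v = spec.values + _noise_array(spec.values.shape, level, model,
                                   float(scale_ref), rng)
    return Spectrum(spec.grid, v, label=spec.label, edge_energy=spec.edge_energy)


def _noise_array(shape, level: float, model: str, scale: float,
                 rng: np.random.Generator) -> np.ndarray:
    if model == "uniform":
        return rng.uniform(-level, level, size=shape) * scale
    return rng.normal(0.0, level / 2.0, size=shape) * scale


# ---------------------------------------------------------------------------
# phantom spectro-microscopy maps

@dataclass(eq=False)
class PhantomRegion:
    """One region of a phantom: a pixel mask, mixing weights, a thickness."""

    mask: np.ndarray
    weights: np.ndarray
    thickness: float = 1.0


@dataclass(eq=False)
class PhantomLayout:
    """Geometry and noise of a phantom map emulating a multi-phase sample."""

    shape: tuple[int, int]
    regions: list[PhantomRegion]
    noise_level: float = 0.0
    noise_model: str = "uniform"
    seed: int = 0


def band_layout(shape: tuple[int, int], phase_columns: Sequence[int],
                n_standards: int, noise_level: float = 0.0,
                seed: int = 0) -> PhantomLayout:
    """Vertical pure-phase bands covering the full frame, one per column index."""
    ny, nx = shape
    k = len(phase_columns)
    edges = np.linspace(0, nx, k + 1).astype(int)
    regions = []
    for i, col in enumerate(phase_columns):
        mask = np.zeros(shape, dtype=bool)
        mask[:, edges[i]:edges[i + 1]] = True
        w = np.zeros(n_standards)
        w[col] = 1.0
        regions.append(PhantomRegion(mask=mask, weights=w))
    return PhantomLayout(shape=shape, regions=regions,
                         noise_level=noise_level, seed=seed)


def _library_amplitude_scale(standards: SpectralLibrary) -> float:
    """Mean edge step over columns with a non-negligible edge jump."""
    if standards.edge_energy is None:
        return 1.0
    steps = []
    for j in range(standards.n):
        try:
            s = edge_step_estimate(standards.spectrum(j))
        except Exception:
            continue
        if abs(s) > 1e-6:
            steps.append(abs(s))
    return float(np.mean(steps)) if steps else 1.0


def make_phantom_map(layout: PhantomLayout, standards: SpectralLibrary,
                     background_cfg=None):
    """Build a (ny, nx, m) stack with per-pixel spectra and stored ground truth.

    Each pixel spectrum is ``thickness * (standards @ weights)`` for its
    region, plus an optional per-pixel random background draw and noise.
    Ground-truth labels (region index, -1 for uncovered pixels) and
    thickness-scaled weights ride along for parameter-recovery tests.
    """
    from .map_analysis import SpectroMap  # deferred: avoids an import cycle

    ny, nx = layout.shape
    m, n = standards.m, standards.n
    data = np.zeros((ny, nx, m))
    labels = np.full((ny, nx), -1, dtype=int)
    weights = np.zeros((ny, nx, n))
    for idx, reg in enumerate(layout.regions):
        mask = np.asarray(reg.mask, dtype=bool)
        if mask.shape != (ny, nx):
            raise ConfigurationError(
                f"region {idx} mask shape {mask.shape} does not match "
                f"layout shape {(ny, nx)}")
        w = np.asarray(reg.weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() > 1 + 1e-9:
            raise ConfigurationError(
                f"region {idx} weights must be >= 0 over {n} standards "
                "and sum to at most 1")
        data[mask] = reg.thickness * (standards.matrix @ w)
        labels[mask] = idx
        weights[mask] = reg.thickness * w

    rng = np.random.default_rng(layout.seed)
    scale = _library_amplitude_scale(standards)
    if background_cfg is not None:
        from .background_augmentation import sample_background
        e = standards.grid.energies
        covered = np.argwhere(labels >= 0)
        for (iy, ix) in covered:
            bg = sample_background(background_cfg, scale, rng)
            data[iy, ix] += bg.evaluate(e)
    if layout.noise_level > 0:
        data = data + _noise_array(data.shape, layout.noise_level,
                                   layout.noise_model, scale, rng)
    return SpectroMap(data=data, grid=standards.grid,
                      truth={"labels": labels, "weights": weights})
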