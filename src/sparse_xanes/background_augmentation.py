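"""Randomized anchored-polynomial background variants for spectral libraries.

XAS data reduction conventionally fits a low-order polynomial below the
edge and a low-order smooth curve above it.  To make a reduced basis (and
hence the selected sampling points) robust to such drift, each standard is
replicated many times with random additive backgrounds drawn from two
anchored families:

* pre-edge: the unique quadratic through a fixed anchor point (value 0)
  and two random control points, applied over the FULL energy range;
* post-edge: the unique cubic through a fixed anchor just above the edge
  (value 0) and three random control points, applied only at and above
  that anchor.

Because each family is an anchored interpolating polynomial, the set of
possible pre curves spans exactly a 2-dimensional function space and the
post curves a 3-dimensional one.  Augmentation therefore raises the rank
of a library by exactly 2 (pre only) or 5 (pre and post), which is what
ties the number of required sampling points to "number of states + 2 (or
5)".  A parametric Bezier realization of the same control points is
available behind a flag, but it is not exactly low-rank and is off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .spectra_core import (
    ConfigurationError,
    EnergyGrid,
    SpectralLibrary,
    Spectrum,
    edge_step_estimate,
)

__all__ = [
    "BackgroundConfig",
    "BackgroundCurve",
    "BezierBackgroundCurve",
    "default_background_config",
    "sample_background",
    "apply_background",
    "augment_library",
]


@dataclass(eq=False)
class BackgroundConfig:
    """Parameters of the random background model.

    Offsets are drawn uniformly in ``+/- offset_range * edge_step`` at
    control energies drawn uniformly inside the pre/post windows.
    ``enabled`` selects ``pre_only`` (quadratic drift everywhere) or
    ``pre_and_post`` (additionally the anchored cubic above the edge).
    """

    edge_energy: float
    pre_anchor: float
    post_anchor: float
    pre_window: tuple[float, float]
    post_window: tuple[float, float]
    offset_range: float = 0.1
    n_variants: int = 500
    seed: int = 0
    enabled: str = "pre_and_post"
    mode: str = "polynomial"  # or "bezier" (parametric, not exactly low-rank)

    def __post_init__(self) -> None:
        if not (self.pre_anchor < self.edge_energy < self.post_anchor):
            raise ConfigurationError(
                "anchors must bracket the edge: pre_anchor < edge < post_anchor")
        if self.offset_range < 0:
            raise ConfigurationError("offset_range must be non-negative")
        if self.n_variants < 1:
            raise ConfigurationError("n_variants must be at least 1")
        if self.enabled not in ("pre_only", "pre_and_post"):
            raise ConfigurationError(f"unknown enabled mode {self.enabled!r}")
        if self.mode not in ("polynomial", "bezier"):
            raise ConfigurationError(f"unknown curve mode {self.mode!r}")
        for name, (lo, hi) in (("pre_window", self.pre_window),
                               ("post_window", self.post_window)):
            if not hi > lo:
                raise ConfigurationError(f"{name} is empty or inverted")


@dataclass(eq=False)
class BackgroundCurve:
    """One realized background: anchored pre quadratic + gated post cubic.

    Coefficients are stored in the shifted variable ``x = E - anchor`` with
    zero constant term, so the anchoring (value 0 at the anchor) is exact by
    construction and the polynomials stay well conditioned at keV energies.
    ``pre_coeffs = (c1, c2)`` means ``c1*x + c2*x^2``; ``post_coeffs =
    (d1, d2, d3)`` means ``d1*x + d2*x^2 + d3*x^3``.
    """

    pre_anchor: float
    post_anchor: float
    pre_coeffs: np.ndarray = field(default_factory=lambda: np.zeros(2))
    post_coeffs: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def pre_values(self, energies: np.ndarray) -> np.ndarray:
        x = np.asarray(energies, dtype=float) - self.pre_anchor
        c1, c2 = self.pre_coeffs
        return c1 * x + c2 * x * x

    def post_values(self, energies: np.ndarray) -> np.ndarray:
        x = np.asarray(energies, dtype=float) - self.post_anchor
        d1, d2, d3 = self.post_coeffs
        return d1 * x + d2 * x * x + d3 * x ** 3

    def evaluate(self, energies: np.ndarray) -> np.ndarray:
        """Pre curve everywhere plus post curve gated at ``E >= post_anchor``."""
        e = np.asarray(energies, dtype=float)
        out = self.pre_values(e)
        gate = e >= self.post_anchor
        if np.any(gate):
            out = out + np.where(gate, self.post_values(e), 0.0)
        return out


def default_background_config(grid: EnergyGrid, edge_energy: float,
                              offset_range: float = 0.1,
                              n_variants: int = 500, seed: int = 0,
                              enabled: str = "pre_and_post") -> BackgroundConfig:
    """Anchors and windows for a typical XANES scan.

    Pre anchor at the start of the scan with random control energies up to
    10 eV below the edge; post anchor 10 eV above the edge with control
    energies out to the end of the scan.
    """
    lo, hi = grid.span
    if not (lo < edge_energy < hi):
        raise ConfigurationError("edge energy must lie inside the grid")
    return BackgroundConfig(
        edge_energy=edge_energy,
        pre_anchor=lo,
        post_anchor=edge_energy + 10.0,
        pre_window=(lo, edge_energy - 10.0),
        post_window=(edge_energy + 10.0, hi),
        offset_range=offset_range,
        n_variants=n_variants,
        seed=seed,
        enabled=enabled,
    )


def _draw_distinct(rng: np.random.Generator, lo: float, hi: float, k: int,
                   avoid: Iterable[float] = ()) -> np.ndarray:
    """Uniform energies in (lo, hi), pairwise distinct and away from anchors."""
    tol = 1e-6 * (hi - lo)
    if hi - lo <= tol * (k + 1):
        raise ConfigurationError(
            f"window ({lo:g}, {hi:g}) eV too narrow for {k} distinct points")
    avoid = list(avoid)
    out: list[float] = []
    for _ in range(k):
        for _attempt in range(100):
            x = float(rng.uniform(lo, hi))
            if all(abs(x - y) > tol for y in out + avoid):
                out.append(x)
                break
        else:  # pragma: no cover - astronomically unlikely
            raise ConfigurationError("could not draw distinct control energies")
    return np.array(out)


def _fit_anchored(anchor: float, energies: np.ndarray,
                  offsets: np.ndarray) -> np.ndarray:
    """Coefficients of the unique anchored polynomial through the controls.

    Solves V c = offsets with V[i, p] = (E_i - anchor)^(p+1); the constant
    term is pinned to zero by construction.
    """
    x = energies - anchor
    powers = np.arange(1, len(energies) + 1)
    vand = x[:, None] ** powers[None, :]
    try:
        return np.linalg.solve(vand, offsets)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ConfigurationError("degenerate control-point configuration") from exc


def _bezier_values(anchor_pt: tuple[float, float],
                   controls: np.ndarray, energies: np.ndarray) -> np.ndarray:
    """Evaluate a parametric Bezier curve through anchor + control points.

    Control points are ordered by energy; the curve is sampled densely in
    the Bezier parameter and interpolated back onto the energy axis.  Only
    used in the optional ``mode="bezier"``.
    """
    pts = np.vstack([np.array([anchor_pt]), controls])
    pts = pts[np.argsort(pts[:, 0])]
    t = np.linspace(0.0, 1.0, 256)[:, None]
    # de Casteljau via explicit Bernstein sum (few control points)
    n = pts.shape[0] - 1
    from math import comb
    bern = np.stack([comb(n, i) * t[:, 0] ** i * (1 - t[:, 0]) ** (n - i)
                     for i in range(n + 1)], axis=1)
    curve = bern @ pts
    order = np.argsort(curve[:, 0])
    return np.interp(energies, curve[order, 0], curve[order, 1])


@dataclass(eq=False)
class BezierBackgroundCurve(BackgroundCurve):
    """Parametric-Bezier realization of the same anchored control points.

    The curve through random control points with random energy knots is
    not exactly a low-order polynomial, so libraries augmented in this
    mode are not exactly low-rank; it exists for experimentation with a
    more literal freehand background and is off by default.
    """

    pre_controls: np.ndarray | None = None
    post_controls: np.ndarray | None = None

    def pre_values(self, energies: np.ndarray) -> np.ndarray:
        if self.pre_controls is None:
            return np.zeros_like(np.asarray(energies, dtype=float))
        return _bezier_values((self.pre_anchor, 0.0), self.pre_controls,
                              np.asarray(energies, dtype=float))

    def post_values(self, energies: np.ndarray) -> np.ndarray:
        if self.post_controls is None:
            return np.zeros_like(np.asarray(energies, dtype=float))
        return _bezier_values((self.post_anchor, 0.0), self.post_controls,
                              np.asarray(energies, dtype=float))


def sample_background(cfg: BackgroundConfig, edge_step: float,
                      rng: np.random.Generator | int | None = None,
                      ) -> BackgroundCurve:
    """Draw one random background curve scaled to ``edge_step``.

    The pre quadratic passes through ``(pre_anchor, 0)`` and two random
    control points; the post cubic through ``(post_anchor, 0)`` and three.
    Offsets are uniform in ``+/- offset_range * edge_step``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    amp = cfg.offset_range * abs(edge_step)
    e_pre = _draw_distinct(rng, *cfg.pre_window, 2, avoid=(cfg.pre_anchor,))
    off_pre = rng.uniform(-amp, amp, size=2)
    do_post = cfg.enabled == "pre_and_post"
    if do_post:
        e_post = _draw_distinct(rng, *cfg.post_window, 3,
                                avoid=(cfg.post_anchor,))
        off_post = rng.uniform(-amp, amp, size=3)
    if cfg.mode == "bezier":
        curve = BezierBackgroundCurve(pre_anchor=cfg.pre_anchor,
                                      post_anchor=cfg.post_anchor)
        if amp > 0:
            curve.pre_controls = np.column_stack([e_pre, off_pre])
            if do_post:
                curve.post_controls = np.column_stack([e_post, off_post])
        return curve
    curve = BackgroundCurve(pre_anchor=cfg.pre_anchor,
                            post_anchor=cfg.post_anchor)
    if amp == 0:
        return curve
    curve.pre_coeffs = _fit_anchored(cfg.pre_anchor, e_pre, off_pre)
    if do_post:
        curve.post_coeffs = _fit_anchored(cfg.post_anchor, e_post, off_post)
    return curve


def apply_background(spec: Spectrum, bg: BackgroundCurve) -> Spectrum:
    """Additively apply a background curve to a spectrum."""
    lo, hi = spec.grid.span
    if not (lo <= bg.pre_anchor <= hi):
        raise ConfigurationError("pre anchor outside the spectrum grid")
    v = spec.values + bg.evaluate(spec.grid.energies)
    return Spectrum(spec.grid, v, label=spec.label,
                    edge_energy=spec.edge_energy)


def augment_library(standards: SpectralLibrary, cfg: BackgroundConfig,
                    append_originals: bool = True) -> SpectralLibrary:
    """Replicate every standard ``cfg.n_variants`` times with random drift.

    Offsets scale with each parent standard's own edge step, so a flat
    (near-zero) column yields flat variants.  Labels record provenance as
    ``<standard>#v<k>``.  With ``append_originals`` the unmodified parents
    are appended after the variants.
    """
    rng = np.random.default_rng(cfg.seed)
    e = standards.grid.energies
    cols: list[np.ndarray] = []
    labels: list[str] = []
    for j in range(standards.n):
        parent = standards.column(j)
        spec_j = standards.spectrum(j)
        try:
            step = edge_step_estimate(spec_j, edge_energy=cfg.edge_energy)
        except Exception:
            step = 0.0
        for k in range(cfg.n_variants):
            bg = sample_background(cfg, step, rng)
            cols.append(parent + bg.evaluate(e))
            labels.append(f"{standards.labels[j]}#v{k}")
    if append_originals:
        for j in range(standards.n):
            cols.append(standards.column(j).copy())
            labels.append(standards.labels[j])
    return SpectralLibrary(standards.grid, np.column_stack(cols),
                           labels=labels, edge_energy=standards.edge_energy,
                           signal_type=standards.signal_type)
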